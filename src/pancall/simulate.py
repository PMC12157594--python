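"""Seeded synthetic diploid data with the structure the caller assumes.

The generator emulates, at desk scale, the data regime a pangenome-aware
short-read caller faces:

* a random linear reference carrying a **high-identity duplicated
  segment** (two near-identical copies, substitution-only divergence),
  the regime where short reads mismap for lack of unique markers;
* a **panel of phased haplotypes** whose variant carrier counts follow a
  neutral-like frequency law (P(i carriers) proportional to 1/i), giving
  the monotonically decreasing allele-frequency spread real panels show;
* a **diploid sample** whose two haplotypes copy two panel donors and add
  rare private variants, so most sample variation exists in the panel;
* **error-bearing reads**: uniform coverage, per-base substitution errors
  with reduced base quality at error positions, and reads originating
  entirely inside a duplication copy re-addressed to the homologous copy
  with a configurable mismap probability (mapping quality <= 3, sequence
  kept — they present as dense mismatch clusters at the wrong locus, the
  reference-bias signature the haplotype block is meant to resolve);
* a **truth VCF** with phased genotypes plus a confident-region BED and a
  labelled duplication-partition BED for stratified evaluation.

Variant sites are placed on a spaced grid (>= 8 bp apart) so exact
diffing and VCF normalization are unambiguous. Reads are single-end:
pairing adds no behaviour this caller exercises. Indels are 10% of
simulated variants (length 1-5), mirroring SNP-dominated small variation.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from .alignment_io import (
    AlignedSequence,
    GenomicInterval,
    Reference,
    write_sam,
)
from .panel import HaplotypePanel, _apply_variants
from .variants import VariantKey, normalize_variant

__all__ = [
    "DuplicationBlock",
    "SimulationConfig",
    "TruthSet",
    "SimulationBundle",
    "simulate_panel",
    "simulate_diploid",
    "simulate_reads",
    "simulate_biased_scenario",
    "write_bundle",
    "PRESETS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SLOT = 12  # variant-site grid pitch; guarantees >= 8 bp between variants


@dataclass(frozen=True)
class DuplicationBlock:
    contig: str
    source_start: int
    source_end: int
    dest_start: int
    dest_end: int

    def __post_init__(self) -> None:
        if self.source_end - self.source_start != self.dest_end - self.dest_start:
            raise ValueError("duplication source and destination differ in length")
        if not (
            self.source_end <= self.dest_start or self.dest_end <= self.source_start
        ):
            raise ValueError(
                f"duplication intervals overlap on {self.contig}: "
                f"({self.source_start},{self.source_end}) vs "
                f"({self.dest_start},{self.dest_end})"
            )

    @property
    def intervals(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (
            GenomicInterval(self.contig, self.source_start, self.source_end),
            GenomicInterval(self.contig, self.dest_start, self.dest_end),
        )


@dataclass(frozen=True)
class SimulationConfig:
    contig_lengths: tuple[tuple[str, int], ...] = (
        ("contig1", 500_000),
        ("contig2", 500_000),
    )
    panel_size: int = 20
    panel_mutation_rate: float = 1e-3  # per bp per haplotype
    indel_fraction: float = 0.10
    max_indel_length: int = 5
    private_variant_rate: float = 5e-5  # per bp per sample haplotype
    read_length: int = 100
    coverage: float = 30.0
    base_error_rate: float = 1e-3
    duplications: tuple[DuplicationBlock, ...] = ()
    duplication_identity: float = 0.99
    mismap_probability: float = 0.25
    confident_margin: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.panel_mutation_rate,
            self.private_variant_rate,
            self.base_error_rate,
            self.mismap_probability,
            self.indel_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if not 0.95 <= self.duplication_identity < 1.0:
            raise ValueError("duplication identity must be in [0.95, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.panel_size < 2:
            raise ValueError("panel_size must be >= 2")


def _dup_blocks(lengths: tuple[tuple[str, int], ...], frac_src=(0.20, 0.28), frac_dst=(0.60, 0.68)):
    return tuple(
        DuplicationBlock(
            contig=name,
            source_start=int(frac_src[0] * length),
            source_end=int(frac_src[1] * length),
            dest_start=int(frac_dst[0] * length),
            dest_end=int(frac_dst[1] * length),
        )
        for name, length in lengths
    )


def _preset_small() -> SimulationConfig:
    lengths = (("contig1", 500_000), ("contig2", 500_000))
    return SimulationConfig(
        contig_lengths=lengths,
        duplications=_dup_blocks(lengths),
        coverage=30.0,
        panel_size=20,
        base_error_rate=1e-3,
        mismap_probability=0.25,
    )


def _preset_biased() -> SimulationConfig:
    # a harder regime: half of each contig sits in a near-identical
    # duplication and a third of duplication-origin reads are mismapped
    lengths = (("contig1", 80_000), ("contig2", 80_000))
    return SimulationConfig(
        contig_lengths=lengths,
        duplications=tuple(
            DuplicationBlock(name, 15_000, 35_000, 45_000, 65_000)
            for name, _ in lengths
        ),
        coverage=25.0,
        panel_size=20,
        base_error_rate=1e-3,
        mismap_probability=0.35,
    )


def _preset_tiny() -> SimulationConfig:
    lengths = (("contig1", 30_000),)
    return SimulationConfig(
        contig_lengths=lengths,
        duplications=(DuplicationBlock("contig1", 5_000, 10_000, 18_000, 23_000),),
        coverage=20.0,
        panel_size=8,
        mismap_probability=0.3,
        confident_margin=200,
    )


PRESETS = {
    "small": _preset_small,
    "biased": _preset_biased,
    "tiny": _preset_tiny,
}


@dataclass
class TruthSet:
    """Phased truth genotypes plus the confident regions they are trusted in."""

    records: list[tuple[VariantKey, tuple[int, int]]]
    confident: list[GenomicInterval]

    def alt_counts(self) -> dict[VariantKey, int]:
        return {key: gt[0] + gt[1] for key, gt in self.records}

    def in_confident(self, key: VariantKey) -> bool:
        return any(iv.contains(key[0], key[1]) for iv in self.confident)


@dataclass
class SimulationBundle:
    config: SimulationConfig
    reference: Reference
    panel: HaplotypePanel
    panel_variants: dict[str, list[tuple[int, str, str, tuple[int, ...]]]]
    donors: tuple[int, int]
    sample_haplotypes: list[AlignedSequence]
    truth: TruthSet
    reads: list[AlignedSequence]
    partition: list[tuple[GenomicInterval, str]]
    manifest: dict


# --------------------------------------------------------------------------
# panel


def _random_reference(config: SimulationConfig, rng: np.random.Generator) -> Reference:
    seqs: dict[str, str] = {}
    for name, length in config.contig_lengths:
        arr = _BASES[rng.integers(0, 4, size=length)]
        seqs[name] = arr.tobytes().decode()
    # stamp duplications: destination = mutated copy of source
    for dup in config.duplications:
        seq = np.frombuffer(seqs[dup.contig].encode(), dtype=np.uint8).copy()
        src = seq[dup.source_start : dup.source_end].copy()
        div_rate = 1.0 - config.duplication_identity
        n = len(src)
        mutate = rng.random(n) < div_rate
        shifts = rng.integers(1, 4, size=int(mutate.sum()))
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        codes = np.array([idx[b] for b in src[mutate]])
        src[mutate] = _BASES[(codes + shifts) % 4]
        seq[dup.dest_start : dup.dest_end] = src
        seqs[dup.contig] = seq.tobytes().decode()
    return Reference(seqs)


def _draw_sites(
    length: int,
    n_sites: int,
    rng: np.random.Generator,
    forbidden_slots: Optional[set] = None,
) -> list[int]:
    """Variant positions on a spaced grid (one per slot, >= 8 bp apart)."""
    n_slots = length // _SLOT - 2
    slots = np.arange(1, n_slots + 1)
    if forbidden_slots:
        slots = np.array([s for s in slots if s not in forbidden_slots])
    chosen = rng.choice(slots, size=min(n_sites, len(slots)), replace=False)
    offsets = rng.integers(0, 4, size=len(chosen))
    return sorted(int(s) * _SLOT + int(o) for s, o in zip(chosen, offsets))


def _draw_allele(
    ref_seq: str,
    pos: int,
    rng: np.random.Generator,
    indel_fraction: float,
    max_indel: int,
) -> tuple[str, str]:
    base = ref_seq[pos]
    if rng.random() >= indel_fraction:  # SNP
        others = [b for b in "ACGT" if b != base]
        return base, others[rng.integers(0, 3)]
    length = int(rng.integers(1, max_indel + 1))
    if rng.random() < 0.5:  # insertion
        ins = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
        return base, base + ins
    return base + ref_seq[pos + 1 : pos + 1 + length], base


def simulate_panel(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Reference, HaplotypePanel, dict]:
    """Reference + panel haplotypes + the per-contig panel variant table.

    The variant table maps contig -> list of (pos, ref, alt, carriers),
    carriers being the tuple of haplotype indices carrying the alt. The
    number of carriers of each variant is drawn with P(i) proportional to
    1/i, a neutral-spectrum-like law concentrating mass at low frequency.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    reference = _random_reference(config, rng)
    # carrier-count law
    ks = np.arange(1, config.panel_size + 1)
    pk = (1.0 / ks) / (1.0 / ks).sum()
    mean_carriers = float((ks * pk).sum())

    panel_variants: dict[str, list] = {}
    for name, length in config.contig_lengths:
        ref_seq = reference.sequence(name)
        n_sites = int(
            round(length * config.panel_mutation_rate * config.panel_size / mean_carriers)
        )
        positions = _draw_sites(length, n_sites, rng)
        table = []
        for pos in positions:
            ref, alt = _draw_allele(
                ref_seq, pos, rng, config.indel_fraction, config.max_indel_length
            )
            ncar = int(rng.choice(ks, p=pk))
            carriers = tuple(
                sorted(rng.choice(config.panel_size, size=ncar, replace=False))
            )
            table.append((pos, ref, alt, carriers))
        panel_variants[name] = table

    haplotypes = []
    for hi in range(config.panel_size):
        for name, _ in config.contig_lengths:
            edits = [
                (pos, ref, alt)
                for pos, ref, alt, carriers in panel_variants[name]
                if hi in carriers
            ]
            haplotypes.append(
                _apply_variants(f"panel_hap{hi:03d}", name, edits, reference)
            )
    panel = HaplotypePanel(
        haplotypes=haplotypes,
        haplotype_count=config.panel_size,
        source="synthetic",
    )
    return reference, panel, panel_variants


# --------------------------------------------------------------------------
# diploid sample


def simulate_diploid(
    panel: HaplotypePanel,
    config: SimulationConfig,
    reference: Reference,
    panel_variants: dict,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AlignedSequence], TruthSet, tuple[int, int]]:
    """Two sample haplotypes copied from two panel donors plus private
    variants, with the exact truth derived from the applied edits."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    donors = tuple(
        int(i) for i in rng.choice(config.panel_size, size=2, replace=False)
    )
    sample_haps: list[AlignedSequence] = []
    edits_by_hap: list[dict[str, list]] = []
    for si, donor in enumerate(donors):
        per_contig: dict[str, list] = {}
        for name, length in config.contig_lengths:
            inherited = [
                (pos, ref, alt)
                for pos, ref, alt, carriers in panel_variants[name]
                if donor in carriers
            ]
            used_slots = {
                pos // _SLOT for pos, _, _, _ in panel_variants[name]
            }
            n_priv = int(round(length * config.private_variant_rate))
            priv_pos = _draw_sites(length, n_priv, rng, forbidden_slots=used_slots)
            ref_seq = reference.sequence(name)
            private = [
                (
                    pos,
                    *_draw_allele(
                        ref_seq, pos, rng, config.indel_fraction, config.max_indel_length
                    ),
                )
                for pos in priv_pos
            ]
            edits = sorted(inherited + private)
            per_contig[name] = edits
            sample_haps.append(
                _apply_variants(f"sample_h{si + 1}", name, edits, reference)
            )
        edits_by_hap.append(per_contig)

    # exact truth: normalized keys with phased genotypes
    keys_by_hap = []
    for per_contig in edits_by_hap:
        keys = set()
        for name, edits in per_contig.items():
            for pos, ref, alt in edits:
                keys.add(normalize_variant(name, pos, ref, alt, reference))
        keys_by_hap.append(keys)
    all_keys = sorted(keys_by_hap[0] | keys_by_hap[1])
    records = [
        (key, (int(key in keys_by_hap[0]), int(key in keys_by_hap[1])))
        for key in all_keys
    ]
    confident = [
        GenomicInterval(
            name, config.confident_margin, length - config.confident_margin
        )
        for name, length in config.contig_lengths
    ]
    records = [
        (key, gt)
        for key, gt in records
        if any(iv.contains(key[0], key[1]) for iv in confident)
    ]
    truth = TruthSet(records=records, confident=confident)
    return sample_haps, truth, donors


# --------------------------------------------------------------------------
# reads


def _alignment_segments(hap: AlignedSequence):
    """Flatten a haplotype alignment into (op, ref_pos, hap_pos, len) plus
    an array of cumulative hap-consumed ends for binary search."""
    segs = []
    rpos, qpos = hap.start, 0
    for op, n in hap.cigar:
        segs.append((op, rpos, qpos, n))
        if op in ("M", "I"):
            qpos += n
        if op in ("M", "D"):
            rpos += n
    hap_ends = np.array(
        [s[2] + (s[3] if s[0] in ("M", "I") else 0) for s in segs]
    )
    return segs, hap_ends


def _subalignment(segs, hap_ends, h0: int, rl: int):
    """Reference start + CIGAR of a read copied from hap coords [h0, h0+rl)."""
    i = int(np.searchsorted(hap_ends, h0, side="right"))
    remaining = rl
    ref_start = None
    cigar: list[tuple[str, int]] = []

    def emit(op, n):
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (cigar[-1][0], cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    pos = h0
    while remaining > 0 and i < len(segs):
        op, rseg, hseg, n = segs[i]
        if op == "M":
            off = pos - hseg
            take = min(n - off, remaining)
            if take > 0:
                if ref_start is None:
                    ref_start = rseg + off
                emit("M", take)
                remaining -= take
                pos += take
        elif op == "I":
            off = pos - hseg
            take = min(n - off, remaining)
            if take > 0:
                emit("S" if ref_start is None else "I", take)
                remaining -= take
                pos += take
        elif op == "D":
            if ref_start is not None and remaining > 0:
                emit("D", n)
        i += 1
    # a trailing insertion cannot closes an alignment; soft-clip it
    if cigar and cigar[-1][0] == "I":
        cigar[-1] = ("S", cigar[-1][1])
    if cigar and cigar[-1][0] == "D":
        cigar.pop()
    return ref_start, tuple(cigar)


def simulate_reads(
    sample_haplotypes: Sequence[AlignedSequence],
    reference: Reference,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[AlignedSequence]:
    """Single-end reads drawn uniformly from both sample haplotypes.

    Per-base substitution errors at ``base_error_rate`` (base quality 12 at
    error positions, 35 elsewhere). Reads lying entirely inside one copy of
    a duplication are re-addressed to the homologous copy with probability
    ``mismap_probability`` and mapping quality 2; all other reads sit at
    their true coordinates with mapping quality 60.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    rl = config.read_length
    reads: list[AlignedSequence] = []
    dup_by_contig: dict[str, list[DuplicationBlock]] = {}
    for dup in config.duplications:
        dup_by_contig.setdefault(dup.contig, []).append(dup)

    for hap in sample_haplotypes:
        if rl > len(hap.bases):
            raise ValueError(
                f"read length {rl} exceeds haplotype length {len(hap.bases)}"
            )
        contig = hap.contig
        n_reads = int(round(config.coverage / 2 * len(hap.bases) / rl))
        segs, hap_ends = _alignment_segments(hap)
        starts = rng.integers(0, len(hap.bases) - rl + 1, size=n_reads)
        starts.sort()
        err_mask = rng.random((n_reads, rl), dtype=np.float32) < config.base_error_rate
        strands = rng.random(n_reads) < 0.5
        mismap_roll = rng.random(n_reads)
        err_shift = rng.integers(1, 4, size=max(int(err_mask.sum()), 1))
        base_to_code = {65: 0, 67: 1, 71: 2, 84: 3, 78: 0}
        ei = 0
        for ri in range(n_reads):
            h0 = int(starts[ri])
            ref_start, cigar = _subalignment(segs, hap_ends, h0, rl)
            if ref_start is None or not cigar:
                continue
            seq = bytearray(hap.bases[h0 : h0 + rl].encode())
            quals = np.full(rl, 35, dtype=np.uint8)
            err_pos = np.nonzero(err_mask[ri])[0]
            for p in err_pos:
                code = base_to_code[seq[p]]
                seq[p] = _BASES[(code + err_shift[ei % len(err_shift)]) % 4]
                quals[p] = 12
                ei += 1
            ref_span = sum(n for op, n in cigar if op in ("M", "D"))
            pos, mapq = ref_start, 60
            for dup in dup_by_contig.get(contig, ()):
                src, dst = dup.intervals
                shift = dup.dest_start - dup.source_start
                if src.start <= ref_start and ref_start + ref_span <= src.end:
                    if mismap_roll[ri] < config.mismap_probability:
                        pos, mapq = ref_start + shift, 2
                    break
                if dst.start <= ref_start and ref_start + ref_span <= dst.end:
                    if mismap_roll[ri] < config.mismap_probability:
                        pos, mapq = ref_start - shift, 2
                    break
            reads.append(
                AlignedSequence(
                    name=f"read_{contig}_{hap.name}_{ri:06d}",
                    contig=contig,
                    start=pos,
                    cigar=cigar,
                    bases=seq.decode(),
                    base_qualities=tuple(int(q) for q in quals),
                    mapping_quality=mapq,
                    strand="-" if strands[ri] else "+",
                    origin="read",
                )
            )
    reads.sort(key=lambda r: (r.contig, r.start, r.name))
    return reads


# --------------------------------------------------------------------------
# full scenario


def _partition_from_config(config: SimulationConfig) -> list[tuple[GenomicInterval, str]]:
    """Labelled, non-overlapping region classes: the duplication copies
    (identity >= 99% by default) and the rest of each contig."""
    ident_label = f"SD>={config.duplication_identity:.0%}"
    out: list[tuple[GenomicInterval, str]] = []
    for name, length in config.contig_lengths:
        cuts = []
        for dup in config.duplications:
            if dup.contig == name:
                cuts.extend(dup.intervals)
        cuts.sort(key=lambda iv: iv.start)
        cursor = 0
        for iv in cuts:
            if cursor < iv.start:
                out.append((GenomicInterval(name, cursor, iv.start), "rest"))
            out.append((iv, ident_label))
            cursor = iv.end
        if cursor < length:
            out.append((GenomicInterval(name, cursor, length), "rest"))
    return out


def simulate_biased_scenario(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    preset: str = "biased",
) -> SimulationBundle:
    """Compose panel, diploid sample and reads into a full fixture bundle.

    The scenario is constructed so the haplotype block is informative:
    sample alt alleles exist in the panel at moderate frequency while
    mismapped duplication reads produce alt-looking pileups the panel does
    not support.
    """
    if config is None:
        config = PRESETS[preset]()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    reference, panel, panel_variants = simulate_panel(config)
    sample_haps, truth, donors = simulate_diploid(
        panel, config, reference, panel_variants
    )
    reads = simulate_reads(sample_haps, reference, config)
    manifest = {
        "generator": "pancall.simulate",
        "seed": config.seed,
        "config": _config_to_dict(config),
        "donors": [f"panel_hap{d:03d}" for d in donors],
        "n_reads": len(reads),
        "n_truth_records": len(truth.records),
    }
    return SimulationBundle(
        config=config,
        reference=reference,
        panel=panel,
        panel_variants=panel_variants,
        donors=donors,
        sample_haplotypes=sample_haps,
        truth=truth,
        reads=reads,
        partition=_partition_from_config(config),
        manifest=manifest,
    )


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["contig_lengths"] = [list(t) for t in config.contig_lengths]
    d["duplications"] = [dataclasses.asdict(b) for b in config.duplications]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["contig_lengths"] = tuple(tuple(t) for t in d["contig_lengths"])
    d["duplications"] = tuple(
        DuplicationBlock(**b) for b in d["duplications"]
    )
    return SimulationConfig(**d)


# --------------------------------------------------------------------------
# serialization


def write_truth_vcf(truth: TruthSet, reference: Reference, path: str) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig, length in reference.lengths.items():
        header.contigs.add(contig, length=length)
    header.add_sample("truth")
    order = {name: i for i, name in enumerate(reference.contigs)}
    records = sorted(truth.records, key=lambda r: (order[r[0][0]], r[0][1]))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for (contig, pos, ref, alt), gt in records:
            rec = vcf.new_record(
                contig=contig,
                start=pos,
                stop=pos + len(ref),
                alleles=(ref, alt),
            )
            rec.samples["truth"]["GT"] = gt
            rec.samples["truth"].phased = True
            vcf.write(rec)


def write_panel_vcf(
    panel_variants: dict,
    panel_size: int,
    reference: Reference,
    path: str,
) -> None:
    """Panel variants as a phased multi-sample VCF (haplotypes paired into
    diploid pseudo-samples in panel order)."""
    n_samples = (panel_size + 1) // 2
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig, length in reference.lengths.items():
        header.contigs.add(contig, length=length)
    for si in range(n_samples):
        header.add_sample(f"panel_s{si:03d}")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for contig in reference.contigs:
            for pos, ref, alt, carriers in sorted(panel_variants.get(contig, [])):
                rec = vcf.new_record(
                    contig=contig,
                    start=pos,
                    stop=pos + len(ref),
                    alleles=(ref, alt),
                )
                cset = set(carriers)
                for si in range(n_samples):
                    a, b = 2 * si, min(2 * si + 1, panel_size - 1)
                    rec.samples[f"panel_s{si:03d}"]["GT"] = (
                        int(a in cset),
                        int(b in cset),
                    )
                    rec.samples[f"panel_s{si:03d}"].phased = True
                vcf.write(rec)


def write_bundle(bundle: SimulationBundle, out_dir: str | os.PathLike) -> None:
    """Write the bundle as standard text formats plus a JSON manifest.

    Regenerating with the manifest's seed and config reproduces the bundle.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    ref = bundle.reference
    with open(os.path.join(out, "reference.fa"), "w") as fh:
        for contig in ref.contigs:
            fh.write(f">{contig}\n")
            seq = ref.sequence(contig)
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_sam(os.path.join(out, "panel.sam"), ref, bundle.panel.haplotypes)
    write_panel_vcf(
        bundle.panel_variants,
        bundle.config.panel_size,
        ref,
        os.path.join(out, "panel.vcf"),
    )
    write_sam(os.path.join(out, "reads.sam"), ref, bundle.reads)
    _write_fastq(os.path.join(out, "reads.fastq"), bundle.reads)
    write_truth_vcf(bundle.truth, ref, os.path.join(out, "truth.vcf"))
    with open(os.path.join(out, "confident.bed"), "w") as fh:
        for iv in bundle.truth.confident:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
    with open(os.path.join(out, "partition.bed"), "w") as fh:
        for iv, label in bundle.partition:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{label}\n")
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _write_fastq(path: str, reads: Sequence[AlignedSequence]) -> None:
    """FASTQ mirror of the reads (reverse-strand reads are written 5'->3',
    i.e. reverse-complemented relative to their SAM representation)."""
    with open(path, "w") as fh:
        for read in reads:
            seq = read.bases
            quals = "".join(chr(q + 33) for q in (read.base_qualities or ()))
            if read.strand == "-":
                seq = seq.encode().translate(_COMP)[::-1].decode()
                quals = quals[::-1]
            fh.write(f"@{read.name}\n{seq}\n+\n{quals}\n")
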