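"""Pangenome haplotype panel: reference-aligned haplotypes and their allele
frequencies.

The pangenome is represented here in its flattened form — one aligned
sequence per panel haplotype per covered region — loadable either from
haplotype-contig alignments (SAM/BAM) or by reconstructing haplotypes from
a phased multi-sample VCF. Panel allele frequency of a variant key is the
fraction of panel haplotypes whose alignment asserts exactly that allele.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from cyvcf2 import VCF

from .alignment_io import (
    AlignedSequence,
    GenomicInterval,
    Reference,
    load_alignments,
)
from .variants import VariantKey, normalize_variant

__all__ = [
    "HaplotypePanel",
    "PanelAlleleFrequency",
    "load_panel_from_alignments",
    "panel_from_phased_vcf",
    "panel_allele_frequency",
    "haplotype_variant_keys",
]


@dataclass(frozen=True)
class PanelAlleleFrequency:
    key: VariantKey
    carriers: int
    haplotype_count: int

    @property
    def frequency(self) -> float:
        return self.carriers / self.haplotype_count


@dataclass
class HaplotypePanel:
    """Ordered set of reference-aligned haplotypes.

    Ordering is the file/reconstruction order and is stable: it determines
    pileup row assignment. ``haplotype_count`` is the declared panel size,
    which may exceed the number of records overlapping a queried region.
    """

    haplotypes: list[AlignedSequence]
    haplotype_count: int
    source: str  # "alignments" | "phased_vcf" | "synthetic" | "personalized"
    _variant_cache: Optional[dict] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.haplotype_count < 1:
            raise ValueError("haplotype_count must be >= 1")
        for hap in self.haplotypes:
            if hap.origin != "haplotype":
                raise ValueError(
                    f"panel record {hap.name!r} has origin {hap.origin!r}"
                )

    def overlapping(self, interval: GenomicInterval) -> list[AlignedSequence]:
        return [h for h in self.haplotypes if h.overlaps(interval)]

    def variant_carriers(self, reference: Reference) -> dict[VariantKey, int]:
        """Normalized variant key -> number of carrying haplotypes (cached)."""
        if self._variant_cache is None:
            counts: dict[VariantKey, int] = {}
            for hap in self.haplotypes:
                for key in haplotype_variant_keys(hap, reference):
                    counts[key] = counts.get(key, 0) + 1
            self._variant_cache = counts
        return self._variant_cache


def haplotype_variant_keys(
    hap: AlignedSequence, reference: Reference
) -> list[VariantKey]:
    """Diff one reference-aligned haplotype against the reference.

    Walks the CIGAR: M-segment mismatches become SNPs, I/D become anchored
    indels; every allele is normalized before being returned.
    """
    keys: list[VariantKey] = []
    ref_seq = reference.sequence(hap.contig)
    rpos, qpos = hap.start, 0
    for op, n in hap.cigar:
        if op == "M":
            seg = hap.bases[qpos : qpos + n]
            ref_seg = ref_seq[rpos : rpos + n]
            for i in range(n):
                if seg[i] != ref_seg[i] and seg[i] != "N" and ref_seg[i] != "N":
                    keys.append(
                        normalize_variant(
                            hap.contig, rpos + i, ref_seg[i], seg[i], reference
                        )
                    )
            rpos += n
            qpos += n
        elif op == "I":
            anchor = rpos - 1
            if anchor >= 0:
                base = ref_seq[anchor]
                keys.append(
                    normalize_variant(
                        hap.contig,
                        anchor,
                        base,
                        base + hap.bases[qpos : qpos + n],
                        reference,
                    )
                )
            qpos += n
        elif op == "D":
            anchor = rpos - 1
            if anchor >= 0:
                base = ref_seq[anchor]
                keys.append(
                    normalize_variant(
                        hap.contig,
                        anchor,
                        base + ref_seq[rpos : rpos + n],
                        base,
                        reference,
                    )
                )
            rpos += n
        elif op == "S":
            qpos += n
    return keys


def load_panel_from_alignments(
    path: str | os.PathLike,
    region: Optional[GenomicInterval] = None,
    reference: Optional[Reference] = None,
    haplotype_count: Optional[int] = None,
) -> HaplotypePanel:
    """Load a panel from haplotype-to-reference alignments.

    Each record becomes one panel haplotype (per covered region). The
    reference the haplotypes were aligned to must contain every contig the
    alignments name — the pangenome must include the linear reference.
    """
    records = load_alignments(path, region=region, origin="haplotype")
    if reference is not None:
        for rec in records:
            if rec.contig not in reference:
                raise ValueError(
                    f"haplotype {rec.name!r} aligned to contig "
                    f"{rec.contig!r} absent from the reference; the panel "
                    "must be aligned to the same linear reference as the reads"
                )
    if haplotype_count is None:
        names = {rec.name for rec in records}
        haplotype_count = max(len(names), 1)
    return HaplotypePanel(
        haplotypes=records, haplotype_count=haplotype_count, source="alignments"
    )


def panel_from_phased_vcf(
    vcf_path: str | os.PathLike,
    reference: Reference,
    region: Optional[GenomicInterval] = None,
) -> HaplotypePanel:
    """Reconstruct panel haplotypes from a phased multi-sample VCF.

    Each diploid sample contributes two haplotypes: the reference sequence
    with that haplotype's alleles applied, with the alignment CIGAR built
    directly from the applied variants (no realignment).
    """
    vcf = VCF(os.fspath(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: VCF has no samples")
    contigs = (
        [region.contig]
        if region is not None
        else [c for c in reference.contigs]
    )
    # per (sample, hap_index, contig): list of (pos, ref, alt)
    edits: dict[tuple[int, int, str], list[tuple[int, str, str]]] = {}
    reg = (
        f"{region.contig}:{region.start + 1}-{region.end}"
        if region is not None
        else None
    )
    for rec in vcf(reg) if reg else vcf:
        if rec.CHROM not in reference.contigs:
            raise ValueError(
                f"VCF record at {rec.CHROM}:{rec.POS} names a contig absent "
                "from the reference"
            )
        if len(rec.ALT) != 1:
            raise ValueError(
                f"VCF record at {rec.CHROM}:{rec.POS} is multiallelic; split "
                "records before building a panel"
            )
        for si, gt in enumerate(rec.genotypes):
            *alleles, phased = gt
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype at {rec.CHROM}:{rec.POS} "
                    f"sample {samples[si]}"
                )
            if not phased and alleles[0] != alleles[1]:
                raise ValueError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} "
                    f"sample {samples[si]}"
                )
            for hi, allele in enumerate(alleles):
                if allele == 1:
                    edits.setdefault((si, hi, rec.CHROM), []).append(
                        (rec.POS - 1, rec.REF.upper(), rec.ALT[0].upper())
                    )
    haplotypes: list[AlignedSequence] = []
    for si, sample in enumerate(samples):
        for hi in (0, 1):
            for contig in contigs:
                variants = sorted(edits.get((si, hi, contig), []))
                haplotypes.append(
                    _apply_variants(
                        f"{sample}_h{hi + 1}", contig, variants, reference
                    )
                )
    return HaplotypePanel(
        haplotypes=haplotypes,
        haplotype_count=2 * len(samples),
        source="phased_vcf",
    )


def _apply_variants(
    name: str,
    contig: str,
    variants: list[tuple[int, str, str]],
    reference: Reference,
) -> AlignedSequence:
    """Apply non-overlapping (pos, ref, alt) edits to the reference and
    build the corresponding aligned haplotype record."""
    ref_seq = reference.sequence(contig)
    pieces: list[str] = []
    cigar: list[tuple[str, int]] = []

    def _emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    cursor = 0
    for pos, ref, alt in variants:
        if pos < cursor:
            raise ValueError(
                f"overlapping variants on haplotype {name!r} at "
                f"{contig}:{pos} (previous edit extends to {cursor})"
            )
        if ref_seq[pos : pos + len(ref)] != ref:
            raise ValueError(
                f"variant REF mismatch at {contig}:{pos}: expected {ref!r}, "
                f"reference has {ref_seq[pos:pos + len(ref)]!r}"
            )
        pieces.append(ref_seq[cursor:pos])
        _emit("M", pos - cursor)
        if len(ref) == len(alt):  # SNP / MNP: aligned substitution
            pieces.append(alt)
            _emit("M", len(alt))
        elif len(ref) < len(alt):  # insertion (anchored)
            pieces.append(alt)
            _emit("M", len(ref))
            _emit("I", len(alt) - len(ref))
        else:  # deletion (anchored)
            pieces.append(alt)
            _emit("M", len(alt))
            _emit("D", len(ref) - len(alt))
        cursor = pos + len(ref)
    pieces.append(ref_seq[cursor:])
    _emit("M", len(ref_seq) - cursor)
    return AlignedSequence(
        name=name,
        contig=contig,
        start=0,
        cigar=tuple(cigar),
        bases="".join(pieces),
        origin="haplotype",
    )


def panel_allele_frequency(
    panel: HaplotypePanel,
    key: VariantKey,
    reference: Reference,
) -> PanelAlleleFrequency:
    """Fraction of panel haplotypes carrying exactly this normalized allele.

    An allele absent from the panel has frequency 0.
    """
    if not panel.haplotypes:
        raise ValueError("panel has no haplotype records")
    key = normalize_variant(key[0], key[1], key[2], key[3], reference)
    carriers = panel.variant_carriers(reference).get(key, 0)
    return PanelAlleleFrequency(
        key=key, carriers=carriers, haplotype_count=panel.haplotype_count
    )
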