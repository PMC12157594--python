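"""Pangenome-augmented pileup tensors.

For each candidate variant a fixed-width window (221 columns by default)
is centered on the candidate position. The tensor stacks two blocks of
equal height: the pangenome-haplotype block on top and the read block
below it, for a total height of 2 x 100 by default. Six channels encode,
per row and reference column: the aligned base, base quality, mapping
quality, strand, whether the row's sequence supports the candidate alt,
and whether it differs from the reference. Quality and strand channels
are left blank (zero) for pangenome haplotypes, which carry neither.

Insertions are anchored at their preceding reference column (the window
is in reference coordinates, so columns are never expanded); deletions
render as a gap symbol in the base channel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment_io import AlignedSequence, GenomicInterval, Reference
from .candidates import CandidateVariant
from .panel import HaplotypePanel
from .variants import VariantKey, normalize_variant

__all__ = [
    "CHANNELS",
    "PileupConfig",
    "PileupExample",
    "candidate_window",
    "encode_rows",
    "build_example",
    "label_example",
    "truth_index",
    "save_examples",
    "load_examples",
]

CHANNELS = (
    "BASE",
    "BASE_QUAL",
    "MAP_QUAL",
    "STRAND",
    "SUPPORTS_ALT",
    "DIFFERS_FROM_REF",
)

LABEL_REF, LABEL_HET, LABEL_HOM_ALT = 0, 1, 2

# base channel encodings; everything is bounded in [0, 1]
_BASE_CODE = {"A": 0.25, "C": 0.50, "G": 0.75, "T": 1.00, "N": 0.05}
_BASE_LUT = np.full(256, _BASE_CODE["N"], dtype=np.float32)
for _b, _v in _BASE_CODE.items():
    _BASE_LUT[ord(_b)] = _v
_GAP_CODE = 0.10
_SUPPORT_ALT, _SUPPORT_REF, _SUPPORT_OTHER = 1.0, 0.5, 0.25
_DIFF_YES, _DIFF_NO = 1.0, 0.3


@dataclass(frozen=True)
class PileupConfig:
    width: int = 221
    height_per_block: int = 100
    channels: tuple[str, ...] = CHANNELS
    haplotype_blank_channels: tuple[str, ...] = (
        "BASE_QUAL",
        "MAP_QUAL",
        "STRAND",
    )
    haplotypes_on_top: bool = True
    haplotype_overflow: str = "error"  # "error" | "subsample"
    row_overflow_seed: int = 0
    max_base_quality: int = 40
    max_mapping_quality: int = 60

    def __post_init__(self) -> None:
        if self.width % 2 != 1:
            raise ValueError("pileup width must be odd (unique center column)")
        if self.height_per_block < 1:
            raise ValueError("height_per_block must be >= 1")
        if not set(self.haplotype_blank_channels) <= set(self.channels):
            raise ValueError("haplotype_blank_channels must be channels")

    @property
    def center(self) -> int:
        return (self.width - 1) // 2


@dataclass
class PileupExample:
    tensor: np.ndarray  # (2*height, width, n_channels) float16 in [0,1]
    candidate: CandidateVariant
    window: GenomicInterval
    label: Optional[int] = None  # 0=REF 1=HET 2=HOM_ALT

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape


def candidate_window(
    candidate: CandidateVariant, config: PileupConfig = PileupConfig()
) -> GenomicInterval:
    """Window of ``width`` columns with the candidate at the center column.

    Near contig edges the window may extend out of bounds; out-of-bounds
    columns are simply left blank by the encoder, so the interval here is
    not clipped (start may be negative conceptually; we clamp at 0 for the
    interval object and remember the offset via the center invariant).
    """
    start = candidate.pos - config.center
    end = start + config.width
    return GenomicInterval(candidate.contig, max(start, 0), end)


def _window_bounds(
    candidate: CandidateVariant, config: PileupConfig
) -> tuple[int, int]:
    start = candidate.pos - config.center
    return start, start + config.width


def _segments(seq: AlignedSequence) -> tuple[list, np.ndarray]:
    """Cached flattened CIGAR: [(op, ref_pos, query_pos, len)] plus an array
    of per-segment reference end positions for binary search."""
    cached = getattr(seq, "_pileup_segments", None)
    if cached is not None:
        return cached
    segs = []
    rpos, qpos = seq.start, 0
    for op, n in seq.cigar:
        segs.append((op, rpos, qpos, n))
        if op in ("M", "I", "S"):
            qpos += n
        if op in ("M", "D"):
            rpos += n
    ref_ends = np.array(
        [r + (n if op in ("M", "D") else 0) for op, r, q, n in segs]
    )
    cached = (segs, ref_ends)
    object.__setattr__(seq, "_pileup_segments", cached)
    return cached


# how far right of the (left-aligned) candidate anchor a raw CIGAR indel
# may sit and still represent the same normalized event
_INDEL_SHIFT_WINDOW = 64


def _sequence_allele(
    seq: AlignedSequence, candidate: CandidateVariant, reference: Reference
) -> Optional[str]:
    """Which allele does this alignment assert at the candidate site?

    Returns "alt", "ref", "other" or None when the alignment does not
    cover the site. Indel events found in the CIGAR are normalized
    (left-aligned) before being compared with the candidate key, since a
    raw alignment may place the same indel anywhere in a repeat run.
    """
    pos = candidate.pos
    covered = False
    asserted: Optional[str] = None  # base aligned at pos; None if deleted
    indel_keys: list[VariantKey] = []
    hi_bound = pos + (
        1 if candidate.kind == "SNP" else _INDEL_SHIFT_WINDOW
    )
    segs, ref_ends = _segments(seq)
    i = int(np.searchsorted(ref_ends, pos, side="right"))
    contig_seq = reference.sequence(seq.contig) if candidate.kind != "SNP" else ""
    while i < len(segs):
        op, rpos, qpos, n = segs[i]
        if rpos > hi_bound:
            break
        if op == "M":
            if rpos <= pos < rpos + n:
                covered = True
                asserted = seq.bases[qpos + (pos - rpos)]
        elif op == "I":
            anchor = rpos - 1
            if candidate.kind != "SNP" and pos - 1 <= anchor <= hi_bound and anchor >= 0:
                indel_keys.append(
                    normalize_variant(
                        seq.contig,
                        anchor,
                        contig_seq[anchor],
                        contig_seq[anchor] + seq.bases[qpos : qpos + n],
                        reference,
                    )
                )
            elif candidate.kind == "SNP" and anchor == pos:
                indel_keys.append(("", -1, "", ""))  # any indel at the site
        elif op == "D":
            if rpos <= pos < rpos + n:
                covered = True
                asserted = None  # site deleted in this sequence
            anchor = rpos - 1
            if candidate.kind != "SNP" and pos - 1 <= anchor <= hi_bound and anchor >= 0:
                indel_keys.append(
                    normalize_variant(
                        seq.contig,
                        anchor,
                        contig_seq[anchor] + contig_seq[rpos : rpos + n],
                        contig_seq[anchor],
                        reference,
                    )
                )
            elif candidate.kind == "SNP" and anchor == pos:
                indel_keys.append(("", -1, "", ""))
        i += 1
    if not covered and not indel_keys:
        return None

    if candidate.kind == "SNP":
        if indel_keys or asserted is None:
            return "other"
        if asserted == candidate.alt_allele:
            return "alt"
        return "ref" if asserted == candidate.ref_allele else "other"
    if candidate.key in indel_keys:
        return "alt"
    if not indel_keys and asserted == candidate.ref_allele[0]:
        return "ref"
    return "other"


_SUPPORT_CODE = {"alt": _SUPPORT_ALT, "ref": _SUPPORT_REF, "other": _SUPPORT_OTHER}


def _encode_one_row(
    seq: AlignedSequence,
    win_start: int,
    candidate: CandidateVariant,
    config: PileupConfig,
    reference: Reference,
    ref_codes: np.ndarray,
    row: np.ndarray,
) -> None:
    """Fill one (width, n_channels) row in place."""
    width = config.width
    support = _SUPPORT_CODE.get(
        _sequence_allele(seq, candidate, reference) or "", 0.0
    )
    mapq = (
        min(seq.mapping_quality, config.max_mapping_quality)
        / config.max_mapping_quality
        if seq.mapping_quality is not None
        else 0.0
    )
    strand = {"+": 0.5, "-": 1.0}.get(seq.strand or "", 0.0)

    segs, ref_ends = _segments(seq)
    i = int(np.searchsorted(ref_ends, win_start, side="right"))
    while i < len(segs):
        op, rpos, qpos, n = segs[i]
        i += 1
        if rpos >= win_start + width:
            break
        if op == "M":
            lo = max(rpos, win_start)
            hi = min(rpos + n, win_start + width)
            if lo < hi:
                cols = slice(lo - win_start, hi - win_start)
                q0 = qpos + (lo - rpos)
                frag = seq.bases[q0 : q0 + (hi - lo)]
                codes = _BASE_LUT[np.frombuffer(frag.encode(), dtype=np.uint8)]
                row[cols, 0] = codes
                if seq.base_qualities is not None:
                    q = np.minimum(
                        np.asarray(
                            seq.base_qualities[q0 : q0 + (hi - lo)],
                            dtype=np.float32,
                        ),
                        config.max_base_quality,
                    )
                    row[cols, 1] = q / config.max_base_quality
                row[cols, 2] = mapq
                row[cols, 3] = strand
                row[cols, 4] = support
                row[cols, 5] = np.where(
                    codes == ref_codes[cols], _DIFF_NO, _DIFF_YES
                )
        elif op == "I":
            anchor = rpos - 1
            if win_start <= anchor < win_start + width:
                row[anchor - win_start, 5] = _DIFF_YES
        elif op == "D":
            lo = max(rpos, win_start)
            hi = min(rpos + n, win_start + width)
            if lo < hi:
                cols = slice(lo - win_start, hi - win_start)
                row[cols, 0] = _GAP_CODE
                row[cols, 2] = mapq
                row[cols, 3] = strand
                row[cols, 4] = support
                row[cols, 5] = _DIFF_YES


def _reference_codes(
    candidate: CandidateVariant, config: PileupConfig, reference: Reference
) -> np.ndarray:
    win_start, win_end = _window_bounds(candidate, config)
    contig_len = reference.lengths[candidate.contig]
    ref_codes = np.zeros(config.width, dtype=np.float32)
    lo = max(win_start, 0)
    hi = min(win_end, contig_len)
    if lo < hi:
        frag = reference.fetch(candidate.contig, lo, hi)
        ref_codes[lo - win_start : hi - win_start] = _BASE_LUT[
            np.frombuffer(frag.encode(), dtype=np.uint8)
        ]
    return ref_codes


def encode_rows(
    sequences: Sequence[AlignedSequence],
    window: GenomicInterval,
    candidate: CandidateVariant,
    config: PileupConfig,
    reference: Reference,
) -> np.ndarray:
    """Encode one block: one row per sequence, shape (len(sequences), width, C).

    ``window`` must be the candidate window; columns map to reference
    positions ``candidate.pos - center .. + center``. Columns a sequence
    does not cover are all-zero. For origin=haplotype rows the configured
    blank channels are zeroed.
    """
    win_start, _ = _window_bounds(candidate, config)
    ref_codes = _reference_codes(candidate, config, reference)
    block = np.zeros(
        (len(sequences), config.width, len(config.channels)), dtype=np.float32
    )
    blank_idx = [
        config.channels.index(c) for c in config.haplotype_blank_channels
    ]
    for i, seq in enumerate(sequences):
        _encode_one_row(
            seq, win_start, candidate, config, reference, ref_codes, block[i]
        )
        if seq.origin == "haplotype":
            block[i][:, blank_idx] = 0.0
    return block


def build_example(
    candidate: CandidateVariant,
    reads: Sequence[AlignedSequence],
    panel: Optional[HaplotypePanel],
    reference: Reference,
    config: PileupConfig = PileupConfig(),
    label: Optional[int] = None,
) -> PileupExample:
    """Assemble the full two-block tensor for one candidate.

    Haplotype rows keep panel order; reads are sorted by (start, name) so
    the tensor is invariant to input read order. If more reads overlap the
    window than the block height, a seeded uniform subsample of exactly
    ``height_per_block`` reads is taken (deterministic per candidate).
    A panel larger than the block height is an error by default — the
    remedy is haplotype sampling to a personalized panel — or a seeded
    subsample when ``haplotype_overflow="subsample"``.
    """
    window = candidate_window(candidate, config)
    h = config.height_per_block

    haps = panel.overlapping(window) if panel is not None else []
    if len(haps) > h:
        if config.haplotype_overflow == "error":
            raise ValueError(
                f"panel has {len(haps)} haplotypes overlapping the window "
                f"but the haplotype block height is {h}; sample the panel "
                "to a personalized subset (haplotype sampling) or set "
                'haplotype_overflow="subsample"'
            )
        rng = np.random.default_rng(
            [config.row_overflow_seed, candidate.pos % (2**31), 1]
        )
        idx = np.sort(rng.choice(len(haps), size=h, replace=False))
        haps = [haps[i] for i in idx]

    overlapping = [r for r in reads if r.overlaps(window)]
    overlapping.sort(key=lambda r: (r.start, r.name))
    if len(overlapping) > h:
        rng = np.random.default_rng(
            [config.row_overflow_seed, candidate.pos % (2**31), 0]
        )
        idx = np.sort(rng.choice(len(overlapping), size=h, replace=False))
        overlapping = [overlapping[i] for i in idx]

    # float16 storage: the encodings are coarse by design, and example sets
    # at scale dominate memory; training casts per batch to float32
    tensor = np.zeros(
        (2 * h, config.width, len(config.channels)), dtype=np.float16
    )
    hap_block = tensor[:h] if config.haplotypes_on_top else tensor[h:]
    read_block = tensor[h:] if config.haplotypes_on_top else tensor[:h]
    win_start, _ = _window_bounds(candidate, config)
    ref_codes = _reference_codes(candidate, config, reference)
    blank_idx = [
        config.channels.index(c) for c in config.haplotype_blank_channels
    ]
    for i, seq in enumerate(haps):
        _encode_one_row(
            seq, win_start, candidate, config, reference, ref_codes, hap_block[i]
        )
        hap_block[i][:, blank_idx] = 0.0
    for i, seq in enumerate(overlapping):
        _encode_one_row(
            seq, win_start, candidate, config, reference, ref_codes, read_block[i]
        )
    return PileupExample(
        tensor=tensor, candidate=candidate, window=window, label=label
    )


def truth_index(
    truth_records: Iterable[tuple[VariantKey, int]],
) -> dict[VariantKey, int]:
    """Build a lookup from normalized variant key to alt-allele count (1/2)."""
    return {key: alt_count for key, alt_count in truth_records}


def label_example(
    candidate: CandidateVariant,
    truth: dict[VariantKey, int],
) -> int:
    """Label a candidate against a truth lookup normalized the same way.

    HET if the truth genotype carries the alt once, HOM_ALT if twice, REF
    if the candidate matches no truth allele.
    """
    alt_count = truth.get(candidate.key, 0)
    if alt_count == 1:
        return LABEL_HET
    if alt_count == 2:
        return LABEL_HOM_ALT
    return LABEL_REF


def save_examples(path: str | os.PathLike, examples: Sequence[PileupExample]) -> None:
    """Serialize examples: float32 tensors in an .npz plus a JSON sidecar
    describing shape, channels and per-example candidate metadata."""
    path = os.fspath(path)
    tensors = {f"tensor_{i}": ex.tensor for i, ex in enumerate(examples)}
    np.savez_compressed(path, **tensors)
    meta = {
        "n_examples": len(examples),
        "channels": list(CHANNELS),
        "shape": list(examples[0].tensor.shape) if examples else None,
        "examples": [
            {
                "contig": ex.candidate.contig,
                "pos": ex.candidate.pos,
                "ref": ex.candidate.ref_allele,
                "alt": ex.candidate.alt_allele,
                "support": ex.candidate.alt_support,
                "depth": ex.candidate.total_depth,
                "kind": ex.candidate.kind,
                "window": [ex.window.contig, ex.window.start, ex.window.end],
                "label": ex.label,
            }
            for ex in examples
        ],
    }
    sidecar = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)


def load_examples(path: str | os.PathLike) -> list[PileupExample]:
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    sidecar = path[:-4] + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = np.load(path)
    out = []
    for i, m in enumerate(meta["examples"]):
        cand = CandidateVariant(
            contig=m["contig"],
            pos=m["pos"],
            ref_allele=m["ref"],
            alt_allele=m["alt"],
            alt_support=m["support"],
            total_depth=m["depth"],
            kind=m["kind"],
        )
        out.append(
            PileupExample(
                tensor=data[f"tensor_{i}"],
                candidate=cand,
                window=GenomicInterval(*m["window"]),
                label=m["label"],
            )
        )
    return out
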