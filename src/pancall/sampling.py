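"""Personalized panels by k-mer similarity (haplotype sampling).

Sample reads are reduced to a set of canonical k-mers (k=29 by default;
a k-mer and its reverse complement are one member, since reads are
unstranded; k-mers seen fewer than ``min_count`` times are dropped to
suppress sequencing-error k-mers). Each panel haplotype is split into
non-overlapping segments (10 kb by default; the last segment is shorter)
and each segment is scored by the containment fraction

    score = |{canonical k-mers of the segment} ∩ read k-mers|
            / |{canonical k-mers of the segment}|

The segmentation lets similarity vary along a haplotype, approximating
recombination between segments (not within one). A haplotype's aggregate
score is the mean of its segment scores, and the top-N haplotypes form
the personalized panel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .alignment_io import AlignedSequence, GenomicInterval
from .panel import HaplotypePanel

__all__ = [
    "KmerSet",
    "SegmentScore",
    "count_read_kmers",
    "score_haplotype_segments",
    "select_haplotypes",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lowercase


@dataclass(frozen=True)
class KmerSet:
    k: int
    kmers: np.ndarray  # sorted unique canonical codes, uint64
    source_read_count: int

    def __contains__(self, code: int) -> bool:
        i = np.searchsorted(self.kmers, code)
        return bool(i < len(self.kmers) and self.kmers[i] == code)

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass(frozen=True)
class SegmentScore:
    haplotype: str  # haplotype record name
    haplotype_index: int  # position in panel order
    segment: GenomicInterval  # haplotype-local coordinates (contig = name)
    score: float


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """All canonical k-mer codes of a sequence (k-mers with N dropped)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = arr != 255
    # forward codes via sliding dot with powers of 4
    idx = np.arange(n)[:, None] + np.arange(k)[None, :]
    windows = arr[idx].astype(np.uint64)
    ok = valid[idx].all(axis=1)
    weights_f = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(
        np.uint64
    )
    fwd = (windows * weights_f).sum(axis=1)
    # reverse complement: complement base = 3 - code, reversed order
    weights_r = (4 ** np.arange(k, dtype=np.uint64)).astype(np.uint64)
    rev = ((3 - windows) * weights_r).sum(axis=1)
    canon = np.minimum(fwd, rev)
    return canon[ok]


def count_read_kmers(
    reads: Union[str, os.PathLike, Sequence[Union[str, AlignedSequence]]],
    k: int = 29,
    min_count: int = 2,
) -> KmerSet:
    """Canonical k-mers occurring at least ``min_count`` times in the reads.

    ``reads`` may be a FASTQ path or a sequence of read strings /
    AlignedSequences.
    """
    if k % 2 == 0 or k < 11:
        raise ValueError("k must be odd and >= 11")
    if isinstance(reads, (str, os.PathLike)):
        seqs = list(_read_fastq(os.fspath(reads)))
    else:
        seqs = [r.bases if isinstance(r, AlignedSequence) else r for r in reads]
    if not seqs:
        raise ValueError("no reads provided")
    max_len = max(len(s) for s in seqs)
    if k > max_len:
        raise ValueError(f"k={k} exceeds the longest read length ({max_len})")
    chunks = [_kmer_codes(s, k) for s in seqs]
    allk = (
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    )
    uniq, counts = np.unique(allk, return_counts=True)
    return KmerSet(
        k=k, kmers=uniq[counts >= min_count], source_read_count=len(seqs)
    )


def _read_fastq(path: str) -> Iterable[str]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # qualities
            yield seq


def score_haplotype_segments(
    panel: HaplotypePanel,
    kmers: KmerSet,
    segment_size: int = 10_000,
) -> list[SegmentScore]:
    """Containment score of every haplotype segment against the read k-mers.

    Segments tile each haplotype's own sequence without overlap; a segment
    with no valid k-mers scores 0.
    """
    if segment_size < kmers.k:
        raise ValueError(
            f"segment_size {segment_size} is smaller than k={kmers.k}"
        )
    scores: list[SegmentScore] = []
    for hi, hap in enumerate(panel.haplotypes):
        seq = hap.bases
        # tile the haplotype; a trailing stub shorter than k carries no
        # k-mers of its own and is merged into the previous segment
        bounds = list(range(0, len(seq), segment_size)) + [len(seq)]
        if len(bounds) > 2 and bounds[-1] - bounds[-2] < kmers.k:
            del bounds[-2]
        for start, end in zip(bounds[:-1], bounds[1:]):
            # extend by k-1 so boundary-spanning k-mers belong to the left segment
            seg_kmers = np.unique(
                _kmer_codes(seq[start : min(end + kmers.k - 1, len(seq))], kmers.k)
            )
            if len(seg_kmers) == 0 or len(kmers.kmers) == 0:
                score = 0.0
            else:
                pos = np.searchsorted(kmers.kmers, seg_kmers)
                inb = pos < len(kmers.kmers)
                hits = int((kmers.kmers[pos[inb]] == seg_kmers[inb]).sum())
                score = hits / len(seg_kmers)
            scores.append(
                SegmentScore(
                    haplotype=hap.name,
                    haplotype_index=hi,
                    segment=GenomicInterval(hap.name, start, end),
                    score=score,
                )
            )
    return scores


def select_haplotypes(
    scores: Sequence[SegmentScore],
    panel: HaplotypePanel,
    n: int,
) -> HaplotypePanel:
    """Top-``n`` haplotypes by mean segment score (ties: panel order).

    Supported preset sizes in the calling pipeline are 16, 32 and 64, but
    any 1 <= n <= panel size works.
    """
    if not 1 <= n <= panel.haplotype_count:
        raise ValueError(
            f"n={n} out of range for a panel of {panel.haplotype_count}"
        )
    # aggregate by haplotype name: a haplotype contributes one record per
    # contig, and its score is the mean over all its segments
    order: dict[str, int] = {}
    by_name: dict[str, list[float]] = {}
    for s in scores:
        if s.haplotype not in order:
            order[s.haplotype] = s.haplotype_index
        by_name.setdefault(s.haplotype, []).append(s.score)
    ranked = sorted(
        by_name, key=lambda name: (-float(np.mean(by_name[name])), order[name])
    )
    chosen = set(ranked[:n])
    return HaplotypePanel(
        haplotypes=[h for h in panel.haplotypes if h.name in chosen],
        haplotype_count=n,
        source="personalized",
    )
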