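"""Candidate small-variant discovery from read pileups.

A candidate is emitted at every (position, alt allele) where at least
``min_support`` reads (default 2) assert the same mismatch or indel.
Indels are anchored at the preceding reference base and left-aligned, so
candidates already use the VCF allele convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alignment_io import AlignedSequence, GenomicInterval, Reference
from .variants import VariantKey, normalize_variant, variant_kind

__all__ = ["CandidateVariant", "DiscoveryConfig", "discover_candidates"]


@dataclass(frozen=True)
class CandidateVariant:
    contig: str
    pos: int  # 0-based, normalized
    ref_allele: str
    alt_allele: str
    alt_support: int
    total_depth: int
    kind: str  # SNP | insertion | deletion

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds for candidate generation.

    ``min_support`` is the core rule: a site needs at least this many reads
    asserting the same alternate allele. ``min_fraction`` (off by default)
    additionally requires support >= fraction * depth — a guard against
    pure-count thresholds exploding at very high depth. ``max_alts_per_site``
    keeps the genotype label space biallelic.
    """

    min_support: int = 2
    min_fraction: float = 0.0
    max_alts_per_site: int = 1
    min_base_quality: int = 0

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.max_alts_per_site < 1:
            raise ValueError("max_alts_per_site must be >= 1")


def discover_candidates(
    reads: Iterable[AlignedSequence],
    reference: Reference,
    region: GenomicInterval,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[CandidateVariant]:
    """Scan read alignments over ``region`` and emit supported candidates.

    Depth at a column counts reads whose alignment spans it with an aligned
    base or a deletion. Soft-clipped bases assert no reference position and
    never generate candidates; N bases (read or reference) are skipped.
    Output is position-sorted and deterministic.
    """
    ref_bytes = np.frombuffer(
        reference.fetch_interval(region).encode(), dtype=np.uint8
    )
    rlen = len(region)
    depth_diff = np.zeros(rlen + 1, dtype=np.int32)
    support: dict[VariantKey, int] = {}
    n_byte = ord("N")

    for read in reads:
        if not read.overlaps(region):
            continue
        rpos, qpos = read.start, 0
        read_bytes = np.frombuffer(read.bases.encode(), dtype=np.uint8)
        quals = read.base_qualities
        for op, n in read.cigar:
            if op == "M":
                lo = max(rpos, region.start)
                hi = min(rpos + n, region.end)
                if lo < hi:
                    depth_diff[lo - region.start] += 1
                    depth_diff[hi - region.start] -= 1
                    q0 = qpos + (lo - rpos)
                    seg = read_bytes[q0 : q0 + (hi - lo)]
                    ref_seg = ref_bytes[lo - region.start : hi - region.start]
                    mism = np.nonzero(seg != ref_seg)[0]
                    for i in mism:
                        b, rb = seg[i], ref_seg[i]
                        if b == n_byte or rb == n_byte:
                            continue
                        if (
                            config.min_base_quality > 0
                            and quals is not None
                            and quals[q0 + i] < config.min_base_quality
                        ):
                            continue
                        key = (region.contig, lo + int(i), chr(rb), chr(b))
                        support[key] = support.get(key, 0) + 1
                rpos += n
                qpos += n
            elif op == "I":
                anchor = rpos - 1
                if region.start <= anchor < region.end and anchor >= 0:
                    ins = read.bases[qpos : qpos + n]
                    base = reference.sequence(region.contig)[anchor]
                    if "N" not in ins and base != "N":
                        key = normalize_variant(
                            region.contig, anchor, base, base + ins, reference
                        )
                        if region.start <= key[1] < region.end:
                            support[key] = support.get(key, 0) + 1
                qpos += n
            elif op == "D":
                anchor = rpos - 1
                lo = max(rpos, region.start)
                hi = min(rpos + n, region.end)
                if lo < hi:
                    depth_diff[lo - region.start] += 1
                    depth_diff[hi - region.start] -= 1
                if region.start <= anchor < region.end and anchor >= 0:
                    ref_seq = reference.sequence(region.contig)
                    deleted = ref_seq[rpos : rpos + n]
                    base = ref_seq[anchor]
                    if "N" not in deleted and base != "N":
                        key = normalize_variant(
                            region.contig, anchor, base + deleted, base, reference
                        )
                        if region.start <= key[1] < region.end:
                            support[key] = support.get(key, 0) + 1
                rpos += n
            elif op == "S":
                qpos += n

    depth = np.cumsum(depth_diff[:-1])

    # group surviving alts by position, apply thresholds, keep top alts
    by_pos: dict[int, list[tuple[int, VariantKey]]] = {}
    for key, count in support.items():
        if count < config.min_support:
            continue
        pos_depth = int(depth[key[1] - region.start])
        if count < config.min_fraction * pos_depth:
            continue
        by_pos.setdefault(key[1], []).append((count, key))

    out: list[CandidateVariant] = []
    for pos in sorted(by_pos):
        entries = sorted(
            by_pos[pos], key=lambda e: (-e[0], len(e[1][3]), e[1][3])
        )
        for count, key in entries[: config.max_alts_per_site]:
            out.append(
                CandidateVariant(
                    contig=key[0],
                    pos=key[1],
                    ref_allele=key[2],
                    alt_allele=key[3],
                    alt_support=count,
                    total_depth=int(depth[key[1] - region.start]),
                    kind=variant_kind(key[2], key[3]),
                )
            )
    return out
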