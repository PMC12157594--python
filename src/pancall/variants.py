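"""Variant-key arithmetic shared across the caller.

A variant key is the normalized tuple ``(contig, pos, ref, alt)`` with
0-based ``pos``, left-aligned and minimally represented, indels anchored on
the preceding reference base (the VCF convention). Every module that
matches alleles — panel frequencies, truth labelling, benchmarking — goes
through this normalization so that matching is well defined.
"""

from __future__ import annotations

from typing import Tuple

from .alignment_io import Reference

VariantKey = Tuple[str, int, str, str]

__all__ = ["VariantKey", "normalize_variant", "is_snp", "variant_kind"]


def is_snp(key: VariantKey) -> bool:
    return len(key[2]) == 1 and len(key[3]) == 1


def variant_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def normalize_variant(
    contig: str, pos: int, ref: str, alt: str, reference: Reference
) -> VariantKey:
    """Left-align and minimally represent an allele pair.

    Standard normalization: trim shared trailing bases; while an allele is
    empty, prepend the previous reference base and shift left; finally trim
    shared leading bases that are not needed as an indel anchor.
    """
    if ref == alt:
        raise ValueError(f"ref and alt identical at {contig}:{pos} ({ref!r})")
    seq = reference.sequence(contig)
    ref, alt = ref.upper(), alt.upper()
    while ref and alt and ref[-1] == alt[-1]:
        trimmed = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 0:
                # cannot extend left of the contig; undo the trim
                ref, alt = ref + trimmed, alt + trimmed
                break
            pos -= 1
            ref, alt = seq[pos] + ref, seq[pos] + alt
    # trim shared leading bases beyond the indel anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (contig, pos, ref, alt)
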