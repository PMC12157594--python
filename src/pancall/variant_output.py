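"""Post-processing: genotype probabilities -> calls -> VCF 4.2.

Genotype is the argmax class with a conservative tie-break (REF, then HET,
then HOM_ALT within a tiny epsilon). Genotype quality is the standard
Phred transform of the residual probability, clipped at 99. Homozygous-
reference outcomes are RefCall records, excluded from the output VCF
unless requested.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from .alignment_io import Reference
from .candidates import CandidateVariant
from .genotyper import GenotypeProbabilities

__all__ = [
    "GenotypeCall",
    "genotype_from_probs",
    "make_calls",
    "write_vcf",
]

_GT_BY_CLASS = ("0/0", "0/1", "1/1")


@dataclass(frozen=True)
class GenotypeCall:
    candidate: CandidateVariant
    probabilities: GenotypeProbabilities
    genotype: str  # "0/0" | "0/1" | "1/1"
    genotype_quality: int
    filter: str  # "PASS" | "RefCall"


def genotype_from_probs(
    probabilities: GenotypeProbabilities, tie_epsilon: float = 1e-9
) -> tuple[str, int, str]:
    """(genotype, GQ, filter) from a probability triple.

    GQ = min(99, round(-10 log10(1 - p_max))) with p_max clipped so the
    quality saturates at 99 rather than overflowing.
    """
    probs = [probabilities.p_ref, probabilities.p_het, probabilities.p_hom]
    p_max = max(probs)
    # conservative tie-break: first class within epsilon of the max
    cls = next(i for i, p in enumerate(probs) if p >= p_max - tie_epsilon)
    p_clipped = min(p_max, 1.0 - 1e-10)
    gq = min(99, round(-10.0 * math.log10(1.0 - p_clipped)))
    genotype = _GT_BY_CLASS[cls]
    return genotype, gq, ("RefCall" if cls == 0 else "PASS")


def make_calls(
    candidates: Sequence[CandidateVariant],
    probabilities: Sequence[GenotypeProbabilities],
    tie_epsilon: float = 1e-9,
) -> list[GenotypeCall]:
    if len(candidates) != len(probabilities):
        raise ValueError(
            f"{len(candidates)} candidates but {len(probabilities)} "
            "probability triples"
        )
    out = []
    for cand, probs in zip(candidates, probabilities):
        gt, gq, filt = genotype_from_probs(probs, tie_epsilon)
        out.append(
            GenotypeCall(
                candidate=cand,
                probabilities=probs,
                genotype=gt,
                genotype_quality=gq,
                filter=filt,
            )
        )
    return out


def write_vcf(
    calls: Iterable[GenotypeCall],
    reference: Reference,
    sample_name: str,
    path: str | os.PathLike,
    emit_refcalls: bool = False,
) -> None:
    """Serialize calls as VCF 4.2 with contig headers from the reference.

    Records are sorted by (contig order, position); duplicate
    (contig, pos, ref, alt) keys are an error. DP and AD come from the
    candidate's depth and support counts. QUAL is set to the genotype
    quality of the called genotype.
    """
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=RefCall,Description="Homozygous reference call">')
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred)">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">'
    )
    for contig, length in reference.lengths.items():
        header.contigs.add(contig, length=length)
    header.add_sample(sample_name)

    calls = [c for c in calls if emit_refcalls or c.filter != "RefCall"]
    contig_order = {name: i for i, name in enumerate(reference.contigs)}
    calls.sort(
        key=lambda c: (contig_order[c.candidate.contig], c.candidate.pos)
    )
    seen: dict[tuple, str] = {}
    dups = []
    for c in calls:
        key = c.candidate.key
        if key in seen:
            dups.append(key)
        seen[key] = c.genotype
    if dups:
        raise ValueError(f"duplicate call keys: {sorted(set(dups))}")

    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for call in calls:
            cand = call.candidate
            rec = vcf.new_record(
                contig=cand.contig,
                start=cand.pos,
                stop=cand.pos + len(cand.ref_allele),
                alleles=(cand.ref_allele, cand.alt_allele),
                qual=float(call.genotype_quality),
                filter=call.filter,
            )
            gt = tuple(int(a) for a in call.genotype.split("/"))
            rec.samples[sample_name]["GT"] = gt
            rec.samples[sample_name]["GQ"] = call.genotype_quality
            rec.samples[sample_name]["DP"] = cand.total_depth
            rec.samples[sample_name]["AD"] = (
                max(cand.total_depth - cand.alt_support, 0),
                cand.alt_support,
            )
            vcf.write(rec)
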