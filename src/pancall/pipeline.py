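"""End-to-end orchestration: simulated bundle -> candidates -> pileup
examples -> trained genotyper -> calls -> benchmark.

These helpers exist so the caller's stages compose the same way in tests,
the command line and scripts. Discovery and example building are done per
contig inside the bundle's confident regions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .alignment_io import GenomicInterval
from .candidates import CandidateVariant, DiscoveryConfig, discover_candidates
from .genotyper import TrainedModel, predict
from .pileup import PileupConfig, PileupExample, build_example, label_example
from .simulate import SimulationBundle
from .evaluate import ComparisonResult, compare_to_truth
from .variant_output import GenotypeCall, make_calls

__all__ = [
    "discover_bundle_candidates",
    "build_labelled_examples",
    "strip_haplotypes",
    "call_variants",
    "evaluate_calls",
    "macro_f1",
]


def discover_bundle_candidates(
    bundle: SimulationBundle,
    contigs: Optional[Sequence[str]] = None,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[CandidateVariant]:
    """Candidates per contig, inside the bundle's confident regions."""
    wanted = set(contigs) if contigs is not None else None
    out: list[CandidateVariant] = []
    for region in bundle.truth.confident:
        if wanted is not None and region.contig not in wanted:
            continue
        reads = [r for r in bundle.reads if r.contig == region.contig]
        out.extend(discover_candidates(reads, bundle.reference, region, config))
    return out


class _ReadIndex:
    """Reads sorted by start with binary search for window overlap."""

    def __init__(self, reads: Sequence):
        by_contig: dict[str, list] = {}
        for r in reads:
            by_contig.setdefault(r.contig, []).append(r)
        self._index = {}
        for contig, rs in by_contig.items():
            rs.sort(key=lambda r: r.start)
            starts = np.array([r.start for r in rs])
            max_span = max((r.end - r.start for r in rs), default=0)
            self._index[contig] = (rs, starts, max_span)

    def overlapping(self, window: GenomicInterval) -> list:
        entry = self._index.get(window.contig)
        if entry is None:
            return []
        rs, starts, max_span = entry
        lo = int(np.searchsorted(starts, window.start - max_span))
        hi = int(np.searchsorted(starts, window.end))
        return [r for r in rs[lo:hi] if r.end > window.start]


def build_labelled_examples(
    bundle: SimulationBundle,
    candidates: Sequence[CandidateVariant],
    pileup_config: PileupConfig = PileupConfig(),
    labelled: bool = True,
    use_panel: bool = True,
) -> list[PileupExample]:
    truth = bundle.truth.alt_counts() if labelled else None
    index = _ReadIndex(bundle.reads)
    out = []
    for cand in candidates:
        label = label_example(cand, truth) if truth is not None else None
        window = GenomicInterval(
            cand.contig,
            max(cand.pos - pileup_config.center, 0),
            cand.pos + pileup_config.center + 1,
        )
        out.append(
            build_example(
                cand,
                index.overlapping(window),
                bundle.panel if use_panel else None,
                bundle.reference,
                pileup_config,
                label=label,
            )
        )
    return out


def strip_haplotypes(
    examples: Sequence[PileupExample],
    pileup_config: PileupConfig = PileupConfig(),
    in_place: bool = False,
) -> list[PileupExample]:
    """Ablation: the haplotype block zeroed, the read block kept.

    Training on stripped tensors gives the linear-reference baseline model
    with an identical architecture and input geometry. ``in_place`` zeroes
    the existing tensors instead of copying (halves peak memory when the
    pangenome arm has already been trained).
    """
    h = pileup_config.height_per_block
    rows = (
        slice(0, h) if pileup_config.haplotypes_on_top else slice(h, 2 * h)
    )
    out = []
    for ex in examples:
        tensor = ex.tensor if in_place else ex.tensor.copy()
        tensor[rows] = 0.0
        out.append(
            PileupExample(
                tensor=tensor,
                candidate=ex.candidate,
                window=ex.window,
                label=ex.label,
            )
        )
    return out


def call_variants(
    model: TrainedModel, examples: Sequence[PileupExample]
) -> list[GenotypeCall]:
    probs = predict(model, examples)
    return make_calls([ex.candidate for ex in examples], probs)


def evaluate_calls(
    bundle: SimulationBundle,
    calls: Sequence[GenotypeCall],
    contigs: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Benchmark PASS calls against the bundle truth, optionally restricted
    to a subset of contigs (e.g. the held-out one)."""
    wanted = set(contigs) if contigs is not None else None
    confident = [
        iv
        for iv in bundle.truth.confident
        if wanted is None or iv.contig in wanted
    ]
    pairs = [
        (c.candidate.key, c.genotype)
        for c in calls
        if c.filter == "PASS"
        and (wanted is None or c.candidate.contig in wanted)
    ]
    return compare_to_truth(pairs, bundle.truth, confident_bed=confident)


def macro_f1(
    y_true: Sequence[int], y_pred: Sequence[int], classes: Sequence[int] = (1, 2)
) -> float:
    """Unweighted mean F1 over the given classes (HET and HOM_ALT by
    default; the REF class is the uninteresting background)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    f1s = []
    for cls in classes:
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        fn = int(((y_true == cls) & (y_pred != cls)).sum())
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))
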