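"""Benchmarking call sets against truth and dissecting what a pangenome
changed.

``compare_to_truth`` is an exact-key matcher in the hap.py spirit: calls
and truth are joined on normalized (contig, pos, ref, alt); a key match
with a genotype mismatch registers as both one FP and one FN so precision
and recall both see the error; only PASS records inside the confident
regions count. (No vcfeval-style local haplotype equivalence: the
synthetic generator emits non-overlapping normalized variants, for which
exact matching is lossless.)

``classify_error_transitions`` computes the four call-set differences
between a baseline and a pangenome-aware run against the same truth:
removed FP, rescued FN (errors fixed), induced FP, induced FN (errors
introduced). Transition entries are genotype-qualified keys
(contig, pos, ref, alt, gt) — the gt component is the called genotype for
FPs and the truth genotype for FNs — which makes the four sets pairwise
disjoint by construction. Counts can be stratified by a labelled region
partition (duplication identity classes), by fixed-size windows (100 kb
default) and by panel allele frequency in bins of 0.2.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .alignment_io import GenomicInterval, Reference, load_bed
from .panel import HaplotypePanel, panel_allele_frequency
from .simulate import TruthSet
from .variants import VariantKey, is_snp, normalize_variant

__all__ = [
    "ComparisonResult",
    "ErrorTransitions",
    "RegionPartition",
    "load_calls_vcf",
    "compare_to_truth",
    "classify_error_transitions",
    "stratify_counts",
    "bin_by_allele_frequency",
    "plot_transitions",
]

QualifiedKey = tuple  # (contig, pos, ref, alt, gt)


@dataclass
class ComparisonResult:
    tp: set
    fp: set
    fn: set
    confident_digest: str

    @property
    def precision(self) -> float:
        d = len(self.tp) + len(self.fp)
        return len(self.tp) / d if d else 0.0

    @property
    def recall(self) -> float:
        d = len(self.tp) + len(self.fn)
        return len(self.tp) / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def total_errors(self) -> int:
        return len(self.fp) + len(self.fn)


@dataclass
class ErrorTransitions:
    removed_fp: set
    rescued_fn: set
    induced_fp: set
    induced_fn: set
    snp_only: bool

    @property
    def n_fixed(self) -> int:
        return len(self.removed_fp) + len(self.rescued_fn)

    @property
    def n_induced(self) -> int:
        return len(self.induced_fp) + len(self.induced_fn)

    def categories(self) -> dict[str, set]:
        return {
            "removed_FP": self.removed_fp,
            "rescued_FN": self.rescued_fn,
            "induced_FP": self.induced_fp,
            "induced_FN": self.induced_fn,
        }


@dataclass
class RegionPartition:
    """Named, non-overlapping interval classes covering the evaluated genome.

    Built from a labelled BED (4th column = class label); any position not
    covered falls in the implicit class "outside".
    """

    classes: dict[str, list[GenomicInterval]]

    @classmethod
    def from_bed(
        cls, path_or_entries: Union[str, os.PathLike, Sequence]
    ) -> "RegionPartition":
        if isinstance(path_or_entries, (str, os.PathLike)):
            entries = load_bed(path_or_entries, with_labels=True)
        else:
            entries = list(path_or_entries)
        classes: dict[str, list[GenomicInterval]] = {}
        for iv, label in entries:
            classes.setdefault(label, []).append(iv)
        part = cls(classes=classes)
        part._check_disjoint()
        return part

    def _check_disjoint(self) -> None:
        all_ivs = sorted(
            (iv for ivs in self.classes.values() for iv in ivs),
            key=lambda iv: (iv.contig, iv.start),
        )
        for a, b in zip(all_ivs, all_ivs[1:]):
            if a.contig == b.contig and b.start < a.end:
                raise ValueError(
                    f"partition classes overlap at {a.contig}:{b.start}"
                )

    def size_mb(self, label: str) -> float:
        return sum(len(iv) for iv in self.classes[label]) / 1e6

    def assign(self, contig: str, pos: int) -> str:
        for label, ivs in self.classes.items():
            for iv in ivs:
                if iv.contains(contig, pos):
                    return label
        return "outside"


def _bed_digest(intervals: Sequence[GenomicInterval]) -> str:
    text = ";".join(f"{iv.contig}:{iv.start}-{iv.end}" for iv in sorted(intervals))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_calls_vcf(
    path: str | os.PathLike,
    reference: Optional[Reference] = None,
    pass_only: bool = True,
) -> list[tuple[VariantKey, str]]:
    """Read a single-sample call VCF into (normalized key, genotype) pairs.

    Genotype is "0/1" or "1/1" (unordered). PASS-only by default; records
    whose FILTER is missing (".") count as PASS.
    """
    out = []
    for rec in VCF(os.fspath(path)):
        if pass_only and rec.FILTER is not None:  # cyvcf2: None == PASS/'.'
            continue
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; split first"
            )
        gt = rec.genotypes[0]
        alleles = [a for a in gt[:-1] if a != -1]
        if not alleles:
            raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
        alt_count = sum(1 for a in alleles if a == 1)
        if alt_count == 0:
            continue  # homozygous-reference record
        key = (rec.CHROM, rec.POS - 1, rec.REF.upper(), rec.ALT[0].upper())
        if reference is not None:
            key = normalize_variant(*key, reference)
        out.append((key, "0/1" if alt_count == 1 else "1/1"))
    return out


def _truth_pairs(truth: TruthSet) -> list[tuple[VariantKey, str]]:
    out = []
    for key, gt in truth.records:
        alt_count = gt[0] + gt[1]
        if alt_count:
            out.append((key, "0/1" if alt_count == 1 else "1/1"))
    return out


def compare_to_truth(
    calls: Union[str, os.PathLike, Sequence[tuple[VariantKey, str]]],
    truth: TruthSet,
    confident_bed: Optional[Sequence[GenomicInterval]] = None,
    reference: Optional[Reference] = None,
) -> ComparisonResult:
    """Join a call set against a truth set inside the confident regions.

    ``calls`` may be a VCF path or (key, genotype) pairs. A call is TP iff
    a truth record shares its normalized key and genotype. A key match
    with a different genotype contributes one FP (at the called genotype)
    and one FN (at the truth genotype). Entries are genotype-qualified
    keys (contig, pos, ref, alt, gt).
    """
    if isinstance(calls, (str, os.PathLike)):
        call_pairs = load_calls_vcf(calls, reference=reference)
    else:
        call_pairs = list(calls)
    confident = list(confident_bed if confident_bed is not None else truth.confident)

    def in_conf(key: VariantKey) -> bool:
        return any(iv.contains(key[0], key[1]) for iv in confident)

    call_map: dict[VariantKey, str] = {}
    for key, gt in call_pairs:
        if gt not in ("0/1", "1/1"):
            raise ValueError(f"malformed call genotype {gt!r} at {key}")
        if in_conf(key):
            call_map[key] = gt
    truth_map: dict[VariantKey, str] = {}
    for key, gt in _truth_pairs(truth):
        if in_conf(key):
            truth_map[key] = gt

    tp, fp, fn = set(), set(), set()
    for key, gt in call_map.items():
        tgt = truth_map.get(key)
        if tgt == gt:
            tp.add(key + (gt,))
        else:
            fp.add(key + (gt,))
            if tgt is not None:
                fn.add(key + (tgt,))
    for key, tgt in truth_map.items():
        if key not in call_map:
            fn.add(key + (tgt,))
    return ComparisonResult(
        tp=tp, fp=fp, fn=fn, confident_digest=_bed_digest(confident)
    )


def classify_error_transitions(
    baseline: ComparisonResult,
    pangenome: ComparisonResult,
    snp_only: bool = True,
) -> ErrorTransitions:
    """Four set differences between a baseline and a pangenome-aware run.

    Both comparisons must have been computed against the same truth and
    confident regions (checked via the confident-region digest).
    """
    if baseline.confident_digest != pangenome.confident_digest:
        raise ValueError(
            "baseline and pangenome comparisons were restricted to "
            "different confident regions; transitions are not meaningful"
        )

    def filt(s: set) -> set:
        if not snp_only:
            return set(s)
        return {e for e in s if is_snp(e[:4])}

    fp_b, fp_p = filt(baseline.fp), filt(pangenome.fp)
    fn_b, fn_p = filt(baseline.fn), filt(pangenome.fn)
    return ErrorTransitions(
        removed_fp=fp_b - fp_p,
        rescued_fn=fn_b - fn_p,
        induced_fp=fp_p - fp_b,
        induced_fn=fn_p - fn_b,
        snp_only=snp_only,
    )


def stratify_counts(
    transitions: ErrorTransitions,
    partition: RegionPartition,
    window_size: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and per-Mb rates per partition class, plus per-window counts.

    Returns (per_class, per_window). ``per_class`` has one row per
    partition class with one count column and one rate (count / Mb)
    column per transition category. ``per_window`` counts each category in
    adjacent non-overlapping windows of ``window_size`` bp.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    cats = transitions.categories()
    labels = list(partition.classes) + ["outside"]
    class_rows = {
        label: {f"{cat}_count": 0 for cat in cats} for label in labels
    }
    window_rows: dict[tuple[str, int], dict[str, int]] = {}
    for cat, entries in cats.items():
        for entry in entries:
            contig, pos = entry[0], entry[1]
            label = partition.assign(contig, pos)
            class_rows[label][f"{cat}_count"] += 1
            wkey = (contig, pos // window_size)
            row = window_rows.setdefault(
                wkey, {f"{c}_count": 0 for c in cats}
            )
            row[f"{cat}_count"] += 1
    per_class = pd.DataFrame.from_dict(class_rows, orient="index")
    per_class.index.name = "class"
    for cat in cats:
        rates = []
        for label in per_class.index:
            if label in partition.classes:
                mb = partition.size_mb(label)
                rates.append(
                    per_class.loc[label, f"{cat}_count"] / mb if mb else np.nan
                )
            else:
                rates.append(np.nan)
        per_class[f"{cat}_per_mb"] = rates
    per_window = pd.DataFrame.from_dict(window_rows, orient="index")
    if len(per_window):
        per_window.index = pd.MultiIndex.from_tuples(
            per_window.index, names=["contig", "window"]
        )
        per_window = per_window.sort_index()
    return per_class, per_window


def bin_by_allele_frequency(
    transitions: ErrorTransitions,
    panel: HaplotypePanel,
    reference: Reference,
    bin_width: float = 0.2,
) -> tuple[pd.DataFrame, set]:
    """Histogram of panel allele frequency per transition category.

    Bins are [i*w, (i+1)*w) with the last bin closed at 1.0. Keys whose
    allele cannot be resolved in the panel get frequency 0 and are
    returned in the flagged set. Per-category totals equal category sizes.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 1 evenly")
    cats = transitions.categories()
    index = [
        f"[{i * bin_width:.1f},{(i + 1) * bin_width:.1f}"
        + (")" if i < n_bins - 1 else "]")
        for i in range(n_bins)
    ]
    hist = pd.DataFrame(0, index=index, columns=list(cats), dtype=int)
    flagged: set = set()
    for cat, entries in cats.items():
        for entry in entries:
            key = entry[:4]
            paf = panel_allele_frequency(panel, key, reference)
            freq = paf.frequency
            if paf.carriers == 0:
                flagged.add(entry)
            b = min(int(freq / bin_width), n_bins - 1)
            hist.iloc[b, hist.columns.get_loc(cat)] += 1
    return hist, flagged


def plot_transitions(
    per_window: pd.DataFrame,
    af_histogram: pd.DataFrame,
    window_size: int = 100_000,
    path: Optional[str] = None,
):
    """Two-panel summary figure: fixed/induced error counts along the
    genome in adjacent windows, and the panel-allele-frequency histogram
    per transition category. Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 6))
    if len(per_window):
        contigs = per_window.index.get_level_values("contig").unique()
        offset = 0
        ticks, labels = [], []
        for contig in contigs:
            sub = per_window.loc[contig]
            x = (sub.index.to_numpy() + 0.5) * window_size / 1e6 + offset
            fixed = sub.get("removed_FP_count", 0) + sub.get("rescued_FN_count", 0)
            induced = sub.get("induced_FP_count", 0) + sub.get("induced_FN_count", 0)
            ax1.bar(x, fixed, width=window_size / 1e6, color="tab:blue", alpha=0.8)
            ax1.bar(x, -induced, width=window_size / 1e6, color="tab:red", alpha=0.8)
            ticks.append(offset)
            labels.append(contig)
            offset += (sub.index.max() + 1) * window_size / 1e6
        ax1.set_xticks(ticks, labels)
    ax1.axhline(0, color="black", lw=0.5)
    ax1.set_ylabel("fixed (up) / induced (down)\nper window")
    af_histogram.plot.bar(ax=ax2, rot=0)
    ax2.set_xlabel("panel allele frequency bin")
    ax2.set_ylabel("count")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
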