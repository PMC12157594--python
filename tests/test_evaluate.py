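"""Benchmarking: truth comparison, error transitions, stratification,
allele-frequency binning."""

import numpy as np
import pytest

from pancall import (
    GenomicInterval,
    RegionPartition,
    Reference,
    bin_by_allele_frequency,
    classify_error_transitions,
    compare_to_truth,
    stratify_counts,
)
from pancall.evaluate import ComparisonResult
from pancall.panel import HaplotypePanel, _apply_variants
from pancall.simulate import TruthSet

from conftest import random_sequence

CONF = [GenomicInterval("c1", 0, 1_000_000)]


def truthset(records):
    """records: list of (pos, ref, alt, gt_string)."""
    recs = []
    for pos, ref, alt, gt in records:
        recs.append((("c1", pos, ref, alt), (1, 0) if gt == "0/1" else (1, 1)))
    return TruthSet(records=recs, confident=CONF)


def calls(pairs):
    return [(("c1", pos, ref, alt), gt) for pos, ref, alt, gt in pairs]


class TestCompareToTruth:
    def test_perfect_calls(self):
        truth = truthset([(100, "A", "G", "0/1"), (200, "C", "T", "1/1")])
        res = compare_to_truth(
            calls([(100, "A", "G", "0/1"), (200, "C", "T", "1/1")]), truth
        )
        assert (res.precision, res.recall) == (1.0, 1.0)
        assert res.fp == set() and res.fn == set()

    def test_extra_call_is_one_fp(self):
        truth = truthset([(100, "A", "G", "0/1")])
        res = compare_to_truth(
            calls([(100, "A", "G", "0/1"), (300, "G", "A", "0/1")]), truth
        )
        assert len(res.fp) == 1 and len(res.fn) == 0

    def test_genotype_mismatch_is_fp_plus_fn(self):
        truth = truthset([(100, "A", "G", "0/1")])
        res = compare_to_truth(calls([(100, "A", "G", "1/1")]), truth)
        assert len(res.tp) == 0
        assert res.fp == {("c1", 100, "A", "G", "1/1")}
        assert res.fn == {("c1", 100, "A", "G", "0/1")}

    def test_outside_confident_ignored(self):
        truth = truthset([(100, "A", "G", "0/1")])
        res = compare_to_truth(
            calls([(100, "A", "G", "0/1"), (2_000_000, "T", "C", "0/1")]),
            truth,
        )
        assert len(res.fp) == 0

    def test_metrics_match_set_join_oracle(self, rng):
        """Seeded 100-record pair: TP/FP/FN equal a brute-force join."""
        positions = sorted(
            int(p) for p in rng.choice(np.arange(10, 99_000), 100, replace=False)
        )
        truth_recs, call_recs = [], []
        for i, pos in enumerate(positions):
            gt = "0/1" if i % 3 else "1/1"
            in_truth = rng.random() < 0.7
            in_calls = rng.random() < 0.7
            called_gt = gt if rng.random() < 0.8 else ("1/1" if gt == "0/1" else "0/1")
            if in_truth:
                truth_recs.append((pos, "A", "G", gt))
            if in_calls:
                call_recs.append((pos, "A", "G", called_gt))
        truth = truthset(truth_recs)
        res = compare_to_truth(calls(call_recs), truth)
        tmap = {(p): g for p, _, _, g in truth_recs}
        cmap = {(p): g for p, _, _, g in call_recs}
        tp = {p for p in cmap if tmap.get(p) == cmap[p]}
        fp = {p for p in cmap if tmap.get(p) != cmap[p]}
        fn = {p for p in tmap if p not in cmap or cmap[p] != tmap[p]}
        assert {e[1] for e in res.tp} == tp
        assert {e[1] for e in res.fp} == fp
        assert {e[1] for e in res.fn} == fn
        assert 0.0 <= res.precision <= 1.0 and 0.0 <= res.recall <= 1.0

    def test_tp_disjoint_from_errors(self, rng):
        truth = truthset([(100, "A", "G", "0/1"), (200, "C", "T", "1/1")])
        res = compare_to_truth(
            calls([(100, "A", "G", "0/1"), (200, "C", "T", "0/1")]), truth
        )
        assert not (res.tp & res.fp) and not (res.tp & res.fn)


class TestErrorTransitions:
    def test_hand_enumerated_toy(self):
        """baseline {FP:x, FN:y}, pangenome {TP:y, FP:z} ->
        removed_FP={x}, rescued_FN={y}, induced_FP={z}, induced_FN={}."""
        truth = truthset([(200, "C", "T", "0/1")])  # y
        base = compare_to_truth(
            calls([(100, "A", "G", "0/1")]), truth  # x is FP, y missed
        )
        pang = compare_to_truth(
            calls([(200, "C", "T", "0/1"), (300, "G", "A", "0/1")]), truth
        )
        tr = classify_error_transitions(base, pang)
        assert tr.removed_fp == {("c1", 100, "A", "G", "0/1")}
        assert tr.rescued_fn == {("c1", 200, "C", "T", "0/1")}
        assert tr.induced_fp == {("c1", 300, "G", "A", "0/1")}
        assert tr.induced_fn == set()
        assert tr.n_fixed == 2 and tr.n_induced == 1

    def test_identical_runs_give_empty_transitions(self):
        truth = truthset([(100, "A", "G", "0/1")])
        res = compare_to_truth(calls([(100, "A", "G", "1/1")]), truth)
        tr = classify_error_transitions(res, res)
        assert all(len(s) == 0 for s in tr.categories().values())

    def test_snp_only_filters_indels(self):
        truth = truthset([(100, "AT", "A", "0/1")])
        base = compare_to_truth(calls([]), truth)
        pang = compare_to_truth(calls([(100, "AT", "A", "0/1")]), truth)
        assert classify_error_transitions(base, pang).rescued_fn == set()
        tr = classify_error_transitions(base, pang, snp_only=False)
        assert tr.rescued_fn == {("c1", 100, "AT", "A", "0/1")}

    def test_mismatched_confident_regions_rejected(self):
        truth_a = truthset([(100, "A", "G", "0/1")])
        truth_b = TruthSet(
            records=truth_a.records,
            confident=[GenomicInterval("c1", 0, 500_000)],
        )
        a = compare_to_truth(calls([]), truth_a)
        b = compare_to_truth(calls([]), truth_b)
        with pytest.raises(ValueError, match="confident"):
            classify_error_transitions(a, b)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_disjointness_and_swap_symmetry(self, seed):
        """Random comparison pairs: the four sets are pairwise disjoint and
        swapping baseline/pangenome swaps removed<->induced."""
        rng = np.random.default_rng([4321, seed])
        for _ in range(50):
            positions = rng.choice(np.arange(10, 50_000), 30, replace=False)
            truth_recs, a_recs, b_recs = [], [], []
            for pos in positions:
                pos = int(pos)
                gt = "0/1" if rng.random() < 0.6 else "1/1"
                if rng.random() < 0.7:
                    truth_recs.append((pos, "A", "G", gt))
                if rng.random() < 0.6:
                    a_recs.append((pos, "A", "G", gt if rng.random() < 0.8 else "1/1"))
                if rng.random() < 0.6:
                    b_recs.append((pos, "A", "G", gt if rng.random() < 0.8 else "1/1"))
            truth = truthset(truth_recs)
            ra = compare_to_truth(calls(a_recs), truth)
            rb = compare_to_truth(calls(b_recs), truth)
            fwd = classify_error_transitions(ra, rb)
            sets = list(fwd.categories().values())
            for i in range(4):
                for j in range(i + 1, 4):
                    assert not (sets[i] & sets[j])
            rev = classify_error_transitions(rb, ra)
            assert rev.removed_fp == fwd.induced_fp
            assert rev.rescued_fn == fwd.induced_fn
            assert rev.induced_fp == fwd.removed_fp
            assert rev.induced_fn == fwd.rescued_fn


class TestStratification:
    def _partition(self):
        return RegionPartition.from_bed(
            [
                (GenomicInterval("c1", 0, 2_000_000), "SD>=99%"),
                (GenomicInterval("c1", 2_000_000, 4_000_000), "rest"),
            ]
        )

    def test_rate_per_mb(self):
        truth = truthset([])
        base = compare_to_truth(calls([(100, "A", "G", "0/1")]), truth)
        pang = compare_to_truth(calls([]), truth)
        tr = classify_error_transitions(base, pang)
        per_class, per_window = stratify_counts(tr, self._partition())
        assert per_class.loc["SD>=99%", "removed_FP_count"] == 1
        assert per_class.loc["SD>=99%", "removed_FP_per_mb"] == 0.5
        assert per_window.loc[("c1", 0), "removed_FP_count"] == 1

    def test_empty_transitions_all_zero(self):
        truth = truthset([(100, "A", "G", "0/1")])
        res = compare_to_truth(calls([(100, "A", "G", "0/1")]), truth)
        tr = classify_error_transitions(res, res)
        per_class, per_window = stratify_counts(tr, self._partition())
        assert per_class.filter(like="_count").to_numpy().sum() == 0
        assert per_window.empty

    def test_counts_match_membership_oracle(self, rng):
        part = self._partition()
        positions = [int(p) for p in rng.choice(np.arange(0, 4_000_000), 500, replace=False)]
        truth = truthset([])
        base = compare_to_truth(
            calls([(p, "A", "G", "0/1") for p in positions]),
            TruthSet(records=[], confident=[GenomicInterval("c1", 0, 4_000_000)]),
        )
        pang = compare_to_truth(
            calls([]),
            TruthSet(records=[], confident=[GenomicInterval("c1", 0, 4_000_000)]),
        )
        tr = classify_error_transitions(base, pang)
        per_class, per_window = stratify_counts(tr, part, window_size=100_000)
        want_sd = sum(1 for p in positions if p < 2_000_000)
        assert per_class.loc["SD>=99%", "removed_FP_count"] == want_sd
        assert per_class.loc["rest", "removed_FP_count"] == 500 - want_sd
        # windows: every key in exactly one window
        assert per_window["removed_FP_count"].sum() == 500
        for (contig, w), row in per_window.iterrows():
            lo, hi = w * 100_000, (w + 1) * 100_000
            assert row["removed_FP_count"] == sum(1 for p in positions if lo <= p < hi)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionPartition.from_bed(
                [
                    (GenomicInterval("c1", 0, 100), "a"),
                    (GenomicInterval("c1", 50, 150), "b"),
                ]
            )


@pytest.fixture(scope="module")
def panel_and_ref():
    rng = np.random.default_rng(31)
    ref = Reference({"c1": random_sequence(rng, 50_000)})
    seq = ref.sequence("c1")
    positions = list(range(100, 40_000, 400))
    variants = [(p, seq[p], "A" if seq[p] != "A" else "G") for p in positions]
    haps = []
    for i in range(10):
        # variant j is carried by exactly (j % 10) + 1 haplotypes
        edits = [v for j, v in enumerate(variants) if i < (j % 10) + 1]
        haps.append(_apply_variants(f"h{i}", "c1", edits, ref))
    panel = HaplotypePanel(haps, haplotype_count=10, source="synthetic")
    return ref, panel, variants


class TestAlleleFrequencyBinning:
    def _transitions(self, entries):
        base = ComparisonResult(tp=set(), fp=set(entries), fn=set(), confident_digest="x")
        pang = ComparisonResult(tp=set(), fp=set(), fn=set(), confident_digest="x")
        return classify_error_transitions(base, pang)

    def test_low_frequency_goes_to_first_bin(self, panel_and_ref):
        ref, panel, variants = panel_and_ref
        p, r, a = variants[0]  # carried by 1/10 -> freq 0.1
        tr = self._transitions([("c1", p, r, a, "0/1")])
        hist, flagged = bin_by_allele_frequency(tr, panel, ref)
        assert hist.iloc[0]["removed_FP"] == 1
        assert hist["removed_FP"].sum() == 1
        assert flagged == set()

    def test_frequency_one_in_closed_last_bin(self, panel_and_ref):
        ref, panel, variants = panel_and_ref
        p, r, a = variants[9]  # carried by 10/10
        tr = self._transitions([("c1", p, r, a, "0/1")])
        hist, _ = bin_by_allele_frequency(tr, panel, ref)
        assert hist.iloc[-1]["removed_FP"] == 1

    def test_unknown_key_flagged_and_counted_at_zero(self, panel_and_ref):
        ref, panel, _ = panel_and_ref
        seq = ref.sequence("c1")
        entry = ("c1", 45_001, seq[45_001], "A" if seq[45_001] != "A" else "C", "0/1")
        tr = self._transitions([entry])
        hist, flagged = bin_by_allele_frequency(tr, panel, ref)
        assert flagged == {entry}
        assert hist.iloc[0]["removed_FP"] == 1

    def test_histogram_matches_counting_oracle_and_sums(self, panel_and_ref, rng):
        ref, panel, variants = panel_and_ref
        chosen = [variants[int(i)] for i in rng.integers(0, len(variants), 100)]
        entries = {("c1", p, r, a, "0/1") for p, r, a in chosen}
        tr = self._transitions(entries)
        hist, _ = bin_by_allele_frequency(tr, panel, ref)
        assert hist["removed_FP"].sum() == len(entries)
        # oracle: carrier count of variant j is (j % 10) + 1
        want = [0] * 5
        for p, r, a in {c for c in chosen}:
            j = (p - 100) // 400
            freq = ((j % 10) + 1) / 10
            want[min(int(freq / 0.2), 4)] += 1
        assert hist["removed_FP"].tolist() == want

    def test_bad_bin_width_rejected(self, panel_and_ref):
        ref, panel, _ = panel_and_ref
        tr = self._transitions([])
        with pytest.raises(ValueError, match="divide"):
            bin_by_allele_frequency(tr, panel, ref, bin_width=0.3)


class TestPlot:
    def test_transition_figure_renders(self, tmp_path):
        from pancall import stratify_counts
        from pancall.evaluate import plot_transitions

        truth = truthset([(150_000, "A", "G", "0/1")])
        base = compare_to_truth(
            calls([(100, "A", "G", "0/1"), (250_000, "C", "T", "0/1")]), truth
        )
        pang = compare_to_truth(calls([(150_000, "A", "G", "0/1")]), truth)
        tr = classify_error_transitions(base, pang)
        part = RegionPartition.from_bed(
            [(GenomicInterval("c1", 0, 1_000_000), "rest")]
        )
        _, per_window = stratify_counts(tr, part)
        rng = np.random.default_rng(31)
        ref = Reference({"c1": random_sequence(rng, 1000)})
        panel = HaplotypePanel(
            [_apply_variants("h0", "c1", [], ref)], haplotype_count=1,
            source="synthetic",
        )
        hist, _ = bin_by_allele_frequency(tr, panel, ref)
        out = tmp_path / "fig.png"
        fig = plot_transitions(per_window, hist, path=str(out))
        assert out.exists() and out.stat().st_size > 0
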