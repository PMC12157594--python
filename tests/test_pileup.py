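"""Pileup tensor geometry, channel semantics and determinism."""

import numpy as np
import pytest

from pancall import (
    GenomicInterval,
    PileupConfig,
    Reference,
    build_example,
    candidate_window,
    encode_rows,
    label_example,
    load_examples,
    save_examples,
)
from pancall.candidates import CandidateVariant
from pancall.panel import HaplotypePanel, _apply_variants
from pancall.pileup import (
    CHANNELS,
    LABEL_HET,
    LABEL_HOM_ALT,
    LABEL_REF,
    _BASE_CODE,
    _DIFF_NO,
    _DIFF_YES,
    _GAP_CODE,
)

from conftest import make_read, random_sequence

C = {name: i for i, name in enumerate(CHANNELS)}


def snp_candidate(contig, pos, ref_base, alt_base, support=3, depth=10):
    return CandidateVariant(
        contig=contig, pos=pos, ref_allele=ref_base, alt_allele=alt_base,
        alt_support=support, total_depth=depth, kind="SNP",
    )


@pytest.fixture(scope="module")
def ref():
    r = np.random.default_rng(77)
    return Reference({"c1": random_sequence(r, 3000)})


class TestWindow:
    def test_centered_width_221(self, ref):
        cand = snp_candidate("c1", 1000, ref.sequence("c1")[1000], "A")
        w = candidate_window(cand, PileupConfig())
        assert (w.start, w.end) == (890, 1111)
        assert w.end - w.start == 221
        # 110 + 1 + 110 columns
        assert cand.pos - w.start == 110

    def test_window_near_contig_start_is_clipped(self, ref):
        cand = snp_candidate("c1", 50, ref.sequence("c1")[50], "A")
        w = candidate_window(cand, PileupConfig())
        assert w.start == 0

    def test_small_test_config(self, ref):
        cand = snp_candidate("c1", 2, ref.sequence("c1")[2], "A")
        cfg = PileupConfig(width=5, height_per_block=4)
        w = candidate_window(cand, cfg)
        assert (w.start, w.end) == (0, 5)
        assert cfg.center == 2

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PileupConfig(width=220)


class TestEncodeRows:
    def _candidate_at(self, ref, pos):
        base = ref.sequence("c1")[pos]
        alt = "A" if base != "A" else "C"
        return snp_candidate("c1", pos, base, alt)

    def test_reference_identical_read_matches_everywhere(self, ref):
        pos = 1500
        cand = self._candidate_at(ref, pos)
        cfg = PileupConfig()
        read = make_read("r", "c1", pos - 30, ref.sequence("c1")[pos - 30 : pos + 30])
        block = encode_rows([read], candidate_window(cand, cfg), cand, cfg, ref)
        covered = block[0, :, C["BASE"]] != 0
        assert covered.sum() == 60
        diff = block[0, covered, C["DIFFERS_FROM_REF"]]
        assert np.all(diff == _DIFF_NO)
        # a reference-carrying read supports the ref allele
        assert np.all(block[0, covered, C["SUPPORTS_ALT"]] == 0.5)

    def test_alt_read_marks_support_at_center(self, ref):
        pos = 1500
        cand = self._candidate_at(ref, pos)
        cfg = PileupConfig()
        frag = list(ref.sequence("c1")[pos - 20 : pos + 20])
        frag[20] = cand.alt_allele
        read = make_read("r", "c1", pos - 20, "".join(frag))
        block = encode_rows([read], candidate_window(cand, cfg), cand, cfg, ref)
        center = cfg.center
        assert block[0, center, C["SUPPORTS_ALT"]] == 1.0
        assert block[0, center, C["DIFFERS_FROM_REF"]] == _DIFF_YES
        assert block[0, center, C["BASE"]] == _BASE_CODE[cand.alt_allele]

    def test_haplotype_row_blanks_quality_and_strand(self, ref):
        pos = 1500
        cand = self._candidate_at(ref, pos)
        cfg = PileupConfig()
        hap = make_read(
            "h", "c1", 0, ref.sequence("c1"), origin="haplotype"
        )
        block = encode_rows([hap], candidate_window(cand, cfg), cand, cfg, ref)
        for ch in ("BASE_QUAL", "MAP_QUAL", "STRAND"):
            assert np.all(block[0, :, C[ch]] == 0.0)
        assert np.all(block[0, :, C["BASE"]] != 0)  # bases still encoded

    def test_deletion_renders_gap(self, ref):
        pos = 1500
        cand = self._candidate_at(ref, pos)
        cfg = PileupConfig(width=21, height_per_block=4)
        seq = ref.sequence("c1")
        read = make_read(
            "r", "c1", pos - 5,
            seq[pos - 5 : pos + 2] + seq[pos + 5 : pos + 10],
            cigar=(("M", 7), ("D", 3), ("M", 5)),
        )
        block = encode_rows([read], candidate_window(cand, cfg), cand, cfg, ref)
        cols = slice(cfg.center + 2, cfg.center + 5)  # deleted columns
        assert np.all(block[0, cols, C["BASE"]] == _GAP_CODE)
        assert np.all(block[0, cols, C["DIFFERS_FROM_REF"]] == _DIFF_YES)

    def test_base_channel_matches_expansion_oracle(self, ref, rng):
        """Seeded random reads: BASE channel equals a per-column expansion
        of the alignment mapped through the encoding table."""
        cfg = PileupConfig(width=81, height_per_block=50)
        pos = 2000
        cand = self._candidate_at(ref, pos)
        window = candidate_window(cand, cfg)
        seq = ref.sequence("c1")
        reads = []
        for i in range(50):
            start = int(rng.integers(pos - 120, pos + 30))
            rl = int(rng.integers(30, 90))
            frag = list(seq[start : start + rl])
            for _ in range(3):
                j = int(rng.integers(0, len(frag)))
                frag[j] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(make_read(f"r{i}", "c1", start, "".join(frag)))
        block = encode_rows(reads, window, cand, cfg, ref)
        win_start = pos - cfg.center
        for i, read in enumerate(reads):
            expected = np.zeros(cfg.width, dtype=np.float32)
            for col in range(cfg.width):
                p = win_start + col
                if read.start <= p < read.start + len(read.bases):
                    expected[col] = _BASE_CODE[read.bases[p - read.start]]
            np.testing.assert_array_equal(block[i, :, C["BASE"]], expected)


class TestBuildExample:
    def _setup(self, rng, n_haps=6, n_reads=12, alt_hap_count=3, alt_read_count=6):
        ref = Reference({"c1": random_sequence(rng, 3000)})
        seq = ref.sequence("c1")
        pos = 1500
        base = seq[pos]
        alt = "A" if base != "A" else "C"
        haps = []
        for i in range(n_haps):
            edits = [(pos, base, alt)] if i < alt_hap_count else []
            haps.append(_apply_variants(f"h{i}", "c1", edits, ref))
        panel = HaplotypePanel(haps, haplotype_count=n_haps, source="synthetic")
        reads = []
        for i in range(n_reads):
            start = pos - 40 + int(rng.integers(0, 20))
            frag = list(seq[start : start + 80])
            if i < alt_read_count:
                frag[pos - start] = alt
            reads.append(make_read(f"r{i:02d}", "c1", start, "".join(frag)))
        cand = snp_candidate("c1", pos, base, alt)
        return ref, panel, reads, cand

    def test_shape_blocks_and_bounds(self, rng):
        ref, panel, reads, cand = self._setup(rng)
        cfg = PileupConfig(height_per_block=10)
        ex = build_example(cand, reads, panel, ref, cfg)
        assert ex.tensor.shape == (20, 221, 6)
        assert float(ex.tensor.min()) >= 0.0 and float(ex.tensor.max()) <= 1.0
        # haplotype block on top: rows 0-5 populated, 6-9 blank
        hap_rows_used = np.abs(ex.tensor[:6]).sum(axis=(1, 2))
        assert np.all(hap_rows_used > 0)
        assert np.all(ex.tensor[6:10] == 0)
        # blank channels zero across the whole haplotype block
        for ch in ("BASE_QUAL", "MAP_QUAL", "STRAND"):
            assert np.all(ex.tensor[:10, :, C[ch]] == 0)
        # read block carries strand and quality
        assert ex.tensor[10:, :, C["STRAND"]].max() > 0

    def test_zero_reads_still_produces_example(self, rng):
        ref, panel, _, cand = self._setup(rng)
        cfg = PileupConfig(height_per_block=10)
        ex = build_example(cand, [], panel, ref, cfg)
        assert np.all(ex.tensor[10:] == 0)
        assert ex.tensor[:10].sum() > 0

    def test_read_order_permutation_invariance(self, rng):
        ref, panel, reads, cand = self._setup(rng)
        cfg = PileupConfig(height_per_block=20)
        a = build_example(cand, reads, panel, ref, cfg).tensor
        perm = [reads[i] for i in rng.permutation(len(reads))]
        b = build_example(cand, perm, panel, ref, cfg).tensor
        np.testing.assert_array_equal(a, b)

    def test_read_overflow_subsamples_deterministically(self, rng):
        ref, panel, reads, cand = self._setup(rng, n_reads=12)
        # 12 reads but height 5: seeded subsample of exactly 5, stable
        cfg = PileupConfig(height_per_block=5, row_overflow_seed=42)
        a = build_example(cand, reads, panel[0:0] if False else None, ref, cfg)
        b = build_example(cand, reads, None, ref, cfg)
        np.testing.assert_array_equal(a.tensor, b.tensor)
        used = np.abs(a.tensor[5:]).sum(axis=(1, 2))
        assert np.all(used > 0)  # exactly height rows, all populated
        cfg2 = PileupConfig(height_per_block=5, row_overflow_seed=43)
        c = build_example(cand, reads, None, ref, cfg2)
        assert not np.array_equal(a.tensor, c.tensor)

    def test_haplotype_overflow_errors_and_suggests_sampling(self, rng):
        ref, panel, reads, cand = self._setup(rng, n_haps=6)
        cfg = PileupConfig(height_per_block=4)
        with pytest.raises(ValueError, match="haplotype sampling"):
            build_example(cand, reads, panel, ref, cfg)
        cfg2 = PileupConfig(height_per_block=4, haplotype_overflow="subsample")
        ex = build_example(cand, reads, panel, ref, cfg2)
        assert ex.tensor.shape == (8, 221, 6)

    def test_supports_alt_fraction_reflects_carriers(self, rng):
        ref, panel, reads, cand = self._setup(
            rng, n_haps=6, alt_hap_count=3, n_reads=10, alt_read_count=5
        )
        cfg = PileupConfig(height_per_block=10)
        ex = build_example(cand, reads, panel, ref, cfg)
        center = cfg.center
        hap_support = ex.tensor[:6, center, C["SUPPORTS_ALT"]]
        assert sorted(hap_support) == [0.5, 0.5, 0.5, 1.0, 1.0, 1.0]


class TestLabelling:
    def test_label_classes(self):
        truth = {("c1", 100, "A", "G"): 1, ("c1", 200, "C", "T"): 2}
        het = snp_candidate("c1", 100, "A", "G")
        hom = snp_candidate("c1", 200, "C", "T")
        missing = snp_candidate("c1", 300, "G", "A")
        wrong_alt = snp_candidate("c1", 100, "A", "T")
        assert label_example(het, truth) == LABEL_HET
        assert label_example(hom, truth) == LABEL_HOM_ALT
        assert label_example(missing, truth) == LABEL_REF
        assert label_example(wrong_alt, truth) == LABEL_REF

    def test_labels_match_key_lookup_oracle(self, rng, tiny_bundle):
        """Candidate labels over a simulated bundle equal a brute-force
        normalized-key join against the truth records."""
        from pancall.pipeline import discover_bundle_candidates

        truth = tiny_bundle.truth.alt_counts()
        cands = discover_bundle_candidates(tiny_bundle)
        assert len(cands) >= 100
        for cand in cands[:150]:
            want = LABEL_REF
            for (key, gt) in tiny_bundle.truth.records:
                if key == cand.key:
                    want = gt[0] + gt[1]
            assert label_example(cand, truth) == want


class TestSerialization:
    def test_examples_round_trip(self, rng, tmp_path):
        ref = Reference({"c1": random_sequence(rng, 1000)})
        seq = ref.sequence("c1")
        reads = [
            make_read(f"r{i}", "c1", 400, seq[400:480]) for i in range(4)
        ]
        cand = snp_candidate("c1", 440, seq[440], "A" if seq[440] != "A" else "C")
        cfg = PileupConfig(height_per_block=6)
        ex = build_example(cand, reads, None, ref, cfg, label=LABEL_HET)
        path = tmp_path / "examples.npz"
        save_examples(path, [ex])
        loaded = load_examples(path)
        assert len(loaded) == 1
        np.testing.assert_array_equal(loaded[0].tensor, ex.tensor)
        assert loaded[0].candidate == ex.candidate
        assert loaded[0].label == LABEL_HET
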