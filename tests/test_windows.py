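"""Sliding windows, winscore enrichment, KS comparison, coverage I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modscape as m
from modscape.windows import (gene_coverage, read_bed12, read_bedgraph,
                              write_bedgraph)


class TestGenerateWindows:
    @pytest.mark.parametrize("L,width,step,expected", [
        (50, 20, 1, 31),      # L - w + 1
        (20, 20, 1, 1),
        (10, 20, 1, 0),
        (50, 20, 5, 7),
    ])
    def test_window_counts(self, L, width, step, expected):
        table = m.generate_windows({"g": "A" * L}, width=width, step=step)
        assert len(table) == expected

    def test_provenance_and_sequence(self):
        table = m.generate_windows({"g": "ACGTACGTAC"}, width=4, step=3)
        assert list(table["win_start"]) == [0, 3, 6]
        assert list(table["sequence"]) == ["ACGT", "TACG", "GTAC"]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(1, 80), min_size=1, max_size=6),
           st.integers(4, 25), st.integers(1, 10))
    def test_total_count_formula(self, lengths, width, step):
        seqs = {f"g{i}": "A" * L for i, L in enumerate(lengths)}
        expected = sum(max(0, (L - width) // step + 1) for L in lengths)
        assert len(m.generate_windows(seqs, width=width, step=step)) == expected

    def test_preconditions(self):
        with pytest.raises(ValueError, match="width"):
            m.generate_windows({"g": "ACGT" * 10}, width=3)
        with pytest.raises(ValueError, match="step"):
            m.generate_windows({"g": "ACGT" * 10}, width=4, step=0)


class TestWinscore:
    def test_formula_substitution(self):
        """MeanWinIP 8 / MedianGeneIP 2 over MeanWinControl 4 / median 2 -> 1.0"""
        ip = {"g": np.concatenate([np.full(50, 8.0), np.full(950, 2.0)])}
        ctrl = {"g": np.concatenate([np.full(50, 4.0), np.full(950, 2.0)])}
        table = m.winscore(ip, ctrl)
        first = table[table["win_start"] == 0].iloc[0]
        assert first["winscore"] == pytest.approx(1.0)
        assert first["mean_win_ip"] == 8.0 and first["median_gene_ip"] == 2.0

    def test_identical_tracks_score_zero(self):
        rng = np.random.default_rng(0)
        cov = {"g": rng.poisson(20, 1000).astype(float) + 1}
        table = m.winscore(cov, {"g": cov["g"].copy()})
        assert len(table) == 20
        assert table["winscore"].abs().max() == 0.0

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(1)
        ip = {"g": rng.poisson(20, 500).astype(float) + 1}
        ctrl = {"g": rng.poisson(20, 500).astype(float) + 1}
        base = m.winscore(ip, ctrl, library_size=1e6)
        scaled = m.winscore({"g": ip["g"] * 7.5}, ctrl, library_size=1e6)
        np.testing.assert_allclose(scaled["winscore"], base["winscore"], atol=1e-12)

    def test_enriched_window_recovers_log2_fold(self):
        ip, ctrl = m.simulate_coverage({"g": 1000}, enriched=[("g", 200, 4.0)],
                                       depth=50, seed=3)
        table = m.winscore(ip, ctrl)
        hit = table[table["win_start"] == 200]["winscore"].iloc[0]
        assert hit == pytest.approx(2.0, abs=0.3)

    def test_zero_median_gene_filtered(self):
        ip = {"g": np.full(200, 5.0), "dead": np.zeros(200)}
        ctrl = {"g": np.full(200, 5.0), "dead": np.full(200, 5.0)}
        table = m.winscore(ip, ctrl)
        assert set(table["gene_id"]) == {"g"}

    def test_low_input_rpkm_windows_filtered(self):
        ip = {"g": np.full(100, 50.0)}
        ctrl = {"g": np.full(100, 50.0)}
        assert len(m.winscore(ip, ctrl, library_size=1e12)) == 0

    def test_mismatched_gene_models_rejected(self):
        with pytest.raises(ValueError, match="same gene"):
            m.winscore({"a": np.ones(10)}, {"b": np.ones(10)})


class TestKsCompare:
    def test_identical_samples(self):
        stat, _ = m.ks_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == 0.0

    def test_disjoint_supports(self):
        stat, p = m.ks_compare([0, 1, 2], [10, 11, 12])
        assert stat == 1.0 and p < 0.2

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            m.ks_compare([1.0], [1, 2, 3])


class TestCoverageIO:
    def test_bedgraph_round_trip(self, tmp_path):
        cov = {"chr1": np.array([0, 0, 3, 3, 3, 1, 0, 2.5]),
               "chr2": np.array([4.0, 4.0])}
        path = tmp_path / "t.bedGraph"
        write_bedgraph(cov, path)
        back = read_bedgraph(path)
        np.testing.assert_allclose(back["chr1"], cov["chr1"])
        np.testing.assert_allclose(back["chr2"], cov["chr2"])

    def test_bed12_exon_concatenation_and_strand(self, tmp_path):
        bed = tmp_path / "genes.bed12"
        bed.write_text("chr1\t10\t100\tgplus\t0\t+\t10\t100\t0\t2\t5,5,\t0,20,\n"
                       "chr1\t10\t100\tgminus\t0\t-\t10\t100\t0\t2\t5,5,\t0,20,\n")
        genes = read_bed12(bed)
        track = {"chr1": np.arange(120, dtype=float)}
        cov = gene_coverage(track, genes)
        expected_plus = np.concatenate([np.arange(10, 15), np.arange(30, 35)])
        np.testing.assert_allclose(cov["gplus"], expected_plus)
        np.testing.assert_allclose(cov["gminus"], expected_plus[::-1])


class TestSlidingWindowDiscovery:
    def test_planted_motif_called_random_not(self):
        """Half the sequences carry GGACTCGTA once; they are flagged, and a
        fully random input yields no motif clusters at all."""
        rng = np.random.default_rng(7)

        def rand_seq(L):
            return "".join(rng.choice(list("ACGT"), size=L))

        motif = "GGACTCGTA"
        seqs = {}
        for i in range(40):
            pos = int(rng.integers(10, 30))
            s = rand_seq(50)
            seqs[f"pos{i}"] = s[:pos] + motif + s[pos + len(motif):]
        for i in range(40):
            seqs[f"neg{i}"] = rand_seq(50)

        result = m.sliding_window_pipeline(
            seqs, width=20, step=2, vote_threshold=0.2,
            cluster_params={"min_cluster_size": 15})
        calls = result["calls"].set_index("gene_id")["motif_positive"]
        positives = calls[calls.index.str.startswith("pos")]
        negatives = calls[calls.index.str.startswith("neg")]
        assert positives.mean() >= 0.8
        assert negatives.mean() <= 0.2      # false-call rate is threshold-dependent
        assert len(result["motif_pwms"]) >= 1

    def test_all_random_input_yields_no_calls(self):
        rng = np.random.default_rng(8)
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=40))
                for i in range(40)}
        result = m.sliding_window_pipeline(
            seqs, width=20, step=2,
            cluster_params={"min_cluster_size": 15})
        assert not result["calls"]["motif_positive"].any()

    @pytest.mark.parametrize("threshold,n,expected", [
        (0.0, 16, 1),        # any motif window suffices
        (0.1, 16, 2),
        (0.5, 31, 16),
        (1.0, 10, 10),
    ])
    def test_vote_rule(self, threshold, n, expected):
        from modscape.windows import votes_needed
        assert votes_needed(threshold, n) == expected
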