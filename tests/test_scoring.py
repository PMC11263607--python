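"""Expression-bin-matched module scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sencaf.errors import DataError
from sencaf.io import GeneSignature
from sencaf.scoring import (
    ControlSet,
    draw_controls,
    mean_expression_bins,
    score_signatures,
    signature_score,
    subseed,
)

from conftest import lognorm_matrix


def brute_force_score(X, gene_ids, sig_genes, controls):
    """Independent nested-loop mean-difference oracle."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in sig_genes if g in idx]
    out = []
    for j in range(X.shape[1]):
        s = sum(X[idx[g], j] for g in present) / len(present)
        c = sum(X[idx[g], j] for g in controls) / len(controls)
        out.append(s - c)
    return np.array(out)


class TestMeanExpressionBins:
    def test_equal_frequency_cut(self):
        means = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        m = lognorm_matrix(np.tile(means[:, None], (1, 2)))
        bins = mean_expression_bins(m, nbin=3)
        assert [bins.bin_of[f"g{i+1}"] for i in range(6)] == [0, 0, 1, 1, 2, 2]

    def test_ties_broken_lexicographically(self):
        m = lognorm_matrix(np.ones((6, 3)), gene_ids=["f", "d", "b", "a", "c", "e"])
        bins = mean_expression_bins(m, nbin=2)
        assert {g for g, b in bins.bin_of.items() if b == 0} == {"a", "b", "c"}
        assert {g for g, b in bins.bin_of.items() if b == 1} == {"d", "e", "f"}

    def test_single_bin(self):
        m = lognorm_matrix(np.arange(8.0).reshape(4, 2))
        bins = mean_expression_bins(m, nbin=1)
        assert set(bins.bin_of.values()) == {0}

    def test_nbin_exceeding_genes_rejected(self):
        m = lognorm_matrix(np.ones((3, 2)))
        with pytest.raises(DataError, match="nbin"):
            mean_expression_bins(m, nbin=4)

    def test_bin_sizes_differ_by_at_most_one(self, rng):
        m = lognorm_matrix(rng.random((23, 5)))
        bins = mean_expression_bins(m, nbin=7)
        sizes = np.bincount(list(bins.bin_of.values()))
        assert sizes.max() - sizes.min() <= 1


class TestDrawControls:
    def _bins(self, n_genes=40, nbin=4, seed=0):
        r = np.random.default_rng(seed)
        m = lognorm_matrix(r.random((n_genes, 6)))
        return m, mean_expression_bins(m, nbin=nbin)

    def test_count_is_per_gene_times_present(self):
        m, bins = self._bins()
        sig = GeneSignature("s", ("g1", "g2"))
        ctrl = draw_controls(sig, bins, per_gene=100, seed=1)
        assert len(ctrl.controls) == 200

    def test_small_bin_falls_back_to_replacement(self):
        m = lognorm_matrix(np.arange(10.0).reshape(5, 2))
        bins = mean_expression_bins(m, nbin=1)  # one bin of 5
        sig = GeneSignature("s", ("g1",))
        ctrl = draw_controls(sig, bins, per_gene=100, seed=0)
        assert len(ctrl.controls) == 100
        assert set(ctrl.controls) <= {"g2", "g3", "g4", "g5"}  # self excluded

    def test_controls_share_bin_with_their_gene(self):
        m, bins = self._bins()
        sig = GeneSignature("s", ("g3",))
        ctrl = draw_controls(sig, bins, per_gene=50, seed=3)
        b = bins.bin_of["g3"]
        assert all(bins.bin_of[c] == b for c in ctrl.controls)

    def test_reproducible_given_seed(self):
        m, bins = self._bins()
        sig = GeneSignature("s", ("g1", "g9"))
        a = draw_controls(sig, bins, per_gene=20, seed=5)
        b = draw_controls(sig, bins, per_gene=20, seed=5)
        assert a.controls == b.controls

    def test_absent_signature_is_error(self):
        m, bins = self._bins()
        with pytest.raises(DataError, match="nope"):
            draw_controls(GeneSignature("nope", ("ZZZ",)), bins, seed=0)

    def test_missing_genes_skipped_with_warning(self, caplog):
        m, bins = self._bins()
        sig = GeneSignature("s", ("g1", "ZZZ"))
        with caplog.at_level("WARNING"):
            ctrl = draw_controls(sig, bins, per_gene=10, seed=0)
        assert len(ctrl.controls) == 10
        assert any("ZZZ" in r.message for r in caplog.records)


class TestSignatureScore:
    def test_worked_mean_difference(self):
        # E(g1)=2, E(g2)=4 for the signature; every control gene at 1
        X = np.array([[2.0], [4.0], [1.0], [1.0]])
        m = lognorm_matrix(X)
        sig = GeneSignature("s", ("g1", "g2"))
        ctrl = ControlSet("s", ["g3", "g4"], per_gene=1, seed=0)
        assert signature_score(m, sig, ctrl)["s"][0] == pytest.approx(2.0)

    def test_self_controls_give_zero(self, rng):
        X = rng.random((6, 5))
        m = lognorm_matrix(X)
        sig = GeneSignature("s", ("g2", "g4"))
        ctrl = ControlSet("s", ["g2", "g4"], per_gene=1, seed=0)
        np.testing.assert_allclose(signature_score(m, sig, ctrl)["s"], 0, atol=1e-14)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(-5, 5), seed=st.integers(0, 1000))
    def test_shift_invariance_per_cell(self, c, seed):
        r = np.random.default_rng(seed)
        X = r.random((8, 4))
        sig = GeneSignature("s", ("g1", "g3"))
        ctrl = ControlSet("s", ["g2", "g5", "g5"], per_gene=1, seed=0)
        base = signature_score(lognorm_matrix(X), sig, ctrl)["s"]
        X2 = X.copy()
        X2[:, 2] += abs(c)
        shifted = signature_score(lognorm_matrix(X2), sig, ctrl)["s"]
        assert shifted[2] == pytest.approx(base[2], abs=1e-10)
        np.testing.assert_allclose(np.delete(shifted, 2), np.delete(base, 2))

    def test_monotone_response_delta_over_g(self, rng):
        X = rng.random((10, 3))
        sig = GeneSignature("s", ("g1", "g2", "g7"))
        ctrl = ControlSet("s", ["g3", "g4"], per_gene=1, seed=0)
        base = signature_score(lognorm_matrix(X), sig, ctrl)["s"]
        X2 = X.copy()
        X2[0, 1] += 0.9
        up = signature_score(lognorm_matrix(X2), sig, ctrl)["s"]
        assert up[1] - base[1] == pytest.approx(0.9 / 3)

    def test_oracle_equivalence_small_matrices(self):
        """Pinned control sets on <=10x10 matrices match the nested-loop
        oracle to 1e-12."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            n_g, n_c = r.integers(4, 11), r.integers(2, 11)
            X = r.random((n_g, n_c)) * 3
            gene_ids = [f"g{i+1}" for i in range(n_g)]
            m = lognorm_matrix(X, gene_ids=gene_ids)
            sig_genes = tuple(r.choice(gene_ids, size=2, replace=False))
            controls = list(r.choice(gene_ids, size=7, replace=True))
            ctrl = ControlSet("s", controls, per_gene=1, seed=0)
            got = signature_score(m, GeneSignature("s", sig_genes), ctrl)["s"]
            want = brute_force_score(X, gene_ids, sig_genes, controls)
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestScoreSignatures:
    def test_composition_matches_single_runs(self, rng):
        X = rng.random((40, 8))
        m = lognorm_matrix(X)
        s1 = GeneSignature("alpha", ("g1", "g2"))
        s2 = GeneSignature("beta", ("g10", "g11"))
        both = score_signatures(m, [s1, s2], nbin=4, per_gene=5, seed=99)
        from sencaf.scoring import mean_expression_bins as bins_fn

        bins = bins_fn(m, nbin=4)
        for sig in (s1, s2):
            ctrl = draw_controls(sig, bins, per_gene=5, seed=subseed(99, sig.name))
            solo = signature_score(m, sig, ctrl)
            np.testing.assert_array_equal(both[sig.name], solo[sig.name])

    def test_empty_signature_list_rejected(self, rng):
        with pytest.raises(DataError, match="empty"):
            score_signatures(lognorm_matrix(rng.random((4, 2))), [])

    def test_bit_identical_determinism(self, rng):
        X = rng.random((30, 6))
        sigs = [GeneSignature("a", ("g1", "g5")), GeneSignature("b", ("g9",))]
        t1 = score_signatures(lognorm_matrix(X), sigs, nbin=3, per_gene=8, seed=4)
        t2 = score_signatures(lognorm_matrix(X), sigs, nbin=3, per_gene=8, seed=4)
        for name in ("a", "b"):
            assert t1[name].tobytes() == t2[name].tobytes()

    def test_spiked_cells_rank_highest(self):
        """Cells with an up-spiked senescence program hold the top scores."""
        r = np.random.default_rng(7)
        X = r.random((60, 50))
        gene_ids = [f"g{i+1}" for i in range(55)] + [
            "CDKN2A", "CDKN2B", "CDKN1A", "CDKN1B", "SERPINE1"
        ]
        spiked = r.choice(50, size=10, replace=False)
        X[55:, spiked] += 3.0
        m = lognorm_matrix(X, gene_ids=gene_ids)
        sig = GeneSignature("senescence", gene_ids[55:])
        t = score_signatures(m, [sig], nbin=5, per_gene=30, seed=0)
        top10 = np.argsort(t["senescence"])[-10:]
        assert set(top10) == set(spiked)

    def test_null_signatures_score_near_zero(self):
        """Random gene sets have mean score ~0 across cells and replicates."""
        r = np.random.default_rng(123)
        X = r.gamma(2.0, 1.0, size=(200, 40))
        gene_ids = [f"g{i+1}" for i in range(200)]
        m = lognorm_matrix(X, gene_ids=gene_ids)
        means = []
        for k in range(30):
            genes = tuple(r.choice(gene_ids, size=8, replace=False))
            t = score_signatures(
                m, [GeneSignature("nullsig", genes)], nbin=10, per_gene=50, seed=k
            )
            means.append(t["nullsig"].mean())
        assert abs(np.mean(means)) < 0.05

    def test_zscore_mode_centers_scores(self, rng):
        X = rng.random((50, 12)) * 2
        sigs = [GeneSignature("a", ("g1", "g2", "g3"))]
        t = score_signatures(lognorm_matrix(X), sigs, nbin=5, per_gene=10,
                             seed=0, expression="zscore")
        assert np.isfinite(t["a"]).all()
        assert abs(t["a"].mean()) < 1.0
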