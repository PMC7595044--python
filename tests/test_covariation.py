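"""Rank correlation, Fisher-z significance, consensus calling, permutation FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import covarnet as cn
from covarnet.covariation import P_FLOOR, _consensus_mask


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [30, 20, 10], -1.0),
            ([1, 2, 3, 4, 5], [5, 6, 7, 8, 7], 8 / np.sqrt(95)),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert cn.spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_midrank_oracle_with_ties(self):
        """Brute-force oracle: Pearson correlation of explicitly computed
        midranks, on vectors with many ties."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 5, size=30).astype(float)
            y = rng.integers(0, 5, size=30).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert cn.spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)
            assert cn.spearman_rho(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    @given(
        st.lists(st.integers(-10_000, 10_000), min_size=5, max_size=40, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transforms(self, xs, transform):
        rng = np.random.default_rng(42)
        x = np.array(xs, dtype=float)
        y = rng.standard_normal(len(x))
        f = {"exp": lambda v: np.exp(v / 10_000), "cube": lambda v: v**3,
             "affine": lambda v: 3 * v + 7}[transform]
        assert cn.spearman_rho(f(x), y) == pytest.approx(
            cn.spearman_rho(x, y), abs=1e-9
        )

    def test_constant_vector_untestable(self):
        assert np.isnan(cn.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_matrix_path_matches_scalar(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(5, size=(6, 40)).astype(float)
        R = cn.spearman_matrix(X)
        for i in range(6):
            for j in range(i + 1, 6):
                assert R[i, j] == pytest.approx(
                    cn.spearman_rho(X[i], X[j]), abs=1e-10
                )
        assert np.allclose(R, R.T, equal_nan=True)


class TestFisherZ:
    def test_rho_zero_gives_p_one(self):
        for n in (10, 100, 1000):
            assert cn.fisher_z_p(0.0, n) == pytest.approx(1.0)

    def test_known_value(self):
        # z = atanh(0.5) * sqrt(100) = 5.4931; two-sided normal tail
        assert cn.fisher_z_p(0.5, 103) == pytest.approx(3.95e-8, rel=1e-2)

    def test_floor_applied(self):
        assert cn.fisher_z_p(0.99, 1000) == P_FLOOR
        assert cn.fisher_z_p(1.0, 10) == P_FLOOR

    def test_monotone_in_rho_and_n(self):
        # range chosen to stay above the p-value floor
        rhos = np.linspace(0.05, 0.6, 20)
        ps = np.array([cn.fisher_z_p(r, 50) for r in rhos])
        assert np.all(np.diff(ps) < 0)
        ns = np.arange(10, 200, 10)
        ps_n = np.array([cn.fisher_z_p(0.3, int(n)) for n in ns])
        assert np.all(np.diff(ps_n) < 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            cn.fisher_z_p(0.5, 3)

    def test_threshold_function(self):
        ns = np.arange(50, 501)
        thr = np.array([cn.rho_threshold(0.01, int(n)) for n in ns])
        assert np.all(np.diff(thr) < 0)
        # at a replicate of ~100-120 cells the threshold brackets rho ~ 0.25
        assert 0.23 < cn.rho_threshold(0.01, 120) < cn.rho_threshold(0.01, 100) < 0.26


class TestConsensusCalling:
    def _mask(self, ps, rhos, **kw):
        rho = np.array(rhos, dtype=float).reshape(-1, 1, 1)
        p = np.array(ps, dtype=float).reshape(-1, 1, 1)
        called, sign, _ = _consensus_mask(
            rho, p, kw.get("alpha", 0.01), kw.get("min_replicates", 2),
            kw.get("strict_sign", True)
        )
        return bool(called[0, 0]), int(sign[0, 0])

    def test_two_of_three_rule(self):
        called, sign = self._mask([0.005, 0.008, 0.5], [0.3, 0.3, 0.1])
        assert called and sign == 1

    def test_sign_inconsistency_discards(self):
        called, _ = self._mask([0.001, 0.001, 0.001], [0.3, 0.3, -0.3])
        assert not called

    def test_one_significant_replicate_insufficient(self):
        called, _ = self._mask([0.005, 0.02, 0.02], [0.3, 0.3, 0.3])
        assert not called

    def test_lenient_mode_ignores_insignificant_sign(self):
        ps, rhos = [0.001, 0.001, 0.9], [0.3, 0.3, -0.01]
        assert not self._mask(ps, rhos)[0]
        assert self._mask(ps, rhos, strict_sign=False)[0]

    def test_negative_consensus(self):
        called, sign = self._mask([0.001, 0.002, 0.3], [-0.3, -0.35, -0.05])
        assert called and sign == -1

    def test_callset_symmetry_under_cell_order(self, null_run):
        adata, _, _, calls = null_run
        perm = np.random.default_rng(5).permutation(adata.n_obs)
        res2 = cn.replicate_correlations(adata[perm].copy())
        calls2 = cn.call_covariations(res2)
        assert calls.pair_set(include_ribo=True) == calls2.pair_set(include_ribo=True)

    def test_recovery_on_planted_modules(self, modular_run):
        _, truth, _, calls = modular_run
        tp = set(truth.true_pairs)
        called = calls.pair_set()
        precision = len(called & tp) / len(called)
        recall = len(called & tp) / len(tp)
        assert precision >= 0.9
        assert recall >= 0.5
        # called signs match the planted loading-product signs
        df = calls.calls
        signed = {(a, b): s for a, b, s in df[["gene_a", "gene_b", "sign"]].to_numpy()}
        agree = [signed[p] == truth.true_pairs[p] for p in (called & tp)]
        assert np.mean(agree) > 0.99


class TestTypeIControl:
    def test_per_replicate_rate_near_alpha(self, null_run):
        _, _, res, _ = null_run
        iu = np.triu_indices(res.n_genes, k=1)
        m = len(iu[0])
        lo, hi = stats.binom.ppf([0.005, 0.995], m, 0.01) / m
        for r in range(3):
            frac = (res.p[r][iu] < 0.01).mean()
            assert lo <= frac <= hi

    def test_consensus_null_rate_bound(self, null_run):
        _, _, res, calls = null_run
        iu = np.triu_indices(res.n_genes, k=1)
        assert len(calls) / len(iu[0]) <= 3e-4


class TestPermutationFDR:
    def test_null_observed_within_permutation_distribution(self, null_run):
        adata, _, _, _ = null_run
        fdr = cn.permutation_fdr(adata, n_perm=50, seed=3)
        assert fdr["empirical_p"] > 0.05

    def test_planted_data_low_fdr(self, modular_run):
        adata, _, _, _ = modular_run
        fdr = cn.permutation_fdr(adata, n_perm=20, seed=1)
        assert fdr["fdr_estimate"] < 0.1

    def test_constant_matrix_zero_calls(self):
        import anndata as ad
        import pandas as pd

        X = np.full((60, 10), 7.0)
        a = ad.AnnData(
            X=X,
            obs=pd.DataFrame(
                {"replicate": ["r1"] * 30 + ["r2"] * 30, "condition": "wt"},
                index=[f"c{i}" for i in range(60)],
            ),
            var=pd.DataFrame(index=[f"g{i}" for i in range(10)]),
        )
        a.layers["rpm"] = X
        fdr = cn.permutation_fdr(a, n_perm=5, seed=0)
        assert fdr["max_count"] == 0 and fdr["observed"] == 0

    def test_invalid_n_perm(self, null_run):
        adata, _, _, _ = null_run
        with pytest.raises(ValueError):
            cn.permutation_fdr(adata, n_perm=0)


class TestAltDependence:
    def test_hoeffding_maximal_on_identity(self):
        x = np.arange(12.0)
        assert cn.hoeffding_d(x, x) == pytest.approx(1.0)

    def test_hoeffding_near_zero_when_independent(self):
        rng = np.random.default_rng(8)
        ds = [cn.hoeffding_d(rng.standard_normal(60), rng.standard_normal(60))
              for _ in range(100)]
        assert abs(np.mean(ds)) < 0.01

    def test_hoeffding_requires_five_points(self):
        with pytest.raises(ValueError):
            cn.hoeffding_d([1, 2, 3, 4], [1, 2, 3, 4])

    def test_pearson_matches_numpy(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert cn.alt_dependence(x, y, "pearson") == pytest.approx(
            np.corrcoef(x, y)[0, 1]
        )

    def test_spearman_calls_overlap_pearson_top_calls(self, modular_run):
        """Called pairs are largely recovered by Pearson correlation on the
        same data, mirroring the robustness of the rank-based calls."""
        adata, _, res, calls = modular_run
        X = np.asarray(adata.layers["rpm"])
        gi = {g: i for i, g in enumerate(res.genes)}
        spike = adata.var["is_spikein"].to_numpy()
        Xg = X[:, ~spike]
        logX = np.log1p(Xg)
        C = np.corrcoef(logX.T)
        called = list(calls.pair_set(include_ribo=True))
        vals = np.abs([C[gi[a], gi[b]] for a, b in called])
        thr = np.quantile(np.abs(C[np.triu_indices(C.shape[0], 1)]),
                          1 - 2 * len(called) / (C.shape[0] * (C.shape[0] - 1) / 2))
        assert (vals > thr).mean() >= 0.8
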