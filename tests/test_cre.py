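"""Crossed-random-effects model: likelihood oracle, OLS limit, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from curiosync import cre, similarity
from curiosync.cre import PairwiseDesign, build_pair_design, fit_cre, fit_cre_map, reml_loglik
from curiosync.similarity import PairwiseMapSet, subject_pairs


def _pair_machinery(n_subjects):
    ids = [f"s{i:02d}" for i in range(n_subjects)]
    pairs = subject_pairs(ids)
    Z = np.zeros((len(pairs), n_subjects))
    for r, (a, b) in enumerate(pairs):
        Z[r, ids.index(a)] = 1.0
        Z[r, ids.index(b)] = 1.0
    return ids, pairs, Z


def _design(y, X, pairs, ids, names):
    fixed = pd.DataFrame(dict(zip(names, X.T)), index=pd.MultiIndex.from_tuples(pairs))
    return PairwiseDesign(y, fixed, pairs, ids)


class TestRemlLikelihood:
    def test_matches_dense_covariance_oracle(self):
        """Woodbury/eigen path vs explicit 10x10 V = sigma2 I + tau2 ZZ' at N=5."""
        rng = np.random.default_rng(0)
        ids, pairs, Z = _pair_machinery(5)
        n = len(pairs)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [0.3, 0.2] + Z @ rng.normal(0, 0.2, 5) + rng.normal(0, 0.14, n)
        for tau2, sigma2 in [(0.04, 0.02), (0.001, 0.1), (0.3, 0.01)]:
            fast = reml_loglik(y, X, pairs, ids, tau2, sigma2)
            V = sigma2 * np.eye(n) + tau2 * (Z @ Z.T)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ beta
            dense = -0.5 * (
                (n - 2) * np.log(2 * np.pi)
                + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(X.T @ Vi @ X)[1]
                + r @ Vi @ r
            )
            assert fast == pytest.approx(dense, abs=1e-8)


class TestFitCre:
    def test_ols_limit_when_no_subject_variance(self):
        """tau2 = 0 data: estimates match OLS, and 2*SE bands cover at ~95%."""
        rng = np.random.default_rng(1)
        ids, pairs, Z = _pair_machinery(30)
        n = len(pairs)
        truth = np.array([0.3, 0.1, 0.0, 0.0])
        inside = total = 0
        for _ in range(10):
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = X @ truth + rng.normal(0, 0.1, n)
            fit = fit_cre(_design(y, X, pairs, ids, ["intercept", "a", "b", "c"]))
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            assert np.allclose(fit.beta.to_numpy(), ols, atol=1e-3)
            inside += int((np.abs(fit.beta.to_numpy() - truth) < 2 * fit.se.to_numpy()).sum())
            total += 4
        assert inside / total >= 0.85

    def test_monte_carlo_recovery_and_coverage(self):
        rng = np.random.default_rng(2)
        ids, pairs, Z = _pair_machinery(30)
        n = len(pairs)
        S = rng.normal(size=n)
        X = np.column_stack([np.ones(n), S])
        est, cover = [], 0
        for _ in range(200):
            y = 0.3 + 0.2 * S + Z @ rng.normal(0, 0.2, 30) + rng.normal(0, np.sqrt(0.02), n)
            fit = fit_cre(_design(y, X, pairs, ids, ["intercept", "similarity"]))
            b, se = fit.beta["similarity"], fit.se["similarity"]
            est.append(b)
            cover += (b - 1.96 * se) <= 0.2 <= (b + 1.96 * se)
        assert abs(np.mean(est) - 0.2) < 0.02
        assert 0.90 <= cover / 200 <= 0.98

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(3)
        ids, pairs, Z = _pair_machinery(40)
        n = len(pairs)
        X = np.ones((n, 1))
        t2s, s2s = [], []
        for _ in range(50):
            y = 0.3 + Z @ rng.normal(0, 0.2, 40) + rng.normal(0, np.sqrt(0.02), n)
            fit = fit_cre(_design(y, X, pairs, ids, ["intercept"]))
            t2s.append(fit.tau2)
            s2s.append(fit.sigma2)
        assert np.mean(t2s) == pytest.approx(0.04, abs=0.01)
        assert np.mean(s2s) == pytest.approx(0.02, abs=0.004)

    def test_row_permutation_and_pair_swap_invariance(self):
        rng = np.random.default_rng(4)
        ids, pairs, Z = _pair_machinery(10)
        n = len(pairs)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.2 + 0.1 * X[:, 1] + Z @ rng.normal(0, 0.2, 10) + rng.normal(0, 0.1, n)
        base = fit_cre(_design(y, X, pairs, ids, ["intercept", "s"]))
        perm = rng.permutation(n)
        swapped = [(b, a) if k % 2 else (a, b) for k, (a, b) in enumerate(pairs)]
        refit = fit_cre(_design(y[perm], X[perm], [swapped[i] for i in perm], ids,
                                ["intercept", "s"]))
        # summation order differs, so agreement is to optimizer termination noise
        assert np.allclose(base.beta, refit.beta, atol=1e-8)
        assert base.tau2 == pytest.approx(refit.tau2, rel=1e-6)

    def test_rank_deficient_design_rejected(self):
        ids, pairs, _ = _pair_machinery(6)
        n = len(pairs)
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            fit_cre(_design(np.zeros(n), X, pairs, ids, ["a", "b"]))

    def test_too_few_subjects_rejected(self):
        ids, pairs, _ = _pair_machinery(3)
        with pytest.raises(ValueError, match="4 subjects"):
            fit_cre(_design(np.zeros(3), np.ones((3, 1)), pairs, ids, ["intercept"]))

    def test_satterthwaite_df_sane(self):
        rng = np.random.default_rng(5)
        ids, pairs, Z = _pair_machinery(20)
        n = len(pairs)
        scores = pd.Series(rng.normal(size=20), index=ids)
        sim = similarity.grand_mean_centre(similarity.annak_similarity(scores))
        fixed = build_pair_design(ids, similarity=sim)
        y = 0.3 + Z @ rng.normal(0, 0.2, 20) + rng.normal(0, 0.14, n)
        fit = fit_cre(PairwiseDesign(y, fixed, pairs, ids), df_method="satterthwaite")
        # a subject-level regressor has effective df near N, not the pair count
        assert 5 < fit.df["similarity"] < 40
        assert ((fit.p > 0) & (fit.p <= 1)).all()


class TestFitCreMap:
    @staticmethod
    def _mapset(values, ids, mask):
        return PairwiseMapSet(pairs=subject_pairs(ids), values=values, mask=mask,
                              n_timepoints=100)

    def test_voxel_order_permutation(self):
        rng = np.random.default_rng(6)
        ids, pairs, Z = _pair_machinery(8)
        mask = np.ones((2, 2, 2), bool)
        vals = rng.normal(0.3, 0.2, size=(len(pairs), 8))
        fixed = build_pair_design(ids)
        m1, _ = fit_cre_map(self._mapset(vals, ids, mask), fixed)
        m2, _ = fit_cre_map(self._mapset(vals[:, ::-1], ids, mask), fixed)
        assert np.allclose(
            m1["intercept"].stat[mask], m2["intercept"].stat[mask][::-1], equal_nan=True
        )

    def test_planted_effect_region_stands_out(self):
        rng = np.random.default_rng(7)
        ids, pairs, Z = _pair_machinery(16)
        n = len(pairs)
        scores = pd.Series(rng.normal(size=16), index=ids)
        sim = similarity.grand_mean_centre(similarity.annak_similarity(scores))
        fixed = build_pair_design(ids, similarity=sim)
        mask = np.ones((4, 4, 4), bool)
        vals = 0.3 + (Z @ rng.normal(0, 0.15, (16, 64))) + rng.normal(0, 0.15, (n, 64))
        planted = np.zeros(64, bool)
        planted[:30] = True  # a known 30-voxel region carries the similarity effect
        vals[:, planted] += 0.5 * sim.values[:, None]
        maps_, conv = fit_cre_map(self._mapset(vals, ids, mask), fixed)
        stat = maps_["similarity"].stat[mask]
        assert stat[planted].mean() > stat[~planted].mean()
        assert conv[mask].all()

    def test_zero_variance_voxel_flagged(self):
        ids, pairs, _ = _pair_machinery(6)
        vals = np.zeros((len(pairs), 2))
        vals[:, 1] = np.random.default_rng(8).normal(size=len(pairs))
        mask = np.ones((1, 1, 2), bool)
        maps_, conv = fit_cre_map(self._mapset(vals, ids, mask), build_pair_design(ids))
        assert not conv[0, 0, 0] and conv[0, 0, 1]
        assert maps_["intercept"].p[0, 0, 0] == 1.0
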