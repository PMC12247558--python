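"""Neural and behavioural similarity: ISC, Fisher z, residualisation, AnnaK, group codes."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curiosync import similarity
from curiosync.similarity import (
    R_CLIP,
    SimilarityMatrix,
    annak_similarity,
    fisher_z,
    grand_mean_centre,
    group_code,
    inverse_fisher_z,
    pairwise_isc,
    residualize,
    subject_pairs,
    trial_similarity,
)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    @given(st.floats(-1.0, 1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @given(st.floats(-0.999999, 0.999999))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_inverse_roundtrip(self, r):
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-9)


class TestPairwiseIsc:
    def test_pair_count(self):
        ids = [f"s{i}" for i in range(50)]
        assert len(subject_pairs(ids)) == 1225

    def test_self_pair_at_clip_bound(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 2, 2, 40))
        ms = pairwise_isc({"a": x, "b": x.copy()}, np.ones((2, 2, 2), bool))
        assert np.allclose(ms.values, np.arctanh(R_CLIP))

    def test_null_mean_z_within_sampling_band(self):
        rng = np.random.default_rng(1)
        T = 594
        data = {f"s{i}": rng.normal(size=(3, 3, 3, T)) for i in range(6)}
        ms = pairwise_isc(data, np.ones((3, 3, 3), bool))
        assert abs(ms.values.mean()) < 2 / np.sqrt(T - 3)

    def test_matches_bruteforce_corrcoef_loop(self):
        rng = np.random.default_rng(2)
        ids = ["a", "b", "c", "d"]
        data = {s: rng.normal(size=(4, 4, 4, 50)) for s in ids}
        mask = np.ones((4, 4, 4), bool)
        ms = pairwise_isc(data, mask)
        flat = {s: d.reshape(-1, 50) for s, d in data.items()}
        for k, (i, j) in enumerate(ms.pairs):
            for v in range(64):
                r = np.corrcoef(flat[i][v], flat[j][v])[0, 1]
                assert ms.values[k, v] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_zero_variance_voxel_set_to_zero(self, caplog):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(2, 2, 2, 30))
        b = rng.normal(size=(2, 2, 2, 30))
        a[0, 0, 0, :] = 5.0  # flat series
        with caplog.at_level(logging.INFO, logger="curiosync.similarity"):
            ms = pairwise_isc({"a": a, "b": b}, np.ones((2, 2, 2), bool))
        assert ms.values[0, 0] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_pairwise_drop_censor_policy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(1, 1, 1, 30))
        b = rng.normal(size=(1, 1, 1, 30))
        cens_a = np.zeros(30, int); cens_a[:5] = 1
        cens_b = np.zeros(30, int); cens_b[28:] = 1
        ms = pairwise_isc({"a": a, "b": b}, np.ones((1, 1, 1), bool),
                          censor={"a": cens_a, "b": cens_b}, censor_policy="pairwise-drop")
        keep = slice(5, 28)
        r = np.corrcoef(a[0, 0, 0, keep], b[0, 0, 0, keep])[0, 1]
        assert ms.values[0, 0] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_isc({"a": np.zeros((1, 1, 1, 10)), "b": np.zeros((1, 1, 1, 12))},
                         np.ones((1, 1, 1), bool))


class TestTrialSimilarity:
    def test_identical_and_opposite_vectors(self):
        v = pd.DataFrame([[1, 2, 3, 4.0], [1, 2, 3, 4.0], [4, 3, 2, 1.0]],
                         index=["a", "b", "c"])
        sm = trial_similarity(v, "curiosity")
        vals = dict(zip(sm.pairs, sm.values))
        assert vals[("a", "b")] == pytest.approx(np.arctanh(R_CLIP))
        assert vals[("a", "c")] == pytest.approx(-np.arctanh(R_CLIP))

    def test_zero_variance_vector_pairs_zero(self, caplog):
        v = pd.DataFrame([[1, 1, 1, 1.0], [1, 2, 3, 4.0]], index=["a", "b"])
        with caplog.at_level(logging.WARNING, logger="curiosync.similarity"):
            sm = trial_similarity(v, "memory")
        assert sm.values[0] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_mean_similarity_monotone_in_shared_component(self):
        # stronger stimulus-level appeal -> more similar rating profiles
        from curiosync import behaviour, synthetic

        means = []
        for share in (0.2, 0.8, 1.6):
            cfg = synthetic.BehaviourSimConfig(
                n_subjects=40, sd_stimulus_appeal=share, seed=40
            )
            t = behaviour.centre_curiosity(synthetic.generate_behaviour(cfg))
            vec = t.pivot(index="subject_id", columns="stimulus_id",
                          values="curiosity_centred")
            sm = trial_similarity(vec, "curiosity")
            means.append(np.tanh(sm.values).mean())
        assert means[0] < means[1] < means[2]

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        v = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcde"))
        sm = trial_similarity(v, "curiosity").matrix()
        perm = list("cabed")
        sm_perm = trial_similarity(v.loc[perm], "curiosity").matrix()
        pd.testing.assert_frame_equal(sm.loc[perm, perm], sm_perm)


class TestResidualize:
    @staticmethod
    def _sim(vals, ids=None, kind="curiosity"):
        n = {1: 2, 3: 3, 6: 4, 10: 5, 1225: 50}[len(vals)]
        ids = ids or [f"s{i}" for i in range(n)]
        return SimilarityMatrix(kind=kind, subject_ids=ids, values=np.asarray(vals, float))

    def test_orthogonal_covariate_returns_centred_target(self):
        t = self._sim([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        c = self._sim([1.0, -1.0, 0.0, 0.0, -1.0, 1.0], kind="memory")  # even vs odd: orthogonal
        out = residualize(t, c)
        assert np.allclose(out.values, t.values - t.values.mean())

    def test_perfect_collinearity_gives_zero(self):
        t = self._sim([1.0, 2.0, 3.0])
        out = residualize(t, self._sim([1.0, 2.0, 3.0], kind="memory"))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(6)
        y, x = rng.normal(size=1225), rng.normal(size=1225)
        out = residualize(self._sim(y), self._sim(x, kind="memory"))
        X = np.column_stack([np.ones(1225), x])
        expect = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(out.values, expect, atol=1e-12)
        assert abs(np.corrcoef(out.values, x)[0, 1]) < 1e-10

    def test_projection_idempotent(self):
        rng = np.random.default_rng(7)
        t = self._sim(rng.normal(size=10))
        c = self._sim(rng.normal(size=10), kind="memory")
        once = residualize(t, c)
        twice = residualize(once, c)
        assert np.allclose(once.values, twice.values, atol=1e-12)
        assert once.kind == twice.kind == "curiosity_unique"

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            residualize(self._sim([1.0, 2.0, 3.0]), self._sim([2.0, 2.0, 2.0], kind="memory"))


class TestAnnakAndGroup:
    def test_symmetric_pair_cancels(self):
        sm = annak_similarity(pd.Series([0.2, -0.2], index=["a", "b"]))
        assert sm.values[0] == 0.0

    def test_constant_scores(self):
        sm = annak_similarity(pd.Series([0.3] * 4, index=list("abcd")))
        assert np.allclose(sm.values, 0.3)

    def test_linearity_and_symmetry(self):
        rng = np.random.default_rng(8)
        s = pd.Series(rng.normal(size=5), index=list("abcde"))
        m = annak_similarity(s).matrix()
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        m2 = annak_similarity(2 * s).matrix()
        assert np.allclose(m2.to_numpy(), 2 * m.to_numpy(), equal_nan=True)

    @pytest.mark.parametrize(
        "groups,expect",
        [(("control", "control"), 1.0), (("control", "incentive"), 0.0),
         (("incentive", "incentive"), -1.0)],
    )
    def test_group_deviation_coding(self, groups, expect):
        sm = group_code(pd.Series(groups, index=["a", "b"]))
        assert sm.values[0] == expect

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ValueError):
            group_code(pd.Series(["control", "placebo"], index=["a", "b"]))


class TestGrandMeanCentre:
    def test_arithmetic(self):
        sm = SimilarityMatrix("curiosity", list("abc"), np.array([1.0, 2.0, 3.0]))
        out = grand_mean_centre(sm)
        assert np.allclose(out.values, [-1.0, 0.0, 1.0])
        assert out.centring == "grand_mean"

    def test_idempotent(self):
        sm = SimilarityMatrix("curiosity", list("abc"), np.array([1.0, 2.0, 3.0]))
        once = grand_mean_centre(sm)
        assert np.allclose(grand_mean_centre(once).values, once.values)

    def test_interaction_column_is_elementwise_product(self):
        from curiosync.cre import build_pair_design

        ids = list("abcd")
        sim = grand_mean_centre(
            SimilarityMatrix("curiosity", ids, np.arange(6, dtype=float))
        )
        g = group_code(pd.Series(["control", "incentive"] * 2, index=ids))
        design = build_pair_design(ids, similarity=sim, group=g, interaction=True)
        assert np.allclose(
            design["group_x_similarity"], design["group"] * design["similarity"]
        )
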