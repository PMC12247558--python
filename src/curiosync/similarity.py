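"""Pairwise intersubject similarity: neural (ISC) and behavioural matrices.

The neural side correlates, voxel by voxel, the concatenated time courses
of every unordered subject pair and Fisher z-transforms the correlations
(``PairwiseMapSet``). The behavioural side builds subject-by-subject
similarity matrices from trial vectors (Pearson r, Fisher z), residualised
versions isolating the unique share of one behavioural variable, the
Anna-Karenina pair mean for scalar scores, and the group deviation code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseMapSet",
    "SimilarityMatrix",
    "subject_pairs",
    "pairwise_isc",
    "fisher_z",
    "inverse_fisher_z",
    "trial_similarity",
    "residualize",
    "annak_similarity",
    "group_code",
    "grand_mean_centre",
]

#: correlations are clipped to +/- this bound before atanh to keep z finite
R_CLIP = 1.0 - 1e-7

SIMILARITY_KINDS = (
    "curiosity",
    "memory",
    "curiosity_unique",
    "memory_unique",
    "annak_cmle",
    "group_code",
)


def subject_pairs(subject_ids) -> list[tuple]:
    """All unordered pairs, in row-major upper-triangle order."""
    ids = list(subject_ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def fisher_z(r):
    """Variance-stabilising Fisher z = atanh(r), with |r| clipped below 1."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def inverse_fisher_z(z):
    return np.tanh(z)


@dataclass
class PairwiseMapSet:
    """Fisher-z ISC per voxel per unordered subject pair."""

    pairs: list  # [(i, j), ...] subject ids
    values: np.ndarray  # (n_pairs, n_masked_voxels), Fisher z
    mask: np.ndarray  # boolean volume; values columns follow mask order
    n_timepoints: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def subject_ids(self) -> list:
        seen = dict.fromkeys(s for pair in self.pairs for s in pair)
        return list(seen)


@dataclass
class SimilarityMatrix:
    """Symmetric subject-by-subject similarity, stored per unordered pair."""

    kind: str
    subject_ids: list
    values: np.ndarray  # condensed, aligned with subject_pairs(subject_ids)
    centring: str = "none"  # none | grand_mean

    def __post_init__(self):
        expect = len(self.subject_ids) * (len(self.subject_ids) - 1) // 2
        if len(self.values) != expect:
            raise ValueError(f"expected {expect} pair values, got {len(self.values)}")

    @property
    def pairs(self) -> list:
        return subject_pairs(self.subject_ids)

    def matrix(self) -> pd.DataFrame:
        """Square symmetric form (diagonal NaN)."""
        n = len(self.subject_ids)
        m = np.full((n, n), np.nan)
        iu = np.triu_indices(n, k=1)
        m[iu] = self.values
        m[(iu[1], iu[0])] = self.values
        return pd.DataFrame(m, index=self.subject_ids, columns=self.subject_ids)


def _zscore_rows(X: np.ndarray):
    """Z-score along the last axis; zero-variance rows become all-zero."""
    Xc = X - X.mean(axis=-1, keepdims=True)
    sd = Xc.std(axis=-1, keepdims=True)
    bad = sd[..., 0] == 0
    np.divide(Xc, sd, out=Xc, where=sd > 0)
    return Xc, bad


def pairwise_isc(
    concatenated: dict,
    mask: np.ndarray,
    censor: dict | None = None,
    censor_policy: str = "include",
) -> PairwiseMapSet:
    """Per-voxel Pearson r over time for every subject pair, Fisher z.

    ``concatenated`` maps subject id -> 4D (or voxel x T) array on a common
    concatenation; ``censor`` optionally maps subject id -> per-volume 0/1
    flags. Policy ``include`` uses volumes as stored (the zeroed-volume
    convention); ``pairwise-drop`` excludes volumes censored in either
    member of a pair. Zero-variance voxels yield z = 0 (logged), not NaN.
    """
    if censor_policy not in ("include", "pairwise-drop"):
        raise ValueError("censor_policy must be 'include' or 'pairwise-drop'")
    if len(concatenated) < 2:
        raise ValueError("need at least 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    ids = list(concatenated)
    arrs = []
    for sid in ids:
        a = np.asarray(concatenated[sid], dtype=float)
        arrs.append(a[mask, :] if a.ndim == 4 else a)
    T = {a.shape[1] for a in arrs}
    if len(T) != 1:
        raise ValueError("subjects differ in concatenated length")
    T = T.pop()
    X = np.stack(arrs)  # (N, V, T)
    pairs = subject_pairs(ids)

    if censor_policy == "include" or censor is None:
        Xz, bad = _zscore_rows(X)
        n_bad = int(bad.sum())
        if n_bad:
            logger.info("%d zero-variance voxel series set to ISC 0", n_bad)
        idx = np.array([(ids.index(a), ids.index(b)) for a, b in pairs])
        r = np.einsum("pvt,pvt->pv", Xz[idx[:, 0]], Xz[idx[:, 1]]) / T
    else:
        cens = np.stack([np.asarray(censor[sid], dtype=bool) for sid in ids])
        r = np.empty((len(pairs), X.shape[1]))
        for k, (a, b) in enumerate(pairs):
            i, j = ids.index(a), ids.index(b)
            keep = ~(cens[i] | cens[j])
            if keep.sum() < 3:
                raise ValueError(f"pair {(a, b)} retains fewer than 3 volumes")
            xi, bad_i = _zscore_rows(X[i][:, keep])
            xj, bad_j = _zscore_rows(X[j][:, keep])
            r[k] = (xi * xj).sum(axis=1) / keep.sum()
    return PairwiseMapSet(pairs=pairs, values=fisher_z(r), mask=mask, n_timepoints=T)


def trial_similarity(vectors: pd.DataFrame, kind: str) -> SimilarityMatrix:
    """Fisher-z Pearson similarity of per-subject trial vectors.

    ``vectors``: subjects x stimuli frame, columns in the canonical
    stimulus order (identical for every subject). Zero-variance vectors
    (e.g. a subject who remembered everything) give pair value 0 with a
    logged warning, preserving the pair index.
    """
    X = vectors.to_numpy(dtype=float)
    Xz, bad = _zscore_rows(X)
    if bad.any():
        logger.warning(
            "%d subjects with zero-variance trial vectors; their pair similarities set to 0",
            int(bad.sum()),
        )
    r = (Xz @ Xz.T) / X.shape[1]
    iu = np.triu_indices(len(vectors), k=1)
    return SimilarityMatrix(
        kind=kind, subject_ids=list(vectors.index), values=fisher_z(r[iu])
    )


def residualize(target: SimilarityMatrix, covariate: SimilarityMatrix) -> SimilarityMatrix:
    """Residuals of the target pair values regressed on the covariate.

    Ordinary least squares with intercept over all pairs; the result is
    orthogonal to the covariate and mean zero. A projection: applying it
    twice equals applying it once.
    """
    if target.subject_ids != covariate.subject_ids:
        raise ValueError("similarity matrices index different subjects")
    x = covariate.values
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: nothing to remove")
    y = target.values
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    new_kind = target.kind + "_unique" if not target.kind.endswith("_unique") else target.kind
    return replace(target, kind=new_kind, values=resid)


def annak_similarity(scores: pd.Series) -> SimilarityMatrix:
    """Anna-Karenina similarity: pair value = mean of the two scores.

    Encodes absolute position on the scale, so one pole of the score
    distribution can be homogeneous while the other is heterogeneous;
    the sign of a downstream brain-behaviour effect says which.
    """
    s = scores.to_numpy(dtype=float)
    iu = np.triu_indices(len(s), k=1)
    vals = (s[iu[0]] + s[iu[1]]) / 2.0
    return SimilarityMatrix(kind="annak_cmle", subject_ids=list(scores.index), values=vals)


def group_code(assignments: pd.Series) -> SimilarityMatrix:
    """Pair-level group deviation code.

    Subjects get +0.5 (control) or -0.5 (incentive); a pair's code is the
    sum: 1 both-control, 0 mixed, -1 both-incentive.
    """
    codes = assignments.map({"control": 0.5, "incentive": -0.5})
    if codes.isna().any():
        raise ValueError("assignments must be 'control' or 'incentive' for every subject")
    c = codes.to_numpy(dtype=float)
    iu = np.triu_indices(len(c), k=1)
    return SimilarityMatrix(
        kind="group_code", subject_ids=list(assignments.index), values=c[iu[0]] + c[iu[1]]
    )


def grand_mean_centre(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Subtract the grand mean over pairs (idempotent)."""
    return replace(sim, values=sim.values - sim.values.mean(), centring="grand_mean")
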