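"""Linear mixed-effects model with crossed random effects (LME-CRE).

Pairwise intersubject data are doubly dependent: every subject enters
N-1 of the N(N-1)/2 pairs. The model for a pair (i, j) response (one
voxel's Fisher-z ISC)

    z_ij = x_ij' beta + u_i + u_j + e_ij,   u ~ iid N(0, tau2), e ~ iid N(0, sigma2)

is fitted by REML, profiling the variance ratio theta = tau2/sigma2 on a
log scale with an explicit boundary check at theta = 0 (where the fit is
exactly ordinary least squares). The covariance V = sigma2*I + tau2*Z Z'
is handled through the eigendecomposition of the N x N matrix Z'Z
(Woodbury identity), so the per-voxel cost is O(N) per candidate theta
and thousands of voxels can share one design. Wald statistics are referred to a t distribution with
Satterthwaite-style degrees of freedom by default (subject-level
regressors have effective df near N, not the pair count, and the plain
normal reference is visibly anticonservative at small N); ``df_method=
"normal"`` restores the normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .similarity import PairwiseMapSet, subject_pairs

__all__ = [
    "PairwiseDesign",
    "CreFit",
    "build_pair_design",
    "fit_cre",
    "fit_cre_map",
    "reml_loglik",
]

_LOG_THETA_LO, _LOG_THETA_HI = -12.0, 8.0


@dataclass
class PairwiseDesign:
    """One voxel's pairwise response with its shared fixed design."""

    response: np.ndarray  # (n_pairs,)
    fixed: pd.DataFrame  # n_pairs x p, includes an intercept column
    pairs: list  # [(i, j), ...] subject ids
    subject_ids: list

    def __post_init__(self):
        n = len(self.subject_ids)
        if len(self.pairs) != n * (n - 1) // 2:
            raise ValueError("pairs must enumerate all unordered subject pairs")
        if len(self.response) != len(self.pairs) or len(self.fixed) != len(self.pairs):
            raise ValueError("response/design rows must match the pair count")


@dataclass
class CreFit:
    beta: pd.Series
    se: pd.Series
    stat: pd.Series  # Wald beta/se
    p: pd.Series
    tau2: float
    sigma2: float
    converged: bool
    df: pd.Series | None = None  # Satterthwaite-style df, if requested
    reml: float = np.nan


def build_pair_design(
    subject_ids,
    similarity=None,
    group=None,
    interaction: bool = False,
) -> pd.DataFrame:
    """Assemble the pair-level fixed design.

    Columns (in order, as present): intercept, ``group`` (deviation code
    per pair), ``similarity`` (grand-mean-centred behavioural similarity),
    ``group_x_similarity``. ``similarity``/``group`` are
    :class:`~curiosync.similarity.SimilarityMatrix` instances aligned to
    ``subject_ids``.
    """
    pairs = subject_pairs(subject_ids)
    cols = {"intercept": np.ones(len(pairs))}
    for name, sim in (("group", group), ("similarity", similarity)):
        if sim is not None:
            if list(sim.subject_ids) != list(subject_ids):
                raise ValueError(f"{name} similarity indexes different subjects")
            cols[name] = sim.values
    if interaction:
        if similarity is None or group is None:
            raise ValueError("interaction requires both group and similarity")
        cols["group_x_similarity"] = cols["group"] * cols["similarity"]
    return pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(pairs))


class _CreWorkspace:
    """Design-level precomputations shared across voxels."""

    def __init__(self, X: np.ndarray, pairs: list, subject_ids: list):
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("rank-deficient fixed design")
        self.X = X
        index = {s: k for k, s in enumerate(subject_ids)}
        N = len(subject_ids)
        Z = np.zeros((self.n, N))
        for row, (a, b) in enumerate(pairs):
            Z[row, index[a]] = 1.0
            Z[row, index[b]] = 1.0
        self.Z = Z
        lam, Q = np.linalg.eigh(Z.T @ Z)
        self.lam, self.Q = lam, Q
        self.XtX = X.T @ X
        self.P = Q.T @ (Z.T @ X)  # (N, p)

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.Q.T @ (self.Z.T @ y)

    def profile(self, theta: float, y, q_v, Xty, yty):
        """GLS at variance ratio theta; returns (beta, XtWX, rss)."""
        if theta <= 0:
            XtWX, XtWy, yWy = self.XtX, Xty, yty
        else:
            d = 1.0 / (1.0 / theta + self.lam)
            XtWX = self.XtX - self.P.T @ (d[:, None] * self.P)
            XtWy = Xty - self.P.T @ (d * q_v)
            yWy = yty - q_v @ (d * q_v)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = float(yWy - beta @ XtWy)
        return beta, XtWX, max(rss, 1e-300)

    def neg2_reml(self, theta: float, y, q_v, Xty, yty) -> float:
        beta, XtWX, rss = self.profile(theta, y, q_v, Xty, yty)
        npp = self.n - self.p
        sigma2 = rss / npp
        logdet_v = self.n * np.log(sigma2) + float(np.sum(np.log1p(theta * self.lam)))
        sign, logdet_x = np.linalg.slogdet(XtWX / sigma2)
        return npp * np.log(2 * np.pi) + logdet_v + logdet_x + npp


def reml_loglik(y, X, pairs, subject_ids, tau2: float, sigma2: float) -> float:
    """REML log-likelihood at given variance components (fast path).

    ``-1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + r'V^-1 r ]`` with
    ``V = sigma2 I + tau2 Z Z'`` and r the GLS residual. Exists so tests
    can pit the Woodbury/eigen path against a dense-V oracle.
    """
    ws = _CreWorkspace(np.asarray(X, float), pairs, subject_ids)
    y = np.asarray(y, float)
    theta = tau2 / sigma2
    q_v, Xty, yty = ws.rotate(y), ws.X.T @ y, float(y @ y)
    beta, XtWX, rss = ws.profile(theta, y, q_v, Xty, yty)
    logdet_v = ws.n * np.log(sigma2) + float(np.sum(np.log1p(theta * ws.lam)))
    sign, logdet_x = np.linalg.slogdet(XtWX / sigma2)
    return -0.5 * (
        (ws.n - ws.p) * np.log(2 * np.pi) + logdet_v + logdet_x + rss / sigma2
    )


def _fit_one(ws: _CreWorkspace, y: np.ndarray, df_method: str):
    q_v, Xty, yty = ws.rotate(y), ws.X.T @ y, float(y @ y)
    if yty <= 0 or np.ptp(y) == 0:
        nanvec = np.full(ws.p, np.nan)
        return np.zeros(ws.p), nanvec, np.full(ws.p, 1.0), 0.0, np.nan, False, None, np.nan

    def crit(log_theta):
        return ws.neg2_reml(float(np.exp(log_theta)), y, q_v, Xty, yty)

    res = optimize.minimize_scalar(
        crit, bounds=(_LOG_THETA_LO, _LOG_THETA_HI), method="bounded",
        options={"xatol": 1e-7},
    )
    theta = float(np.exp(res.x))
    c_boundary = ws.neg2_reml(0.0, y, q_v, Xty, yty)
    if c_boundary <= res.fun or res.x <= _LOG_THETA_LO + 1e-6:
        theta = 0.0
    beta, XtWX, rss = ws.profile(theta, y, q_v, Xty, yty)
    sigma2 = rss / (ws.n - ws.p)
    tau2 = theta * sigma2
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    reml = -0.5 * ws.neg2_reml(theta, y, q_v, Xty, yty)

    df = None
    if df_method == "satterthwaite":
        df = _satterthwaite_df(ws, y, q_v, Xty, yty, tau2, sigma2)
        pvals = 2.0 * stats.t.sf(np.abs(beta / se), df)
    elif df_method == "normal":
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    else:
        raise ValueError("df_method must be 'normal' or 'satterthwaite'")
    return beta, se, pvals, tau2, sigma2, bool(res.success), df, reml


def _satterthwaite_df(ws, y, q_v, Xty, yty, tau2, sigma2):
    """Approximate per-coefficient df: 2 (se^2)^2 / Var(se^2).

    Var(se^2) comes from the delta method with the variance-parameter
    covariance taken as the inverse numeric Hessian of -2 REML in
    (tau2, sigma2).
    """
    def n2r(v):
        t2, s2 = max(v[0], 0.0), max(v[1], 1e-12)
        th = t2 / s2
        beta, XtWX, rss = ws.profile(th, y, q_v, Xty, yty)
        logdet_v = ws.n * np.log(s2) + float(np.sum(np.log1p(th * ws.lam)))
        sign, logdet_x = np.linalg.slogdet(XtWX / s2)
        return logdet_v + logdet_x + rss / s2

    def cov_diag(v):
        th = max(v[0], 0.0) / max(v[1], 1e-12)
        beta, XtWX, rss = ws.profile(th, y, q_v, Xty, yty)
        return max(v[1], 1e-12) * np.diag(np.linalg.inv(XtWX))

    v0 = np.array([tau2, sigma2])
    h = np.maximum(1e-6, 1e-4 * np.maximum(v0, sigma2))
    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(2):
            ea, eb = np.eye(2)[a] * h[a], np.eye(2)[b] * h[b]
            H[a, b] = (
                n2r(v0 + ea + eb) - n2r(v0 + ea - eb) - n2r(v0 - ea + eb) + n2r(v0 - ea - eb)
            ) / (4 * h[a] * h[b])
    try:
        vcov = 2.0 * np.linalg.inv(H)  # Hessian of -2*REML -> x2
    except np.linalg.LinAlgError:
        return np.full(ws.p, ws.n - ws.p)
    grads = np.stack(
        [(cov_diag(v0 + np.eye(2)[a] * h[a]) - cov_diag(v0 - np.eye(2)[a] * h[a])) / (2 * h[a])
         for a in range(2)]
    )  # (2, p)
    var_se2 = np.einsum("ap,ab,bp->p", grads, vcov, grads)
    se2 = cov_diag(v0)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * se2**2 / var_se2
    return np.clip(np.nan_to_num(df, nan=ws.n - ws.p), 1.0, 1e7)


def fit_cre(design: PairwiseDesign, df_method: str = "satterthwaite") -> CreFit:
    """REML fit of the crossed-random-intercept model for one response."""
    if len(design.subject_ids) < 4:
        raise ValueError("need at least 4 subjects")
    ws = _CreWorkspace(design.fixed.to_numpy(dtype=float), design.pairs, design.subject_ids)
    beta, se, pvals, tau2, sigma2, ok, df, reml = _fit_one(
        ws, np.asarray(design.response, dtype=float), df_method
    )
    names = list(design.fixed.columns)
    return CreFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        stat=pd.Series(beta / se, index=names),
        p=pd.Series(pvals, index=names),
        tau2=tau2,
        sigma2=sigma2,
        converged=ok,
        df=None if df is None else pd.Series(df, index=names),
        reml=reml,
    )


def fit_cre_map(mapset: PairwiseMapSet, fixed: pd.DataFrame, df_method: str = "satterthwaite"):
    """Voxelwise LME-CRE over a pairwise map set.

    Returns ``(stat_maps, converged)`` where ``stat_maps`` maps each fixed
    effect name to a :class:`~curiosync.maps.VoxelStatMap` and
    ``converged`` is a boolean volume flagging voxels whose variance
    optimisation converged.
    """
    from .maps import VoxelStatMap

    subject_ids = mapset.subject_ids()
    if len(fixed) != mapset.n_pairs:
        raise ValueError("fixed design rows do not match the pair count")
    ws = _CreWorkspace(fixed.to_numpy(dtype=float), mapset.pairs, subject_ids)
    n_vox = mapset.values.shape[1]
    p = fixed.shape[1]
    betas = np.zeros((n_vox, p))
    stats_ = np.zeros((n_vox, p))
    pvals = np.ones((n_vox, p))
    conv = np.zeros(n_vox, dtype=bool)
    for v in range(n_vox):
        b, se, pv, tau2, sigma2, ok, df, _ = _fit_one(ws, mapset.values[:, v], df_method)
        betas[v], pvals[v], conv[v] = b, pv, ok
        with np.errstate(invalid="ignore"):
            stats_[v] = b / se
    mask = mapset.mask

    def to_vol(col):
        vol = np.full(mask.shape, np.nan)
        vol[mask] = col
        return vol

    out = {}
    for k, name in enumerate(fixed.columns):
        out[name] = VoxelStatMap(
            estimate=to_vol(betas[:, k]),
            stat=to_vol(stats_[:, k]),
            p=to_vol(pvals[:, k]),
            mask=mask,
            affine=np.eye(4),
            effect=name,
        )
    conv_vol = np.zeros(mask.shape, dtype=bool)
    conv_vol[mask] = conv
    return out, conv_vol
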