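"""Behavioural arm: trial coding and the logistic mixed model.

Implements within-subject mean-centring of curiosity ratings,
confidence-cutoff coding of recognition memory, the generalised linear
mixed model (gLME) predicting a binary memory outcome from curiosity x
incentive with crossed random intercepts for subject and stimulus (plus,
in the ``full`` variant, per-subject random curiosity slopes), and the
extraction of per-subject curiosity slopes (CMLE scores).

The gLME is estimated by Laplace-approximate maximum likelihood: for a
candidate set of random-effect SDs the joint penalized log-likelihood is
maximised over (beta, u) by Newton's method, and the Laplace approximation
to the marginal deviance is minimised over the log-SDs (the estimation
scheme of lme4's ``glmer``). Standard errors are conditional on the
variance estimates, taken from the inverse of the joint Hessian at the
optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "GlmeFit",
    "centre_curiosity",
    "code_memory",
    "fit_glme",
    "extract_cmle",
]

FIXED_EFFECT_NAMES = ("intercept", "curiosity_centred", "incentive_code", "curiosity_x_incentive")

#: a random-effect SD below this (or at the optimiser floor) flags a singular fit
SINGULAR_SD = 1e-4
_LOG_SD_FLOOR = -10.0
_LOG_SD_CEIL = 3.0


def centre_curiosity(table: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite ``curiosity_centred`` = rating - subject mean.

    Idempotent on the centred column; raises if any rating is missing,
    listing the offending rows.
    """
    if "curiosity_raw" not in table.columns:
        raise ValueError("table has no 'curiosity_raw' column")
    missing = table.index[table["curiosity_raw"].isna()]
    if len(missing):
        raise ValueError(f"missing curiosity ratings in rows {list(missing)}")
    out = table.copy()
    out["curiosity_centred"] = out["curiosity_raw"] - out.groupby("subject_id")[
        "curiosity_raw"
    ].transform("mean")
    return out


def code_memory(table: pd.DataFrame, cutoff: int, measure: str = "recognition") -> pd.Series:
    """Binary outcome under a confidence cutoff.

    For recognition the outcome is 1 iff the answer was correct AND the
    confidence rating is strictly greater than ``cutoff`` (so cutoff 0
    reproduces plain recognition and cutoff 3 is the high-confidence
    measure). Recall ignores the cutoff.
    """
    if measure not in ("recognition", "recall"):
        raise ValueError("measure must be 'recognition' or 'recall'")
    if measure == "recall":
        return table["recall_correct"].astype(int)
    if not (0 <= int(cutoff) <= 5):
        raise ValueError("cutoff must be in 0..5")
    conf = table["confidence"]
    if ((conf < 1) | (conf > 6)).any():
        raise ValueError("confidence ratings must be in 1..6")
    return ((table["recognition_correct"] == 1) & (conf > cutoff)).astype(int)


@dataclass
class GlmeFit:
    """Laplace-ML logistic mixed-model fit."""

    fixed_effects: pd.DataFrame  # index effect name; columns b, se, z, p
    random_sd: dict  # name -> SD estimate
    subject_slopes: pd.Series | None  # fixed + BLUP, full variant only
    converged: bool
    singular: bool
    model_variant: str  # full | reduced
    loglik: float
    n_obs: int


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum(y*eta - log1p(exp(eta))), numerically safe
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _build_design(table: pd.DataFrame, outcome: np.ndarray, variant: str):
    """Canonicalise row order and build X plus the random-effect layout."""
    df = table.copy()
    df["_y"] = np.asarray(outcome, dtype=float)
    df = df.sort_values(["subject_id", "stimulus_id"], kind="mergesort").reset_index(drop=True)
    y = df["_y"].to_numpy()
    subj, subj_levels = pd.factorize(df["subject_id"], sort=True)
    stim, stim_levels = pd.factorize(df["stimulus_id"], sort=True)
    c = df["curiosity_centred"].to_numpy(dtype=float)
    g = df["incentive_code"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), c, g, c * g])
    S, M = len(subj_levels), len(stim_levels)
    layout = _RELayout(subj, stim, c, S, M, variant)
    names = ["subject_intercept", "stimulus_intercept"]
    sizes = [S, M]
    if variant == "full":
        names.append("curiosity_slope")
        sizes.append(S)
    return y, X, layout, names, np.array(sizes), subj_levels


def _make_sparse_Z(layout: _RELayout) -> sp.csr_matrix:
    """Explicit sparse Z, used once per fit for the joint-Hessian SEs."""
    n = len(layout.subj)
    rows = np.arange(n)
    cols = [layout.subj, layout.S + layout.stim]
    vals = [np.ones(n), np.ones(n)]
    if layout.full:
        cols.append(layout.S + layout.M + layout.subj)
        vals.append(layout.c)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.tile(rows, len(cols)), np.concatenate(cols))),
        shape=(n, layout.q),
    )


def _plain_logistic(y, X, max_iter=50):
    """Unpenalized logistic regression by Newton; starting values for the outer search."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < 1e-8:
            break
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = X.T @ (X * w[:, None])
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = np.clip(beta, -30, 30)  # guard against separation runaway
    return beta


class _RELayout:
    """Index bookkeeping for the crossed random-effect blocks.

    The u vector is ordered [subject intercepts (S), stimulus intercepts
    (M), subject slopes (S, full variant)]. Because the design is crossed,
    every Z'WZ block is a diagonal or an S x M table assembled by bincount,
    which keeps the inner Newton step free of sparse-matrix overhead.
    """

    def __init__(self, subj, stim, c, S, M, variant):
        self.subj, self.stim, self.c = subj, stim, c
        self.S, self.M = S, M
        self.full = variant == "full"
        self.q = 2 * S + M if self.full else S + M
        self.flat = subj * M + stim  # unique per row after aggregation

    def z_times(self, u):
        out = u[self.subj] + u[self.S + self.stim]
        if self.full:
            out = out + self.c * u[self.S + self.M + self.subj]
        return out

    def zt_times(self, r):
        parts = [np.bincount(self.subj, r, self.S), np.bincount(self.stim, r, self.M)]
        if self.full:
            parts.append(np.bincount(self.subj, r * self.c, self.S))
        return np.concatenate(parts)

    def hessian(self, w, pen_diag):
        S, M = self.S, self.M
        H = np.zeros((self.q, self.q))
        sm = np.bincount(self.flat, w, S * M).reshape(S, M)
        H[np.arange(S), np.arange(S)] = np.bincount(self.subj, w, S)
        H[S + np.arange(M), S + np.arange(M)] = np.bincount(self.stim, w, M)
        H[:S, S:S + M] = sm
        H[S:S + M, :S] = sm.T
        if self.full:
            o = S + M
            wc = w * self.c
            H[o + np.arange(S), o + np.arange(S)] = np.bincount(self.subj, wc * self.c, S)
            dsl = np.bincount(self.subj, wc, S)
            H[np.arange(S), o + np.arange(S)] = dsl
            H[o + np.arange(S), np.arange(S)] = dsl
            slm = np.bincount(self.flat, wc, S * M).reshape(S, M)
            H[o:o + S, S:S + M] = slm
            H[S:S + M, o:o + S] = slm.T
        H[np.arange(self.q), np.arange(self.q)] += pen_diag
        return H


def _u_mode(y, X, layout: _RELayout, pen_diag, beta, u, max_iter=60, tol=1e-9):
    """Newton (with step halving) over the random effects at fixed beta.

    Returns the conditional mode, the penalized log-likelihood there, and
    log|Z'WZ + G^-1| for the Laplace correction.
    """
    xb = X @ beta

    def _h(uu):
        return _logistic_loglik(xb + layout.z_times(uu), y) - 0.5 * float(
            np.sum(pen_diag * uu**2)
        )

    h_cur = _h(u)
    gmax = np.inf
    L = None
    for _ in range(max_iter):
        eta = xb + layout.z_times(u)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = layout.zt_times(y - mu) - pen_diag * u
        gmax = np.max(np.abs(grad))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        L = np.linalg.cholesky(layout.hessian(w, pen_diag))
        if gmax < tol:
            break
        step = np.linalg.solve(L.T, np.linalg.solve(L, grad))
        t = 1.0
        for _ in range(30):
            cand = u + t * step
            h_new = _h(cand)
            if h_new >= h_cur - 1e-12:
                u, h_cur = cand, h_new
                break
            t *= 0.5
        else:
            break
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(L))))
    return u, h_cur, logdet_H, gmax < 1e-5


def _laplace_criterion(params, p, y, X, layout, sizes, state):
    """-2 * Laplace log marginal likelihood as a function of (log_sd, beta).

    The random effects are profiled out by the inner Newton mode; the
    criterion includes the log-determinant correction, so beta is a free
    outer parameter exactly as in glmer's (theta, beta) deviance.
    """
    log_sd = np.clip(params[: len(sizes)], _LOG_SD_FLOOR, _LOG_SD_CEIL)
    beta = params[len(sizes):]
    sd = np.exp(log_sd)
    pen_diag = np.repeat(1.0 / sd**2, sizes)
    u, h, logdet_H, ok = _u_mode(y, X, layout, pen_diag, beta, state["u"])
    state.update(beta=beta, u=u, inner_ok=ok)
    log_det_G = 2.0 * float(np.sum(np.repeat(log_sd, sizes)))
    return -2.0 * h + logdet_H + log_det_G


def fit_glme(
    table: pd.DataFrame, outcome, variant: str = "full", fix_sd=None
) -> GlmeFit:
    """Fit the gLME for one binary memory outcome.

    ``outcome`` is a column name or an array aligned with ``table``.
    Fixed effects: intercept, subject-centred curiosity, effect-coded
    incentive group, and their interaction. Random effects: crossed
    subject/stimulus intercepts, plus per-subject curiosity slopes for
    ``variant='full'``. ``fix_sd`` (sequence, one value per random-effect
    block) holds the SDs fixed instead of estimating them, e.g. for
    sensitivity analyses; zeros are clamped to the optimiser floor, which
    reduces the model to plain logistic regression.
    """
    if variant not in ("full", "reduced"):
        raise ValueError("variant must be 'full' or 'reduced'")
    y = table[outcome].to_numpy() if isinstance(outcome, str) else np.asarray(outcome)
    if not np.isin(np.unique(y), [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    df = table
    if "curiosity_centred" not in df.columns:
        df = centre_curiosity(df)
    keep = df["curiosity_centred"].notna() & pd.Series(y, index=df.index).notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d rows with missing values (listwise)", n_drop)
        df, y = df.loc[keep], y[keep.to_numpy()]
    groups = df.groupby("subject_id")["incentive_code"].first()
    if (groups == -1).sum() < 2 or (groups == 1).sum() < 2:
        raise ValueError("need at least 2 subjects per incentive group")

    y_s, X, layout, re_names, sizes, subj_levels = _build_design(df, y, variant)
    p = X.shape[1]
    state = {"beta": np.zeros(p), "u": np.zeros(layout.q), "inner_ok": True}
    beta0 = _plain_logistic(y_s, X)
    if fix_sd is not None:
        fixed_log_sd = np.log(np.maximum(np.asarray(fix_sd, dtype=float), np.exp(_LOG_SD_FLOOR)))
        if fixed_log_sd.shape != (len(sizes),):
            raise ValueError(f"fix_sd must supply {len(sizes)} SDs for variant {variant!r}")

        def _crit_beta(beta_only):
            return _laplace_criterion(
                np.concatenate([fixed_log_sd, beta_only]), p, y_s, X, layout, sizes, state
            )

        res = scipy.optimize.minimize(
            _crit_beta, beta0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxfev": 2000, "adaptive": True},
        )
        xopt = np.concatenate([fixed_log_sd, res.x])
    else:
        x0 = np.concatenate([np.full(len(sizes), np.log(0.5)), beta0])
        res = scipy.optimize.minimize(
            _laplace_criterion,
            x0,
            args=(p, y_s, X, layout, sizes, state),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxfev": 4000, "adaptive": True},
        )
        xopt = res.x
    log_sd = np.clip(xopt[: len(sizes)], _LOG_SD_FLOOR, _LOG_SD_CEIL)
    crit = _laplace_criterion(xopt, p, y_s, X, layout, sizes, state)  # refresh mode at optimum
    sd = np.exp(log_sd)
    beta, u = state["beta"], state["u"]

    # SEs from the joint Hessian at the optimum (conditional on the SDs)
    pen_diag = np.repeat(1.0 / sd**2, sizes)
    Z = _make_sparse_Z(layout)
    M = sp.hstack([sp.csr_matrix(X), Z]).tocsr()
    eta = M @ np.concatenate([beta, u])
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    A = M.multiply(np.sqrt(w)[:, None]).tocsr()
    H = (A.T @ A).toarray()
    H[np.arange(p + layout.q), np.arange(p + layout.q)] += np.concatenate(
        [np.zeros(p), pen_diag]
    )
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov)[:p])
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {"b": beta, "se": se, "z": z, "p": pvals}, index=list(FIXED_EFFECT_NAMES)
    )

    singular = bool((sd < SINGULAR_SD).any())
    converged = bool(res.success and state["inner_ok"])
    if not converged:
        warnings.warn("gLME fit did not fully converge; estimates flagged", RuntimeWarning)
    if singular:
        logger.info("singular gLME fit: random-effect SD at boundary (%s)", dict(zip(re_names, sd)))

    subject_slopes = None
    if variant == "full":
        off = int(sizes[0] + sizes[1])
        subject_slopes = pd.Series(
            beta[1] + u[off : off + sizes[2]], index=list(subj_levels), name="curiosity_slope"
        )
    return GlmeFit(
        fixed_effects=fixed,
        random_sd=dict(zip(re_names, sd)),
        subject_slopes=subject_slopes,
        converged=converged,
        singular=singular,
        model_variant=variant,
        loglik=-0.5 * crit,
        n_obs=len(y_s),
    )


def extract_cmle(fit: GlmeFit) -> pd.Series:
    """Per-subject curiosity slopes, mean-centred across subjects.

    The slope is the fixed curiosity effect plus the subject's conditional
    mode (BLUP analogue); mean-centring makes the fixed-effect offset
    irrelevant for downstream similarity geometry.
    """
    if fit.model_variant != "full" or fit.subject_slopes is None:
        raise ValueError("CMLE scores require a full-variant fit with random slopes")
    s = fit.subject_slopes
    return s - s.mean()
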