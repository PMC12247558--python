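"""Fixed-effect meta-analytic integration of mixed-model coefficients.

Pools unstandardised log-odds estimates across data collections by
inverse-variance weighting, converts pooled effects to odds ratios with
95% confidence intervals, and regresses pooled effects on the confidence
cutoff of the memory measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectEstimate",
    "MetaResult",
    "fixed_effect_meta",
    "to_odds_ratio",
    "cutoff_regression",
    "meta_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectEstimate:
    study_id: str
    effect_name: str
    b: float
    se: float
    cutoff: int | None = None

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    effect_name: str
    b_pooled: float
    se_pooled: float
    z: float
    p: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    weights: tuple
    cutoff: int | None = None


def fixed_effect_meta(estimates: list[EffectEstimate]) -> MetaResult:
    """Inverse-variance (weighted least squares) fixed-effect pooling.

    ``b_pooled = sum(b/SE^2)/sum(1/SE^2)``, ``SE_pooled = 1/sqrt(sum(1/SE^2))``.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    names = {e.effect_name for e in estimates}
    if len(names) > 1:
        raise ValueError(f"mixed effect names in meta-analysis: {sorted(names)}")
    b = np.array([e.b for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    b_pooled = float(np.sum(w * b) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    z = b_pooled / se_pooled
    p = 2.0 * stats.norm.sf(abs(z))
    or_, (lo, hi) = to_odds_ratio(b_pooled, se_pooled)
    cutoffs = {e.cutoff for e in estimates}
    return MetaResult(
        effect_name=names.pop(),
        b_pooled=b_pooled,
        se_pooled=se_pooled,
        z=float(z),
        p=float(p),
        odds_ratio=or_,
        ci95_low=lo,
        ci95_high=hi,
        weights=tuple(w),
        cutoff=cutoffs.pop() if len(cutoffs) == 1 else None,
    )


def to_odds_ratio(b: float, se: float) -> tuple[float, tuple[float, float]]:
    """Odds ratio ``exp(b)`` with 95% CI ``exp(b +/- 1.96 SE)``.

    Rounding to 2 decimal places is left to the report layer.
    """
    if not se > 0:
        raise ValueError("standard error must be positive")
    return float(np.exp(b)), (float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se)))


def cutoff_regression(pooled: list[MetaResult], weighted: bool = False):
    """OLS of pooled log-odds on the confidence cutoff (scaled 0..5).

    Returns ``(slope, (ci_low, ci_high), p)`` with the CI and two-sided p
    from the t distribution on ``n - 2`` degrees of freedom. ``weighted``
    optionally weights by inverse pooled variances.
    """
    cutoffs = np.array([m.cutoff for m in pooled], dtype=float)
    if len(cutoffs) != len(set(cutoffs)):
        raise ValueError("duplicate cutoffs")
    if len(cutoffs) < 3:
        raise ValueError("need at least 3 cutoffs for a slope with a CI")
    y = np.array([m.b_pooled for m in pooled])
    w = np.array([1.0 / m.se_pooled**2 for m in pooled]) if weighted else np.ones_like(y)
    X = np.column_stack([np.ones_like(cutoffs), cutoffs])
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    beta = xtx_inv @ (WX.T @ y)
    resid = y - X @ beta
    dof = len(y) - 2
    s2 = float(np.sum(w * resid**2) / dof)
    se_slope = float(np.sqrt(s2 * xtx_inv[1, 1]))
    slope = float(beta[1])
    if se_slope == 0.0:
        return slope, (slope, slope), 0.0 if slope != 0 else 1.0
    t = slope / se_slope
    p = float(2.0 * stats.t.sf(abs(t), dof))
    tq = stats.t.ppf(0.975, dof)
    return slope, (slope - tq * se_slope, slope + tq * se_slope), p


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    """Report-layer table: b (SE), OR [95%-CI] at 2 dp, z, p."""
    rows = []
    for m in results:
        rows.append(
            {
                "effect": m.effect_name,
                "cutoff": m.cutoff,
                "b": m.b_pooled,
                "se": m.se_pooled,
                "b_se": f"{m.b_pooled:.3f} ({m.se_pooled:.3f})",
                "or_ci": f"{m.odds_ratio:.2f} [{m.ci95_low:.2f}; {m.ci95_high:.2f}]",
                "z": m.z,
                "p": m.p,
                "p_label": f"{m.p:.3f}" if m.p >= 0.001 else "< 0.001",
            }
        )
    return pd.DataFrame(rows)
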