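"""Pooling of per-source MR estimates and effect-scale conversions.

The study design estimates each exposure-outcome effect against two
independent outcome GWAS sources and pools them by inverse-variance
meta-analysis: fixed-effect when Cochran Q shows no heterogeneity, otherwise
DerSimonian-Laird random effects.  Log-odds effects are reported as odds
ratios per 1-SD exposure change, optionally as percent risk increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError
from .estimators import MREstimate, Z95

_F = "%.10g"


@dataclass(slots=True)
class MetaResult:
    pooled_beta: float
    pooled_se: float
    ci_low: float
    ci_high: float
    pval: float
    model: str
    Q: float
    Q_pval: float
    I2: float
    tau2: float
    k_sources: int
    note: str = ""


def _coerce(estimates) -> np.ndarray:
    rows = []
    for e in estimates:
        if isinstance(e, MREstimate):
            rows.append((e.beta, e.se))
        else:
            rows.append((float(e[0]), float(e[1])))
    return np.asarray(rows, dtype=float)


def meta_combine(estimates, model: str = "auto") -> MetaResult:
    """Inverse-variance meta-analysis of (beta, se) pairs or MREstimates.

    ``fixed`` weights by 1/se^2; ``random_dl`` adds the DerSimonian-Laird
    tau^2 = max(0, (Q - (k-1)) / (Sw - Sw2/Sw)) to each variance; ``auto``
    picks random_dl iff the Q p-value is below 0.05.  I^2 with only two
    sources is reported but flagged unstable.
    """
    arr = _coerce(estimates)
    k = arr.shape[0]
    if k < 2:
        raise AnalysisError("meta-analysis needs at least two estimates")
    b, se = arr[:, 0], arr[:, 1]
    w = 1.0 / se ** 2
    pooled_fixed = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - pooled_fixed) ** 2))
    df = k - 1
    q_pval = float(stats.chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    sw, sw2 = float(np.sum(w)), float(np.sum(w ** 2))
    tau2 = max(0.0, (Q - df) / (sw - sw2 / sw))

    if model == "auto":
        model = "random_dl" if q_pval < 0.05 else "fixed"
    if model == "fixed":
        pooled, pooled_se, tau2_used = pooled_fixed, sw ** -0.5, 0.0
    elif model == "random_dl":
        w_star = 1.0 / (se ** 2 + tau2)
        pooled = float(np.sum(w_star * b) / np.sum(w_star))
        pooled_se = float(np.sum(w_star)) ** -0.5
        tau2_used = tau2
    else:
        raise AnalysisError(f"unknown meta-analysis model: {model}")

    pval = float(2.0 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult(
        pooled_beta=pooled, pooled_se=pooled_se,
        ci_low=pooled - Z95 * pooled_se, ci_high=pooled + Z95 * pooled_se,
        pval=pval, model=model, Q=Q, Q_pval=q_pval, I2=i2, tau2=tau2_used,
        k_sources=k, note="I2 unstable at k=2" if k == 2 else "")


def or_with_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio with 95% CI from a log-odds effect and its SE."""
    if se <= 0:
        raise AnalysisError("se must be positive")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def percent_increase_from_or(or_value: float) -> float:
    """Percent risk change implied by an odds ratio ((OR - 1) * 100)."""
    if or_value <= 0:
        raise AnalysisError("odds ratio must be positive")
    return (or_value - 1.0) * 100.0


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance cut-off alpha / n_tests."""
    if n_tests < 1:
        raise AnalysisError("n_tests must be >= 1")
    return alpha / n_tests
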