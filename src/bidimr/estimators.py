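"""Two-sample MR estimators and diagnostics.

Given harmonized per-SNP effect pairs (beta_exp_j, se_exp_j, beta_out_j,
se_out_j), the per-SNP causal estimate is the Wald ratio
r_j = beta_out_j / beta_exp_j.  The estimators here combine the ratios under
different assumptions about horizontal pleiotropy:

* **IVW** — inverse-variance-weighted mean of the ratios with weights
  w_j = beta_exp_j^2 / se_out_j^2, equivalent to a zero-intercept weighted
  regression of outcome on exposure effects.  The multiplicative
  random-effects variant scales the SE by max(1, sqrt(Q/(k-1))).
* **MR-Egger** — the same regression with a free intercept; a non-zero
  intercept estimates average directional pleiotropy and flags bias in IVW.
* **Weighted median** — consistent when instruments carrying up to half the
  weight are invalid; SE by seeded parametric bootstrap.
* **MR-PRESSO** — resampling-based global heterogeneity (residual sum of
  squares) test with per-SNP outlier detection, an outlier-corrected IVW
  estimate, and a distortion test.

Each estimator is exposed both as a scikit-learn style class
(``IVWEstimator().fit(hset)`` with trailing-underscore fitted attributes) and
as a thin module-level function.  All two-sided p-values use the normal
distribution, the usual convention for summary-data MR; Egger can use a
t reference with k-2 df behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import AnalysisError
from .sumstats import HarmonizedInstrumentSet, HarmonizedRecord

Z95 = 1.96  # reporting convention for 95% CIs


@dataclass(slots=True)
class MREstimate:
    """One method's causal estimate with its diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    Q: float | None = None
    Q_df: int | None = None
    Q_pval: float | None = None
    I2: float | None = None


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_pval: float
    outlier_snps: list[tuple[str, float]]
    distortion_pval: float | None
    corrected: MREstimate | None
    raw: MREstimate
    n_sim: int
    seed: int


def _extract(data):
    """(beta_exp, se_exp, beta_out, se_out, snp_ids) from flexible input."""
    if isinstance(data, HarmonizedInstrumentSet):
        be, se_e, bo, se_o = data.arrays()
        return be, se_e, bo, se_o, data.snp_ids
    if isinstance(data, pd.DataFrame):
        return (data["beta_exp"].to_numpy(float), data["se_exp"].to_numpy(float),
                data["beta_out"].to_numpy(float), data["se_out"].to_numpy(float),
                list(data["snp_id"]) if "snp_id" in data else
                [str(i) for i in range(len(data))])
    be, se_e, bo, se_o = (np.asarray(a, dtype=float) for a in data)
    return be, se_e, bo, se_o, [str(i) for i in range(be.size)]


def _finish(method, beta, se, k, **extra) -> MREstimate:
    pval = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
                      pval=pval, n_snp=int(k), **extra)


def _het(Q: float, df: int) -> tuple[float, float]:
    q_pval = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return q_pval, i2


# ---------------------------------------------------------------------------
# Wald ratio

def wald_ratio(rec: HarmonizedRecord, second_order: bool = False) -> MREstimate:
    """Per-SNP causal estimate beta_out/beta_exp.

    The default SE is the first-order delta approximation se_out/|beta_exp|;
    ``second_order`` adds the exposure-uncertainty term.
    """
    if rec.beta_exp == 0:
        raise AnalysisError(f"null instrument: beta_exp = 0 for {rec.snp_id}")
    beta = rec.beta_out / rec.beta_exp
    var = rec.se_out ** 2 / rec.beta_exp ** 2
    if second_order:
        var += rec.beta_out ** 2 * rec.se_exp ** 2 / rec.beta_exp ** 4
    return _finish("wald", beta, np.sqrt(var), 1)


# ---------------------------------------------------------------------------
# IVW

def _ivw_arrays(be, se_e, bo, se_o, model: str = "auto") -> dict:
    k = be.size
    if k == 0:
        raise AnalysisError("IVW needs at least one instrument")
    w = 1.0 / se_o ** 2                      # regression weights
    sxx = float(np.sum(w * be * be))
    if sxx == 0:
        raise AnalysisError("all exposure effects are zero")
    beta = float(np.sum(w * be * bo)) / sxx  # zero-intercept WLS slope
    se_fixed = sxx ** -0.5
    resid = bo - beta * be
    Q = float(np.sum(w * resid * resid))
    df = k - 1
    q_pval, i2 = _het(Q, df)
    scale = max(1.0, np.sqrt(Q / df)) if df > 0 else 1.0
    if model == "auto":
        model = "mre" if (df > 0 and q_pval < 0.05) else "fixed"
    if model == "fixed":
        se, method = se_fixed, "ivw_fe"
    elif model == "mre":
        se, method = se_fixed * scale, "ivw_mre"
    else:
        raise AnalysisError(f"unknown IVW model: {model}")
    return dict(method=method, beta=beta, se=se, k=k, Q=Q, Q_df=df,
                Q_pval=q_pval, I2=i2)


def ivw(data, model: str = "auto") -> MREstimate:
    """IVW combination of Wald ratios; a single SNP degenerates to its ratio."""
    be, se_e, bo, se_o, _ = _extract(data)
    r = _ivw_arrays(be, se_e, bo, se_o, model)
    return _finish(r["method"], r["beta"], r["se"], r["k"],
                   Q=r["Q"], Q_df=r["Q_df"], Q_pval=r["Q_pval"], I2=r["I2"])


# ---------------------------------------------------------------------------
# MR-Egger

def _egger_arrays(be, se_e, bo, se_o, use_t: bool = False) -> dict:
    k = be.size
    if k < 3:
        raise AnalysisError("insufficient instruments for Egger (need >= 3)")
    flip = np.where(be < 0, -1.0, 1.0)  # orient so beta_exp >= 0
    x, y = be * flip, bo * flip
    w = 1.0 / se_o ** 2
    sw, sx, sy = float(np.sum(w)), float(np.sum(w * x)), float(np.sum(w * y))
    sxx, sxy = float(np.sum(w * x * x)), float(np.sum(w * x * y))
    den = sw * sxx - sx * sx
    if den <= 0:
        raise AnalysisError("degenerate design: exposure effects identical")
    slope = (sw * sxy - sx * sy) / den
    intercept = (sxx * sy - sx * sxy) / den
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid * resid))
    sigma2 = max(1.0, rss / (k - 2))         # multiplicative over-dispersion
    se_slope = np.sqrt(sigma2 * sw / den)
    se_int = np.sqrt(sigma2 * sxx / den)
    if use_t:
        pfun = lambda z: float(2.0 * stats.t.sf(abs(z), k - 2))
    else:
        pfun = lambda z: float(2.0 * stats.norm.sf(abs(z)))
    q_pval, i2 = _het(rss, k - 2)
    return dict(slope=slope, se_slope=se_slope, slope_pval=pfun(slope / se_slope),
                intercept=intercept, se_int=se_int,
                int_pval=pfun(intercept / se_int), rss=rss, k=k,
                Q_pval=q_pval, I2=i2)


def mr_egger(data, use_t: bool = False) -> MREstimate:
    """Weighted regression with intercept; slope = causal effect, intercept =
    average directional pleiotropy."""
    be, se_e, bo, se_o, _ = _extract(data)
    r = _egger_arrays(be, se_e, bo, se_o, use_t=use_t)
    est = _finish("egger", r["slope"], r["se_slope"], r["k"],
                  intercept=float(r["intercept"]), intercept_se=float(r["se_int"]),
                  intercept_pval=float(r["int_pval"]),
                  Q=float(r["rss"]), Q_df=r["k"] - 2, Q_pval=r["Q_pval"], I2=r["I2"])
    est.pval = r["slope_pval"]
    return est


# ---------------------------------------------------------------------------
# Weighted median

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w               # cumulative midpoints
    return float(np.interp(0.5, p, r))


def weighted_median(data, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    The estimate interpolates the weight-cumulative distribution of sorted
    ratios at 0.5; the bootstrap redraws each beta from a normal with its SE
    and takes the SD of the recomputed medians.
    """
    be, se_e, bo, se_o, _ = _extract(data)
    k = be.size
    if k < 3:
        raise AnalysisError("insufficient instruments for weighted median (need >= 3)")
    w = be ** 2 / se_o ** 2
    est = _weighted_median(bo / be, w)
    rng = np.random.default_rng(seed)
    be_b = rng.normal(be, se_e, size=(n_boot, k))
    bo_b = rng.normal(bo, se_o, size=(n_boot, k))
    meds = np.empty(n_boot)
    for i in range(n_boot):
        with np.errstate(divide="ignore", invalid="ignore"):
            meds[i] = _weighted_median(bo_b[i] / be_b[i], be_b[i] ** 2 / se_o ** 2)
    se = float(np.std(meds, ddof=1))
    return _finish("weighted_median", est, se, k)


# ---------------------------------------------------------------------------
# Cochran Q

def cochran_q(data):
    """Heterogeneity of a set of estimates.

    ``data`` may be a HarmonizedInstrumentSet (Wald ratios with first-order
    SEs) or a sequence of (beta, se) pairs.  Returns (Q, df, pval, I2) with
    Q about the inverse-variance pooled mean.
    """
    if isinstance(data, HarmonizedInstrumentSet):
        be, se_e, bo, se_o = data.arrays()
        b, s = bo / be, se_o / np.abs(be)
    else:
        arr = np.asarray(list(data), dtype=float)
        b, s = arr[:, 0], arr[:, 1]
    if b.size < 2:
        raise AnalysisError("Cochran Q needs at least two estimates")
    w = 1.0 / s ** 2
    pooled = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    pval, i2 = _het(Q, df)
    return Q, df, pval, i2


# ---------------------------------------------------------------------------
# MR-PRESSO

def _loo_slopes(be, bo, w):
    """Leave-one-out zero-intercept WLS slopes, vectorised over rows."""
    sxy = np.sum(w * be * bo, axis=-1, keepdims=True)
    sxx = np.sum(w * be * be, axis=-1, keepdims=True)
    return (sxy - w * be * bo) / (sxx - w * be * be)


def mr_presso(data, n_sim: int = 1000, seed: int = 0, sig: float = 0.05) -> PressoResult:
    """MR-PRESSO global heterogeneity test, outlier search and correction.

    The observed statistic is the weighted residual sum of squares of each
    SNP about its leave-one-out IVW prediction.  Its null distribution is
    built by redrawing effects from their sampling normals around the
    leave-one-out fit; p-values use the add-one permutation estimator so they
    are never exactly zero.  Per-SNP outlier p-values are Bonferroni-corrected
    by k and reported when the global test is significant; the corrected
    estimate is IVW on the remaining SNPs, and the distortion test compares
    the observed corrected-vs-raw shift to the shift from removing random
    SNP subsets of the same size.
    """
    be, se_e, bo, se_o, snp_ids = _extract(data)
    k = be.size
    if k < 4:
        raise AnalysisError("insufficient instruments for PRESSO (need >= 4)")
    w = 1.0 / se_o ** 2
    slopes = _loo_slopes(be, bo, w)
    obs_terms = w * (bo - slopes * be) ** 2
    rss_obs = float(np.sum(obs_terms))

    rng = np.random.default_rng(seed)
    be_s = rng.normal(be, se_e, size=(n_sim, k))
    bo_s = rng.normal(slopes * be, se_o, size=(n_sim, k))
    slopes_s = _loo_slopes(be_s, bo_s, w)
    sim_terms = w * (bo_s - slopes_s * be_s) ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    raw = ivw((be, se_e, bo, se_o), model="auto")

    outliers: list[tuple[str, float]] = []
    corrected = None
    distortion_pval = None
    if global_pval < sig:
        p_snp = (1 + np.sum(sim_terms >= obs_terms, axis=0)) / (n_sim + 1)
        p_bonf = np.minimum(1.0, k * p_snp)
        for j in np.flatnonzero(p_bonf < sig):
            outliers.append((snp_ids[j], float(p_bonf[j])))
        if outliers and len(outliers) < k:
            out_idx = {snp_ids.index(s) for s, _ in outliers}
            keep = np.array([j for j in range(k) if j not in out_idx])
            corrected = ivw((be[keep], se_e[keep], bo[keep], se_o[keep]), model="auto")
            corrected.method = "presso_outlier_corrected"
            if raw.beta != 0:
                d_obs = (corrected.beta - raw.beta) / raw.beta
                n_out = len(outliers)
                d_sim = np.empty(n_sim)
                for i in range(n_sim):
                    drop = rng.choice(k, size=n_out, replace=False)
                    keep_i = np.setdiff1d(np.arange(k), drop)
                    r = _ivw_arrays(be[keep_i], se_e[keep_i], bo[keep_i],
                                    se_o[keep_i], model="fixed")
                    d_sim[i] = (r["beta"] - raw.beta) / raw.beta
                distortion_pval = float(
                    (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))
    raw.method = "presso_raw"
    return PressoResult(global_rss_obs=rss_obs, global_pval=global_pval,
                        outlier_snps=outliers, distortion_pval=distortion_pval,
                        corrected=corrected, raw=raw, n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# scikit-learn style estimator classes

class _MRBase(BaseEstimator):
    """Shared fit plumbing: accepts a HarmonizedInstrumentSet, a DataFrame
    with beta_exp/se_exp/beta_out/se_out columns, or a 4-tuple of arrays."""

    def fit(self, X, y=None):
        est = self._estimate(X)
        self.estimate_ = est
        self.beta_ = est.beta
        self.se_ = est.se
        self.pval_ = est.pval
        self.ci_ = (est.ci_low, est.ci_high)
        self.n_snp_ = est.n_snp
        return self

    def predict(self, X):
        """Predicted outcome effects for exposure effects ``X`` (array-like)."""
        x = np.asarray(X, dtype=float)
        intercept = getattr(self.estimate_, "intercept", None) or 0.0
        return intercept + self.beta_ * x


class IVWEstimator(_MRBase):
    """Inverse-variance-weighted MR estimator.

    Parameters
    ----------
    model : {"auto", "fixed", "mre"}
        ``auto`` uses multiplicative random effects iff the Cochran Q p-value
        falls below 0.05.
    """

    def __init__(self, model: str = "auto"):
        self.model = model

    def _estimate(self, X):
        return ivw(X, model=self.model)

    def fit(self, X, y=None):
        super().fit(X, y)
        est = self.estimate_
        self.Q_, self.Q_df_, self.Q_pval_, self.I2_ = est.Q, est.Q_df, est.Q_pval, est.I2
        return self


class EggerEstimator(_MRBase):
    """MR-Egger regression; the fitted intercept estimates directional
    pleiotropy and its test p-value is ``intercept_pval_``."""

    def __init__(self, use_t: bool = False):
        self.use_t = use_t

    def _estimate(self, X):
        return mr_egger(X, use_t=self.use_t)

    def fit(self, X, y=None):
        super().fit(X, y)
        est = self.estimate_
        self.intercept_ = est.intercept
        self.intercept_se_ = est.intercept_se
        self.intercept_pval_ = est.intercept_pval
        return self


class WeightedMedianEstimator(_MRBase):
    def __init__(self, n_boot: int = 1000, random_state: int = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def _estimate(self, X):
        return weighted_median(X, n_boot=self.n_boot, seed=self.random_state)


class MRPressoEstimator(_MRBase):
    """MR-PRESSO: after ``fit``, ``result_`` holds the global/outlier/
    distortion tests and ``estimate_`` the outlier-corrected IVW when outliers
    were found (the raw IVW otherwise)."""

    def __init__(self, n_sim: int = 1000, random_state: int = 0, sig: float = 0.05):
        self.n_sim = n_sim
        self.random_state = random_state
        self.sig = sig

    def _estimate(self, X):
        self.result_ = mr_presso(X, n_sim=self.n_sim, seed=self.random_state,
                                 sig=self.sig)
        return self.result_.corrected or self.result_.raw

    def fit(self, X, y=None):
        super().fit(X, y)
        self.global_pval_ = self.result_.global_pval
        self.outlier_snps_ = self.result_.outlier_snps
        return self
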