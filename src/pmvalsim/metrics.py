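"""Performance measures for one simulated external-validation cohort.

Each estimator returns a :class:`MetricResult` carrying the point
estimate, its standard error and a 95% confidence interval.  Following
standard practice for validation studies, every CI is Wald-type
(estimate +/- 1.96 * SE) on the original scale, except the O/E ratio
whose CI is built on the log scale and back-transformed.

Measures:

* C-statistic (area under the ROC curve) with the DeLong variance
  estimator.
* Calibration slope: ML logistic refit of outcomes on the linear
  predictor; slope 1 is ideal, < 1 indicates predictions too extreme.
* Calibration-in-the-large: intercept of a logistic fit with the LP as
  a fixed offset; 0 is ideal.
* O/E ratio: mean observed outcome over mean predicted probability.
* Integrated calibration index (ICI): mean absolute gap between a
  locally weighted calibration curve and the 45-degree line.
* Net benefit at a decision threshold p_t.

Population-level helpers (:func:`true_c_statistic`,
:func:`sigma_from_target_c`) support scenario design, e.g. recovering
the LP standard deviation from a published C-statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import rankdata

from .datagen import (
    Calibration,
    CalibrationParams,
    LPDistribution,
    ValidationDataset,
    _as_calibration,
)

__all__ = [
    "MetricResult",
    "NetBenefitSpec",
    "SmootherConfig",
    "METRIC_NAMES",
    "c_statistic",
    "calibration_slope",
    "calibration_in_the_large",
    "oe_ratio",
    "ici",
    "net_benefit",
    "net_benefit_components",
    "true_c_statistic",
    "sigma_from_target_c",
]

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

METRIC_NAMES = (
    "c_statistic",
    "cal_slope",
    "cal_in_large",
    "oe_ratio",
    "ici",
    "net_benefit",
)


@dataclass(frozen=True)
class MetricResult:
    """One performance estimate with SE and 95% CI.

    ``ci_scale`` is ``"original"`` (ci_upper - ci_lower = 2*1.96*se) or
    ``"log"`` (O/E: log(ci_upper) - log(ci_lower) = 2*1.96*se, with
    ``se`` on the log scale).  ``converged=False`` flags estimates that
    could not be computed reliably (separation, degenerate outcome
    vectors, smoother failure); their fields are NaN and they are
    excluded from precision averages upstream.
    """

    name: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    ci_scale: str = "original"
    converged: bool = True

    @property
    def ci_width(self) -> float:
        """CI width on the original (reporting) scale."""
        return self.ci_upper - self.ci_lower

    @property
    def log_ci_width(self) -> float:
        """CI width on the log scale (only meaningful for ci_scale='log')."""
        if self.ci_scale != "log":
            raise ValueError(f"{self.name} CI is not on the log scale")
        return math.log(self.ci_upper) - math.log(self.ci_lower)


def _failed(name: str, ci_scale: str = "original") -> MetricResult:
    nan = float("nan")
    return MetricResult(name, nan, nan, nan, nan, ci_scale=ci_scale, converged=False)


def _wald(name: str, est: float, se: float, converged: bool = True) -> MetricResult:
    return MetricResult(
        name, float(est), float(se), float(est - Z95 * se), float(est + Z95 * se),
        ci_scale="original", converged=converged,
    )


# --------------------------------------------------------------------------
# C-statistic (AUC) with DeLong variance
# --------------------------------------------------------------------------

def _auc_midrank(pos: np.ndarray, neg: np.ndarray):
    """AUC and DeLong placement components via midranks, O(n log n)."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    r = rankdata(combined)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r[:m] - r_pos) / n          # placements of events among non-events
    v01 = 1.0 - (r[m:] - r_neg) / m    # placements of non-events among events
    return auc, v10, v01


def c_statistic(data: ValidationDataset) -> MetricResult:
    """Concordance probability (ties counted 1/2) with DeLong SE.

    The Wald CI is stored untruncated so that the width identity
    ci_width == 2 * 1.96 * se holds; reporting layers may clip the
    bounds to [0, 1] for display.
    """
    y = data.outcomes
    pos = data.pred_prob[y == 1]
    neg = data.pred_prob[y == 0]
    if pos.size == 0 or neg.size == 0:
        return _failed("c_statistic")
    auc, v10, v01 = _auc_midrank(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    se = math.sqrt(s10 / pos.size + s01 / neg.size)
    return _wald("c_statistic", auc, se)


# --------------------------------------------------------------------------
# Calibration slope and calibration-in-the-large (logistic refits)
# --------------------------------------------------------------------------

# Wald inference is meaningless under (near-)separation; these bounds flag it.
_MAX_ABS_COEF = 20.0
_MAX_SE = 100.0


def _glm_logistic(y, X, offset=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
        try:
            res = model.fit(maxiter=100)
        except Exception:
            return None
        if not getattr(res, "converged", True):
            return None
        if np.any(~np.isfinite(res.params)) or np.any(~np.isfinite(res.bse)):
            return None
        return res


def calibration_slope(data: ValidationDataset) -> MetricResult:
    """ML logistic fit of Y on (intercept + LP); returns the LP coefficient."""
    lp = data.lp_values
    if np.ptp(lp) == 0.0:
        raise ValueError("calibration slope is unidentifiable: LP has zero variance")
    y = data.outcomes
    if y.min() == y.max():
        return _failed("cal_slope")
    X = np.column_stack([np.ones(data.n), lp])
    res = _glm_logistic(y, X)
    if res is None:
        return _failed("cal_slope")
    slope, se = res.params[1], res.bse[1]
    if abs(slope) > _MAX_ABS_COEF or se > _MAX_SE:
        return _failed("cal_slope")
    return _wald("cal_slope", slope, se)


def calibration_in_the_large(data: ValidationDataset) -> MetricResult:
    """Intercept of a logistic fit with the LP as a fixed offset (slope held at 1)."""
    y = data.outcomes
    if y.min() == y.max():
        return _failed("cal_in_large")
    X = np.ones((data.n, 1))
    res = _glm_logistic(y, X, offset=data.lp_values)
    if res is None:
        return _failed("cal_in_large")
    intercept, se = res.params[0], res.bse[0]
    if abs(intercept) > _MAX_ABS_COEF or se > _MAX_SE:
        return _failed("cal_in_large")
    return _wald("cal_in_large", intercept, se)


# --------------------------------------------------------------------------
# O/E ratio
# --------------------------------------------------------------------------

def oe_ratio(data: ValidationDataset) -> MetricResult:
    """Observed over expected events; CI derived on the log scale.

    se(ln O/E) = sqrt((1 - O) / (N * O)), the binomial approximation
    treating the expected (mean predicted) probability as fixed.
    """
    o = float(data.outcomes.mean())
    if o == 0.0:
        return _failed("oe_ratio", ci_scale="log")
    e = float(data.pred_prob.mean())
    est = o / e
    se_log = math.sqrt((1.0 - o) / (data.n * o))
    return MetricResult(
        "oe_ratio",
        est,
        se_log,
        est * math.exp(-Z95 * se_log),
        est * math.exp(Z95 * se_log),
        ci_scale="log",
    )


# --------------------------------------------------------------------------
# Integrated calibration index
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SmootherConfig:
    """Locally weighted calibration curve and bootstrap settings for the ICI.

    ``frac`` is the lowess span; ``delta_frac`` the lowess linear-
    interpolation window as a fraction of the predicted-risk range (a
    pure speed device); ``n_boot`` bootstrap replicates for the SE;
    ``ci_method`` 'normal' (Wald with bootstrap SE, the default, keeping
    the uniform estimate +/- 1.96*SE convention) or 'percentile'.
    """

    frac: float = 0.75
    delta_frac: float = 0.01
    min_n: int = 50
    n_boot: int = 200
    ci_method: str = "normal"


def _smoothed_calibration(y, p, config: SmootherConfig) -> np.ndarray:
    """Lowess estimate of P(Y=1 | p-hat) evaluated at each p-hat, clipped to [0,1]."""
    delta = config.delta_frac * (p.max() - p.min())
    fitted = sm.nonparametric.lowess(y, p, frac=config.frac, it=0, delta=delta)
    return np.clip(np.interp(p, fitted[:, 0], fitted[:, 1]), 0.0, 1.0)


def _ici_point(y, p, config: SmootherConfig) -> float:
    return float(np.mean(np.abs(_smoothed_calibration(y, p, config) - p)))


def ici(
    data: ValidationDataset,
    config: SmootherConfig = SmootherConfig(),
    rng: Optional[np.random.Generator] = None,
) -> MetricResult:
    """Mean absolute distance between the smoothed calibration curve and p-hat.

    The SE comes from a nonparametric bootstrap (resampling
    participants); the CI is Wald by default or percentile on request.
    """
    y, p = data.outcomes, data.pred_prob
    if data.n < config.min_n:
        raise ValueError(f"ICI needs at least {config.min_n} participants, got {data.n}")
    if y.min() == y.max():
        return _failed("ici")
    if rng is None:
        rng = np.random.default_rng(0)
    try:
        est = _ici_point(y, p, config)
        boots = np.empty(config.n_boot)
        for b in range(config.n_boot):
            idx = rng.integers(0, data.n, size=data.n)
            boots[b] = _ici_point(y[idx], p[idx], config)
    except Exception:
        return _failed("ici")
    se = float(boots.std(ddof=1))
    if config.ci_method == "normal":
        return _wald("ici", est, se)
    if config.ci_method == "percentile":
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return MetricResult("ici", est, se, float(lo), float(hi), converged=True)
    raise ValueError(f"unknown ci_method {config.ci_method!r}")


# --------------------------------------------------------------------------
# Net benefit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetBenefitSpec:
    """Decision threshold for net benefit; classify positive when p-hat >= threshold."""

    threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def net_benefit_components(data: ValidationDataset, spec: NetBenefitSpec):
    """(sensitivity, specificity, prevalence) at the threshold; NaN when undefined."""
    positive = data.pred_prob >= spec.threshold
    y = data.outcomes.astype(bool)
    n_ev = y.sum()
    n_ne = data.n - n_ev
    sens = float((positive & y).sum() / n_ev) if n_ev else float("nan")
    spec_ = float((~positive & ~y).sum() / n_ne) if n_ne else float("nan")
    return sens, spec_, float(n_ev / data.n)


def net_benefit(data: ValidationDataset, spec: NetBenefitSpec = NetBenefitSpec()) -> MetricResult:
    """NB = sens*prev - (1-spec)*(1-prev)*pt/(1-pt) at threshold pt.

    Computed as the mean of per-participant contributions
    1(p>=pt)*Y - 1(p>=pt)*(1-Y)*pt/(1-pt), which is algebraically
    identical to the sensitivity/specificity form but yields an SE
    directly (sample SD of contributions / sqrt(N)).
    """
    pt = spec.threshold
    positive = data.pred_prob >= pt
    y = data.outcomes.astype(float)
    contrib = positive * (y - (1.0 - y) * pt / (1.0 - pt))
    est = float(contrib.mean())
    se = float(contrib.std(ddof=1) / math.sqrt(data.n)) if data.n > 1 else 0.0
    return _wald("net_benefit", est, se)


# --------------------------------------------------------------------------
# Population-level helpers for scenario design
# --------------------------------------------------------------------------

def true_c_statistic(
    lp: LPDistribution,
    calib: Calibration = None,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo population C-statistic implied by the generator.

    Draws ``n_mc`` (LP, outcome) pairs and computes the concordance of
    the LP between events and non-events (predictions are monotone in
    the LP, so the AUC is identical).
    """
    c = _as_calibration(calib) if calib is not None else CalibrationParams()
    if lp.sigma == 0.0:
        return 0.5
    rng = np.random.default_rng(seed)
    lps = rng.normal(lp.mu, lp.sigma, size=n_mc)
    y = rng.random(n_mc) < expit(c.gamma + c.slope * lps)
    pos, neg = lps[y], lps[~y]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    auc, _, _ = _auc_midrank(pos, neg)
    return float(auc)


def sigma_from_target_c(
    target_c: float,
    lp_mu: float,
    tol: float = 0.002,
    n_mc: int = 400_000,
    seed: int = 0,
) -> float:
    """Infer the LP standard deviation from a reported C-statistic.

    Root-finds sigma >= 0 such that the population C-statistic of a
    well-calibrated model with LP ~ Normal(lp_mu, sigma^2) matches
    ``target_c``.  Common random numbers (one fixed draw of normals and
    uniforms, re-scaled per candidate sigma) make the objective smooth
    and the answer deterministic.
    """
    if not 0.5 < target_c < 1.0:
        raise ValueError("target_c must be in (0.5, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_mc)
    u = rng.random(n_mc)

    def c_of(sigma: float) -> float:
        lps = lp_mu + sigma * z
        y = u < expit(lps)
        pos, neg = lps[y], lps[~y]
        auc, _, _ = _auc_midrank(pos, neg)
        return float(auc)

    def f(sigma: float) -> float:
        return c_of(sigma) - target_c

    hi = 2.0
    while f(hi) < 0.0:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError(f"target C-statistic {target_c} unattainable for mu={lp_mu}")
    sigma = brentq(f, 0.0, hi, xtol=1e-4)
    if abs(f(sigma)) > tol:
        raise RuntimeError("sigma root-find did not reach the C-statistic tolerance")
    return float(sigma)
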