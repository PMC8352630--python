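"""Validation-population model and synthetic cohort generation.

A logistic prediction model assigns each individual a linear predictor
(LP, on the log-odds scale).  For planning an external validation study
the LP in the target population is modelled as LP ~ Normal(mu, sigma^2),
and the *true* outcome risk is tied to the LP through a calibration model

    logit(p) = gamma + S * LP

so that (gamma=0, S=1) means the model is perfectly calibrated, S < 1
means predictions are too extreme (typical of overfitting), and a
non-zero gamma shifts the overall event rate.  This module draws
synthetic validation cohorts from that data-generating process and
provides the deterministic quadrature helpers (expected event
proportion, gamma-solving) needed to design scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "LPDistribution",
    "CalibrationParams",
    "MiscalibrationFactor",
    "ScenarioSpec",
    "ValidationDataset",
    "base_probability",
    "expected_event_proportion",
    "solve_gamma",
    "cohort_size_from_events",
    "generate_dataset",
]


@dataclass(frozen=True)
class LPDistribution:
    """Distribution of the model's linear predictor in the validation population.

    Parameters
    ----------
    mu : float
        Mean of the LP on the log-odds scale.  ``expit(mu)`` is the
        "base probability": the outcome risk of an individual at the
        mean LP (and the event proportion itself when ``sigma == 0``).
    sigma : float
        Standard deviation of the LP (log-odds scale), >= 0.  Wider LP
        distributions imply better discrimination (higher C-statistic).
    family : str
        Distribution family; only ``"normal"`` is implemented.  The
        field exists as an extension point for discrete/beta/gamma
        shaped linear predictors.
    """

    mu: float
    sigma: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.sigma)):
            raise ValueError("mu and sigma must be finite")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.family != "normal":
            raise NotImplementedError(
                f"LP family {self.family!r} not implemented (only 'normal')"
            )

    @property
    def base_probability(self) -> float:
        return float(expit(self.mu))

    @classmethod
    def from_base_probability(cls, p: float, sigma: float) -> "LPDistribution":
        if not 0.0 < p < 1.0:
            raise ValueError(f"base probability must be in (0, 1), got {p}")
        return cls(mu=float(logit(p)), sigma=sigma)


@dataclass(frozen=True)
class CalibrationParams:
    """True calibration model ``logit(p) = gamma + slope * LP``.

    ``(gamma=0, slope=1)`` is perfect calibration.
    """

    gamma: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gamma) and math.isfinite(self.slope)):
            raise ValueError("gamma and slope must be finite")


@dataclass(frozen=True)
class MiscalibrationFactor:
    """Multiplier m applied to the LP in the outcome generator.

    Outcomes are drawn with probability ``expit(m * LP)`` while
    predictions still use the original LP, so the deployed model is
    deliberately miscalibrated in truth; ``m == 1`` recovers the
    perfectly calibrated generator.  Equivalent to
    ``CalibrationParams(gamma=0, slope=m)``.
    """

    m: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and self.m > 0):
            raise ValueError(f"miscalibration factor must be finite and > 0, got {self.m}")

    def as_calibration(self) -> CalibrationParams:
        return CalibrationParams(gamma=0.0, slope=self.m)


Calibration = Union[CalibrationParams, MiscalibrationFactor]


def _as_calibration(calib: Calibration) -> CalibrationParams:
    if isinstance(calib, MiscalibrationFactor):
        return calib.as_calibration()
    return calib


def base_probability(lp: LPDistribution) -> float:
    """Outcome probability at the mean LP: ``1 / (1 + exp(-mu))``."""
    return lp.base_probability


@lru_cache(maxsize=8)
def _hermgauss(n_nodes: int):
    # physicists' Hermite nodes; transform below maps them to N(mu, sigma^2)
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    return t, w / math.sqrt(math.pi)


def expected_event_proportion(
    lp: LPDistribution,
    calib: Calibration = CalibrationParams(),
    n_nodes: int = 150,
) -> float:
    """Marginal event proportion E[expit(gamma + S*LP)] under LP ~ N(mu, sigma^2).

    Computed by Gauss-Hermite quadrature (deterministic, abs. error well
    below 1e-6 at the default 150 nodes for the sigma range of interest),
    so gamma-solving and events-to-N conversion are exactly reproducible.
    """
    c = _as_calibration(calib)
    if not all(map(math.isfinite, (lp.mu, lp.sigma, c.gamma, c.slope))):
        raise ValueError("non-finite scenario parameters")
    if lp.sigma == 0.0:
        return float(expit(c.gamma + c.slope * lp.mu))
    t, w = _hermgauss(n_nodes)
    x = lp.mu + math.sqrt(2.0) * lp.sigma * t
    return float(np.sum(w * expit(c.gamma + c.slope * x)))


def solve_gamma(
    lp: LPDistribution,
    slope: float,
    target_proportion: float,
    tol: float = 1e-9,
) -> float:
    """Find gamma so the expected event proportion equals ``target_proportion``.

    The expectation is strictly increasing in gamma, so a bracketed
    root-find (Brent) applies.  Raises if the root cannot be bracketed.
    """
    if not 0.0 < target_proportion < 1.0:
        raise ValueError("target_proportion must be in (0, 1)")
    if lp.sigma == 0.0:
        return float(logit(target_proportion) - slope * lp.mu)

    def f(g: float) -> float:
        return expected_event_proportion(lp, CalibrationParams(g, slope)) - target_proportion

    # start from the sigma=0 closed form and expand symmetrically
    g0 = float(logit(target_proportion) - slope * lp.mu)
    half = 2.0 * (1.0 + abs(slope) * lp.sigma)
    lo, hi = g0 - half, g0 + half
    for _ in range(40):
        if f(lo) < 0.0 < f(hi):
            break
        lo -= half
        hi += half
    else:
        raise RuntimeError(
            f"could not bracket gamma for target proportion {target_proportion}"
        )
    gamma = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(f(gamma)) > 1e-6:
        raise RuntimeError("gamma root-find did not reach tolerance 1e-6")
    return float(gamma)


def cohort_size_from_events(
    expected_events: int,
    lp: LPDistribution,
    calib: Calibration = CalibrationParams(),
    basis: str = "base_probability",
) -> int:
    """Convert a desired expected event count E into a cohort size N.

    ``basis="base_probability"`` divides by ``expit(mu)`` (the planning
    convention of defining scenarios by base probability and E);
    ``basis="event_proportion"`` divides by the marginal event
    proportion under the generator, so the realised mean event count
    matches E even when sigma > 0 or the generator is miscalibrated.
    N is rounded up so the expected event count is at least E.
    """
    if expected_events < 1:
        raise ValueError("expected_events must be >= 1")
    if basis == "base_probability":
        p = lp.base_probability
    elif basis == "event_proportion":
        p = expected_event_proportion(lp, calib)
    else:
        raise ValueError(f"unknown events basis {basis!r}")
    return int(math.ceil(expected_events / p))


@dataclass(frozen=True)
class ScenarioSpec:
    """One fully specified simulation scenario.

    Exactly one of ``n`` (cohort size) or ``expected_events`` must be
    given; in the latter case N is derived as ceil(E / p) with p chosen
    by ``events_basis`` (see :func:`cohort_size_from_events`).
    """

    lp: LPDistribution
    calib: Calibration = field(default_factory=CalibrationParams)
    n: Optional[int] = None
    expected_events: Optional[int] = None
    seed: int = 0
    events_basis: str = "base_probability"

    def __post_init__(self) -> None:
        if (self.n is None) == (self.expected_events is None):
            raise ValueError("exactly one of n / expected_events must be given")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.expected_events is not None and self.expected_events < 1:
            raise ValueError("expected_events must be >= 1")
        if self.events_basis not in ("base_probability", "event_proportion"):
            raise ValueError(f"unknown events basis {self.events_basis!r}")

    @property
    def cohort_size(self) -> int:
        if self.n is not None:
            return self.n
        return cohort_size_from_events(
            self.expected_events, self.lp, self.calib, basis=self.events_basis
        )

    @property
    def calibration(self) -> CalibrationParams:
        return _as_calibration(self.calib)

    def with_n(self, n: int) -> "ScenarioSpec":
        return replace(self, n=n, expected_events=None)

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)

    # --- flat key=value serialization ------------------------------------
    def to_config(self) -> str:
        c = self.calibration
        lines = [
            f"lp_mu = {self.lp.mu!r}",
            f"lp_sigma = {self.lp.sigma!r}",
            f"gamma = {c.gamma!r}",
            f"slope = {c.slope!r}",
            f"seed = {self.seed}",
            f"events_basis = {self.events_basis}",
        ]
        if self.n is not None:
            lines.append(f"n = {self.n}")
        else:
            lines.append(f"expected_events = {self.expected_events}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ScenarioSpec":
        kv: dict = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        lp = LPDistribution(mu=float(kv["lp_mu"]), sigma=float(kv["lp_sigma"]))
        calib = CalibrationParams(
            gamma=float(kv.get("gamma", 0.0)), slope=float(kv.get("slope", 1.0))
        )
        return cls(
            lp=lp,
            calib=calib,
            n=int(kv["n"]) if "n" in kv else None,
            expected_events=int(kv["expected_events"]) if "expected_events" in kv else None,
            seed=int(kv.get("seed", 0)),
            events_basis=kv.get("events_basis", "base_probability"),
        )


@dataclass(frozen=True)
class ValidationDataset:
    """One simulated validation cohort.

    ``lp_values`` holds each participant's linear predictor as produced
    by the prediction model, ``pred_prob`` the corresponding predicted
    probability ``expit(LP)``, and ``outcomes`` the true binary outcome
    (drawn from the possibly miscalibrated generator).
    """

    lp_values: np.ndarray
    pred_prob: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        lp = np.asarray(self.lp_values, dtype=float)
        p = np.asarray(self.pred_prob, dtype=float)
        y = np.asarray(self.outcomes)
        object.__setattr__(self, "lp_values", lp)
        object.__setattr__(self, "pred_prob", p)
        object.__setattr__(self, "outcomes", np.asarray(y, dtype=np.int8))
        if not (lp.shape == p.shape == y.shape) or lp.ndim != 1 or lp.size < 1:
            raise ValueError("lp_values, pred_prob, outcomes must be 1-d, same length >= 1")
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError("pred_prob must lie strictly in (0, 1)")
        if not np.allclose(p, expit(lp), atol=1e-12):
            raise ValueError("pred_prob must equal expit(lp_values)")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")

    @property
    def n(self) -> int:
        return int(self.lp_values.size)

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lp": self.lp_values, "pred_prob": self.pred_prob, "outcome": self.outcomes}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ValidationDataset":
        df = pd.read_csv(path)
        return cls(
            lp_values=df["lp"].to_numpy(),
            pred_prob=df["pred_prob"].to_numpy(),
            outcomes=df["outcome"].to_numpy(),
        )


def generate_dataset(
    spec: ScenarioSpec, rng: Optional[np.random.Generator] = None
) -> ValidationDataset:
    """Draw one validation cohort under the scenario's generating process.

    LP_i ~ Normal(mu, sigma^2); predictions p_i = expit(LP_i); outcomes
    Y_i ~ Bernoulli(expit(gamma + S * LP_i)).  When ``rng`` is omitted a
    fresh generator is seeded from ``spec.seed``, so identical specs
    yield bit-identical datasets.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.cohort_size
    c = spec.calibration
    lp_values = rng.normal(spec.lp.mu, spec.lp.sigma, size=n)
    true_prob = expit(c.gamma + c.slope * lp_values)
    outcomes = (rng.random(n) < true_prob).astype(np.int8)
    return ValidationDataset(
        lp_values=lp_values, pred_prob=expit(lp_values), outcomes=outcomes
    )
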