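"""Iterative simulation-based sample-size search.

Given the anticipated LP distribution, the assumed true calibration of
the model, and a target mean 95% CI width for each performance measure
of interest, find the smallest validation-study size N at which every
target is met.  Mean CI widths behave like a/sqrt(N) to good accuracy,
so the search runs a small geometric ladder of pilot simulations, fits
that curve to propose a candidate N per metric, and then walks locally
(steps of 1% of the proposal) to the first N whose simulated mean
width meets the target.  Every reported N is verified by direct
simulation at that N; the curve only accelerates the search.

The result is deterministic given (targets, reps, seed): each
candidate N is evaluated with a seed schedule derived from the root
seed and N, so re-evaluations of the same N agree exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datagen import (
    Calibration,
    CalibrationParams,
    LPDistribution,
    MiscalibrationFactor,
    ScenarioSpec,
    expected_event_proportion,
    solve_gamma,
    _as_calibration,
)
from .engine import PrecisionSummary, run_precision

__all__ = [
    "PrecisionTargets",
    "MetricRequirement",
    "SampleSizeResult",
    "TargetUnreachableError",
    "WidthCurve",
    "model_width_curve",
    "find_sample_size",
]

# target key -> (metric evaluated, scale its width is measured on)
_TARGET_MAP = {
    "c_statistic": ("c_statistic", "original"),
    "cal_slope": ("cal_slope", "original"),
    "cal_in_large": ("cal_in_large", "original"),
    "oe_log": ("oe_ratio", "log"),
    "ici": ("ici", "original"),
    "net_benefit": ("net_benefit", "original"),
}


@dataclass(frozen=True)
class PrecisionTargets:
    """Target mean 95% CI widths, one per measure of interest.

    All targets are on the measure's reporting scale except ``oe_log``,
    the width of the CI for ln(O/E) (the scale the O/E interval is
    constructed on).  At least one target must be set.
    """

    c_statistic: Optional[float] = None
    cal_slope: Optional[float] = None
    cal_in_large: Optional[float] = None
    oe_log: Optional[float] = None
    ici: Optional[float] = None
    net_benefit: Optional[float] = None

    def __post_init__(self) -> None:
        items = self.items()
        if not items:
            raise ValueError("at least one precision target must be specified")
        for key, width, _, _ in items:
            if not (math.isfinite(width) and width > 0):
                raise ValueError(f"target width for {key} must be > 0, got {width}")

    def items(self) -> List[Tuple[str, float, str, str]]:
        """(target key, width, metric name, width scale) for each set target."""
        out = []
        for key, (metric, scale) in _TARGET_MAP.items():
            width = getattr(self, key)
            if width is not None:
                out.append((key, float(width), metric, scale))
        return out

    def metric_names(self) -> Tuple[str, ...]:
        return tuple(metric for _, _, metric, _ in self.items())


class TargetUnreachableError(RuntimeError):
    """A precision target could not be met below the sample-size cap."""

    def __init__(self, message: str, trace: List[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class WidthCurve:
    """Least-squares fit of width = a / sqrt(N) to pilot evaluations."""

    a: float

    def width_at(self, n: int) -> float:
        return self.a / math.sqrt(n)

    def propose(self, target_width: float) -> int:
        return int(math.ceil((self.a / target_width) ** 2))


def model_width_curve(points: Sequence[Tuple[int, float]]) -> WidthCurve:
    """Fit a/sqrt(N) by least squares on (N, width) pilot points."""
    if len(points) < 3:
        raise ValueError("need at least 3 pilot points")
    ns = np.asarray([p[0] for p in points], dtype=float)
    ws = np.asarray([p[1] for p in points], dtype=float)
    if np.any(ws <= 0) or np.any(ns <= 0):
        raise ValueError("pilot widths and sizes must be positive")
    x = 1.0 / np.sqrt(ns)
    a = float(np.sum(ws * x) / np.sum(x * x))
    return WidthCurve(a=a)


@dataclass(frozen=True)
class MetricRequirement:
    n_required: int
    events_required: float
    target_width: float
    achieved_width: float
    mc_se_of_width: float


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the iterative search.

    ``n_required`` is the overall answer (the maximum over targeted
    measures); ``events_required`` the implied expected event count
    (N x marginal event proportion under the generator).  The full
    evaluation trace is retained for audit.
    """

    n_required: int
    events_required: float
    driving_metric: str
    per_metric: Dict[str, MetricRequirement]
    event_proportion: float
    reps: int
    seed: int
    trace: List[dict] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)

    def to_dict(self) -> dict:
        return {
            "n_required": self.n_required,
            "events_required": self.events_required,
            "driving_metric": self.driving_metric,
            "event_proportion": self.event_proportion,
            "reps": self.reps,
            "seed": self.seed,
            "per_metric": {
                k: {
                    "n_required": v.n_required,
                    "events_required": v.events_required,
                    "target_width": v.target_width,
                    "achieved_width": v.achieved_width,
                    "mc_se_of_width": v.mc_se_of_width,
                }
                for k, v in self.per_metric.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _candidate_seed(seed: int, n: int) -> int:
    """Seed for evaluating candidate N; same N -> same datasets, any order."""
    return int(np.random.SeedSequence((seed, n)).generate_state(1)[0] % 2**31)


def find_sample_size(
    lp: LPDistribution,
    calib: Calibration,
    targets: PrecisionTargets,
    reps: int = 500,
    seed: int = 0,
    start_n: int = 100,
    cap_n: int = 1_000_000,
    nb_threshold: float = 0.1,
    target_proportion: Optional[float] = None,
    pilot_factor: int = 4,
    n_pilots: int = 3,
    max_evals_per_metric: int = 60,
) -> SampleSizeResult:
    """Minimum validation-study size meeting every precision target.

    If ``target_proportion`` is given, the calibration intercept gamma
    is first re-solved (holding the assumed slope fixed) so the
    marginal event proportion equals it; the search then treats the
    generator as fixed.  The search domain is [start_n, cap_n]; a
    target that is not met at ``cap_n`` raises
    :class:`TargetUnreachableError` with the evaluation trace attached.
    """
    c = _as_calibration(calib)
    if target_proportion is not None:
        c = CalibrationParams(
            gamma=solve_gamma(lp, c.slope, target_proportion), slope=c.slope
        )
    pi = expected_event_proportion(lp, c)
    if start_n < 2:
        raise ValueError("start_n must be >= 2")

    trace: List[dict] = []
    width_cache: Dict[int, PrecisionSummary] = {}
    all_metrics = targets.metric_names()

    def measure(n: int, metric_names: Sequence[str], stage: str) -> PrecisionSummary:
        cached = width_cache.get(n)
        if cached is not None and all(m in cached.metrics for m in metric_names):
            return cached
        spec = ScenarioSpec(lp=lp, calib=c, n=n, seed=_candidate_seed(seed, n))
        summary = run_precision(spec, metric_names, reps=reps, nb_threshold=nb_threshold)
        if cached is not None:  # merge metric sets measured at the same N
            merged = dict(cached.metrics)
            merged.update(summary.metrics)
            summary = PrecisionSummary(
                n=summary.n, reps=reps, seed=summary.seed,
                mean_observed_events=summary.mean_observed_events, metrics=merged,
            )
        width_cache[n] = summary
        for key, _, metric, scale in targets.items():
            if metric in summary.metrics and metric in metric_names:
                trace.append(
                    {
                        "n": n,
                        "stage": stage,
                        "target": key,
                        "width": summary.width(metric, scale),
                        "mc_se_of_width": summary[metric].mc_se_of_width,
                    }
                )
        return summary

    # ---- pilot ladder (geometric from start_n) ---------------------------
    pilot_ns = []
    n = start_n
    for _ in range(n_pilots):
        pilot_ns.append(min(n, cap_n))
        n *= pilot_factor
    pilot_ns = sorted(set(pilot_ns))
    for n in pilot_ns:
        measure(n, all_metrics, stage="pilot")

    per_metric: Dict[str, MetricRequirement] = {}
    for key, target_width, metric, scale in targets.items():

        def width_at(n: int, stage: str) -> Tuple[float, float]:
            s = measure(n, (metric,), stage)
            mp = s[metric]
            if mp.n_converged == 0 or not math.isfinite(s.width(metric, scale)):
                raise TargetUnreachableError(
                    f"metric {metric} produced no converged estimates at N={n}", trace
                )
            return s.width(metric, scale), mp.mc_se_of_width

        evals = 0

        # minimum of the search domain already suffices?
        w_start, se_start = width_at(start_n, "check-start")
        if w_start <= target_width:
            per_metric[key] = MetricRequirement(
                start_n, start_n * pi, target_width, w_start, se_start
            )
            continue

        pilot_pts = [
            (np_, width_cache[np_].width(metric, scale))
            for np_ in pilot_ns
            if metric in width_cache[np_].metrics
            and width_cache[np_][metric].n_converged > 0
            and math.isfinite(width_cache[np_].width(metric, scale))
        ]
        if len(pilot_pts) >= 3:
            curve = model_width_curve(pilot_pts)
        else:
            # ladder truncated by cap_n (or convergence failures): one-point
            # a/sqrt(N) extrapolation from whatever pilots exist
            a = float(
                np.mean([w * math.sqrt(np_) for np_, w in pilot_pts])
            ) if pilot_pts else w_start * math.sqrt(start_n)
            curve = WidthCurve(a=a)
        n_cur = min(max(curve.propose(target_width), start_n), cap_n)
        w_cur, se_cur = width_at(n_cur, "proposal")
        evals += 1

        # multiplicative (secant-style) re-proposals while far from target
        for _ in range(3):
            if abs(w_cur / target_width - 1.0) <= 0.05 or (
                n_cur == cap_n and w_cur > target_width
            ):
                break
            n_next = int(math.ceil(n_cur * (w_cur / target_width) ** 2))
            n_next = min(max(n_next, start_n), cap_n)
            if n_next == n_cur:
                break
            n_cur = n_next
            w_cur, se_cur = width_at(n_cur, "secant")
            evals += 1

        # local walk in 1% steps to the first N meeting the target
        step = max(1, round(0.01 * n_cur))
        if w_cur <= target_width:
            best = (n_cur, w_cur, se_cur)
            while n_cur - step >= start_n and evals < max_evals_per_metric:
                n_cur -= step
                w_cur, se_cur = width_at(n_cur, "walk-down")
                evals += 1
                if w_cur > target_width:
                    break
                best = (n_cur, w_cur, se_cur)
            else:
                if n_cur - step < start_n and w_cur <= target_width:
                    # reached the domain floor while still passing
                    best = (max(start_n, n_cur), w_cur, se_cur)
            n_req, w_req, se_req = best
        else:
            while w_cur > target_width and evals < max_evals_per_metric:
                if n_cur >= cap_n:
                    raise TargetUnreachableError(
                        f"target width {target_width} for {key} not met at cap N={cap_n}",
                        trace,
                    )
                n_cur = min(n_cur + step, cap_n)
                w_cur, se_cur = width_at(n_cur, "walk-up")
                evals += 1
            if w_cur > target_width:
                raise TargetUnreachableError(
                    f"search budget exhausted for {key} (last N={n_cur})", trace
                )
            n_req, w_req, se_req = n_cur, w_cur, se_cur

        per_metric[key] = MetricRequirement(
            int(n_req), n_req * pi, target_width, w_req, se_req
        )

    driving = max(per_metric, key=lambda k: per_metric[k].n_required)
    n_overall = per_metric[driving].n_required
    return SampleSizeResult(
        n_required=n_overall,
        events_required=n_overall * pi,
        driving_metric=driving,
        per_metric=per_metric,
        event_proportion=pi,
        reps=reps,
        seed=seed,
        trace=trace,
    )
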