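"""Plain-text run configuration for the command-line tools.

Configs are flat ``key = value`` files (``#`` starts a comment).  The
scenario can be specified directly (``lp_mu``, ``lp_sigma``) or
indirectly the way published models are reported (``base_probability``
for the mean, ``target_c`` for the spread via C-statistic inversion);
contradictory combinations are rejected.

Recognised keys
---------------
lp_mu | base_probability     mean of the LP (log-odds) | its inverse-logit
lp_sigma | target_c          SD of the LP | C-statistic to invert for sigma
gamma | target_proportion    calibration intercept | event proportion to solve gamma for
slope | miscal_factor        calibration slope | LP multiplier (slope with gamma=0)
targets.c_statistic, targets.cal_slope, targets.cal_in_large,
targets.oe_log, targets.ici, targets.net_benefit
                             target mean 95% CI widths (oe_log on the ln(O/E) scale)
n | expected_events          cohort size | expected events (for assess-precision)
events_basis                 base_probability (default) | event_proportion
reps, seed, start_n, cap_n, nb_threshold
sigmas, base_probs, events, miscal_factors   comma-separated grid factors
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .datagen import (
    CalibrationParams,
    LPDistribution,
    MiscalibrationFactor,
)
from .metrics import sigma_from_target_c
from .samplesize import PrecisionTargets

__all__ = ["ConfigError", "RunConfig", "parse_config"]

_SCALAR_KEYS = {
    "lp_mu", "lp_sigma", "base_probability", "target_c",
    "gamma", "slope", "miscal_factor", "target_proportion",
    "n", "expected_events", "events_basis",
    "reps", "seed", "start_n", "cap_n", "nb_threshold",
}
_TARGET_KEYS = {f"targets.{k}" for k in (
    "c_statistic", "cal_slope", "cal_in_large", "oe_log", "ici", "net_benefit"
)}
_GRID_KEYS = {"sigmas", "base_probs", "events", "miscal_factors"}
KNOWN_KEYS = _SCALAR_KEYS | _TARGET_KEYS | _GRID_KEYS


class ConfigError(ValueError):
    """Invalid, missing, or contradictory configuration."""


def _read_kv(text: str) -> Dict[str, str]:
    kv: Dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in KNOWN_KEYS:
            raise ConfigError(
                f"line {lineno}: unknown key {key!r} (known keys: {', '.join(sorted(KNOWN_KEYS))})"
            )
        if key in kv:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        kv[key] = value
    return kv


def _exclusive(kv: Dict[str, str], a: str, b: str, required: bool = True) -> Optional[str]:
    if a in kv and b in kv:
        raise ConfigError(f"keys {a!r} and {b!r} are contradictory; give exactly one")
    if a in kv:
        return a
    if b in kv:
        return b
    if required:
        raise ConfigError(f"one of {a!r} or {b!r} is required")
    return None


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration shared by the CLI commands."""

    lp: LPDistribution
    calib: object  # CalibrationParams | MiscalibrationFactor
    target_proportion: Optional[float]
    targets: Optional[PrecisionTargets]
    seed: int
    reps: int = 500
    start_n: int = 100
    cap_n: int = 1_000_000
    nb_threshold: float = 0.1
    n: Optional[int] = None
    expected_events: Optional[int] = None
    events_basis: str = "base_probability"
    grid: Dict[str, List[float]] = field(default_factory=dict)
    raw: Dict[str, str] = field(default_factory=dict)

    def to_config(self) -> str:
        """Re-emit the parsed configuration as key = value text (round-trips)."""
        return "\n".join(f"{k} = {v}" for k, v in self.raw.items()) + "\n"


def parse_config(path_or_text: str, is_text: bool = False) -> RunConfig:
    """Parse and validate a flat key=value config file (or literal text)."""
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    kv = _read_kv(text)

    if "seed" not in kv:
        raise ConfigError("key 'seed' is mandatory (reproducibility)")
    seed = int(kv["seed"])

    mu_key = _exclusive(kv, "lp_mu", "base_probability")
    if mu_key == "lp_mu":
        mu = float(kv["lp_mu"])
    else:
        from scipy.special import logit

        p = float(kv["base_probability"])
        if not 0.0 < p < 1.0:
            raise ConfigError("base_probability must be in (0, 1)")
        mu = float(logit(p))

    slope_key = _exclusive(kv, "slope", "miscal_factor", required=False)
    gamma_key = _exclusive(kv, "gamma", "target_proportion", required=False)
    if slope_key == "miscal_factor" and gamma_key == "gamma" and float(kv["gamma"]) != 0.0:
        raise ConfigError("miscal_factor implies gamma=0; give slope instead")

    sigma_key = _exclusive(kv, "lp_sigma", "target_c")
    if sigma_key == "lp_sigma":
        sigma = float(kv["lp_sigma"])
    else:
        sigma = sigma_from_target_c(float(kv["target_c"]), mu)
    lp = LPDistribution(mu=mu, sigma=sigma)

    if slope_key == "miscal_factor":
        calib = MiscalibrationFactor(float(kv["miscal_factor"]))
    else:
        slope = float(kv["slope"]) if slope_key else 1.0
        gamma = float(kv["gamma"]) if gamma_key == "gamma" else 0.0
        calib = CalibrationParams(gamma=gamma, slope=slope)
    target_proportion = (
        float(kv["target_proportion"]) if gamma_key == "target_proportion" else None
    )

    target_vals = {
        key.split(".", 1)[1]: float(val)
        for key, val in kv.items()
        if key in _TARGET_KEYS
    }
    targets = PrecisionTargets(**target_vals) if target_vals else None

    _exclusive(kv, "n", "expected_events", required=False)

    grid: Dict[str, List[float]] = {}
    for gk in _GRID_KEYS:
        if gk in kv:
            grid[gk] = [float(v) for v in kv[gk].split(",") if v.strip()]

    return RunConfig(
        lp=lp,
        calib=calib,
        target_proportion=target_proportion,
        targets=targets,
        seed=seed,
        reps=int(kv.get("reps", 500)),
        start_n=int(kv.get("start_n", 100)),
        cap_n=int(kv.get("cap_n", 1_000_000)),
        nb_threshold=float(kv.get("nb_threshold", 0.1)),
        n=int(kv["n"]) if "n" in kv else None,
        expected_events=int(kv["expected_events"]) if "expected_events" in kv else None,
        events_basis=kv.get("events_basis", "base_probability"),
        grid=grid,
        raw=dict(kv),
    )
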