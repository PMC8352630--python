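"""Deterministic small synthetic cohorts used across the test suite.

All fixtures derive from the worked diagnostic-model scenario
(LP ~ Normal(-1.75, 1.47^2)) with a controlled departure from perfect
calibration per kind:

* ``perfect``    gamma=0, slope=1
* ``overfitted`` slope=0.9 (predictions slightly too extreme)
* ``shifted``    gamma=0.5 (average risk under-predicted)
* ``tiny``       N=20, redrawn until both outcome classes are present
"""

from __future__ import annotations

from .datagen import (
    CalibrationParams,
    LPDistribution,
    ScenarioSpec,
    ValidationDataset,
    generate_dataset,
)

__all__ = ["FIXTURE_KINDS", "make_fixture"]

_DVT_LP = LPDistribution(mu=-1.75, sigma=1.47)

FIXTURE_KINDS = ("perfect", "overfitted", "shifted", "tiny")

_CALIB = {
    "perfect": CalibrationParams(0.0, 1.0),
    "overfitted": CalibrationParams(0.0, 0.9),
    "shifted": CalibrationParams(0.5, 1.0),
    "tiny": CalibrationParams(0.0, 1.0),
}


def make_fixture(kind: str, seed: int = 0, n: int | None = None) -> ValidationDataset:
    """Build a deterministic fixture cohort of the given kind.

    ``n`` overrides the default size (500; 20 for ``tiny``), e.g. to
    check large-sample generator properties.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    size = n if n is not None else (20 if kind == "tiny" else 500)
    spec = ScenarioSpec(lp=_DVT_LP, calib=_CALIB[kind], n=size, seed=seed)
    data = generate_dataset(spec)
    if kind == "tiny":
        bump = 0
        while data.outcomes.min() == data.outcomes.max():
            bump += 1
            data = generate_dataset(spec.with_seed(seed + 1_000_003 * bump))
    return data
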