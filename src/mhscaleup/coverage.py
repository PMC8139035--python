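"""Coverage scale-up trajectories.

A scale-up plan moves each intervention from its baseline coverage (percent
of eligible prevalent cases treated in the first horizon year) to a target
coverage in the last horizon year.  Four interpolation patterns are
supported:

``linear``
    equal annual increments.
``front_loaded``
    concave power curve ``b + (T - b) * (t/N)**p`` with ``p < 1`` (default
    0.5): coverage rises quickly at first and increments shrink over time —
    the shape typically planned when delivery infrastructure already exists.
``s_shaped``
    smoothstep ``b + (T - b) * (3x^2 - 2x^3)``: increments rise then fall.
``exponential``
    geometric growth from baseline to target (convex; increments grow);
    falls back to the convex power curve ``(t/N)**2`` when the baseline is
    zero.

Published per-year trajectories can be supplied verbatim via
:func:`from_table`, which takes precedence over any pattern.  Generated
percentages are kept at full float precision; rounding to one decimal is a
display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

PatternName = Literal["linear", "front_loaded", "s_shaped", "exponential"]
PATTERNS: tuple[str, ...] = ("linear", "front_loaded", "s_shaped", "exponential")

#: default concavity of the front-loaded power curve
FRONT_LOADED_POWER = 0.5
#: convexity used for the zero-baseline exponential fallback
EXPONENTIAL_POWER = 2.0

_TOL = 1e-9  # monotonicity slack for float round-off


class CoverageError(ValueError):
    """Invalid coverage endpoints or trajectory."""


@dataclass(frozen=True)
class CoverageTrajectory:
    """Annual coverage percentages for one intervention.

    Invariants (checked at construction): one value per horizon year,
    all values in [0, 100], non-decreasing.
    """

    intervention: str
    years: tuple[int, ...]
    percents: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.years) != len(self.percents):
            raise CoverageError("years and percents must align")
        if len(self.years) == 0:
            raise CoverageError("trajectory must cover at least one year")
        if list(self.years) != sorted(self.years):
            raise CoverageError("years must be ascending")
        arr = np.asarray(self.percents, dtype=float)
        if np.any(arr < -_TOL) or np.any(arr > 100 + _TOL):
            raise CoverageError(f"coverage out of [0, 100]: {self.intervention}")
        if np.any(np.diff(arr) < -_TOL):
            raise CoverageError(
                f"coverage must be non-decreasing: {self.intervention}"
            )

    @property
    def baseline_pct(self) -> float:
        return self.percents[0]

    @property
    def target_pct(self) -> float:
        return self.percents[-1]

    def percent_for(self, year: int) -> float:
        try:
            return self.percents[self.years.index(year)]
        except ValueError:
            raise CoverageError(f"year {year} outside trajectory") from None


def _check_endpoints(baseline_pct: float, target_pct: float) -> None:
    if not (0 <= baseline_pct <= 100 and 0 <= target_pct <= 100):
        raise CoverageError("coverage percents must lie in [0, 100]")
    if baseline_pct > target_pct:
        raise CoverageError(
            f"baseline {baseline_pct} exceeds target {target_pct}"
        )


def _shape(x: np.ndarray, pattern: str, baseline: float, target: float,
           power: float) -> np.ndarray:
    """Normalised progress (0 at x=0, 1 at x=1) for each pattern."""
    if pattern == "linear":
        return x
    if pattern == "front_loaded":
        return x**power
    if pattern == "s_shaped":
        return 3 * x**2 - 2 * x**3
    if pattern == "exponential":
        if baseline > 0 and target > baseline:
            g = target / baseline
            return (g**x - 1.0) / (g - 1.0)
        return x**EXPONENTIAL_POWER
    raise CoverageError(f"unknown pattern: {pattern!r}")


def interpolate(
    baseline_pct: float,
    target_pct: float,
    n_steps: int,
    pattern: PatternName,
    *,
    intervention: str = "",
    start_year: int = 2020,
    front_loaded_power: float = FRONT_LOADED_POWER,
) -> CoverageTrajectory:
    """Interpolate ``n_steps + 1`` annual coverage values baseline → target.

    Endpoints are pinned exactly; interior values follow the pattern's
    shape.  ``n_steps`` is the number of annual increments (10 for a
    2020–2030 horizon).
    """
    _check_endpoints(baseline_pct, target_pct)
    if n_steps < 1:
        raise CoverageError("n_steps must be >= 1")
    x = np.arange(n_steps + 1, dtype=float) / n_steps
    vals = baseline_pct + (target_pct - baseline_pct) * _shape(
        x, pattern, baseline_pct, target_pct, front_loaded_power
    )
    vals[0], vals[-1] = baseline_pct, target_pct  # pin exactly
    years = tuple(range(start_year, start_year + n_steps + 1))
    return CoverageTrajectory(intervention, years, tuple(vals.tolist()))


def from_table(
    rows: Mapping[int, float] | Iterable[tuple[int, float]],
    *,
    intervention: str = "",
    horizon_years: Sequence[int] | None = None,
) -> CoverageTrajectory:
    """Build a trajectory from explicit per-year percents (authoritative).

    ``horizon_years``, when given, must be covered exactly — a missing year
    is an error, as is any dip in the sequence.
    """
    mapping = dict(rows.items() if isinstance(rows, Mapping) else rows)
    if not mapping:
        raise CoverageError("empty coverage table")
    if horizon_years is not None:
        missing = [y for y in horizon_years if y not in mapping]
        if missing:
            raise CoverageError(
                f"coverage table missing years {missing} for {intervention!r}"
            )
        mapping = {y: mapping[y] for y in horizon_years}
    years = tuple(sorted(mapping))
    return CoverageTrajectory(intervention, years,
                              tuple(float(mapping[y]) for y in years))


def increments(trajectory: CoverageTrajectory) -> np.ndarray:
    """Per-year coverage increases in percentage points.

    Non-negative; telescopes to ``target - baseline`` exactly.
    """
    return np.diff(np.asarray(trajectory.percents, dtype=float))
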