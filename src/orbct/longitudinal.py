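"""Linear density-vs-lifespan trends for implant cohorts.

Implant apparent density (mean HU over the implant volume) is regressed
on implant lifespan (days since implantation) by ordinary least squares.
Fits can use the raw uncalibrated means, the published corrected column,
or corrected values recomputed per scan from each record's own anchors
via :mod:`orbct.hu_calibration`.  Slopes are reported both per day and
per year (365.25 d by default — the source never states its year
convention) together with the closed-form slope standard error; no
further inferential machinery is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hu_calibration import MsctReference, build_calibration, correct_hu
from .study_table import ImplantRecord

__all__ = [
    "TrendFit",
    "InsufficientDataError",
    "DAYS_PER_YEAR",
    "ols_fit",
    "density_trend",
    "POOLED_GROUP",
]

DAYS_PER_YEAR = 365.25

#: Group key used for the ungrouped (pooled) fit.
POOLED_GROUP = "pooled"


class InsufficientDataError(ValueError):
    """Fewer than three points, or a degenerate (constant-x) design."""


@dataclass(frozen=True)
class TrendFit:
    slope_hu_per_day: float
    slope_hu_per_year: float
    intercept_hu: float
    r_squared: float
    n: int
    slope_se_hu_per_day: float
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def ols_fit(
    x: Sequence[float], y: Sequence[float], *, days_per_year: float = DAYS_PER_YEAR
) -> TrendFit:
    """Closed-form OLS of y (HU) on x (days).

    slope = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)², intercept = ȳ − slope·x̄; R² from
    explained variance, defined as 0 for a constant response.  The slope
    standard error is the usual √(σ̂²/Σ(x−x̄)²) with n−2 residual dof.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    n = xv.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((xv - xv.mean()) ** 2))
    if sxx == 0.0:
        raise InsufficientDataError("zero variance in x (degenerate design)")
    sxy = float(np.sum((xv - xv.mean()) * (yv - yv.mean())))
    slope = sxy / sxx
    intercept = float(yv.mean() - slope * xv.mean())
    resid = yv - (intercept + slope * xv)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    sigma2 = ss_res / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    return TrendFit(
        slope_hu_per_day=slope,
        slope_hu_per_year=slope * days_per_year,
        intercept_hu=intercept,
        r_squared=min(r2, 1.0),
        n=n,
        slope_se_hu_per_day=se,
        days_per_year=days_per_year,
    )


def _record_value(
    r: ImplantRecord,
    use_corrected: bool,
    corrected_source: str,
    reference: MsctReference,
    literal_equation: bool,
) -> float:
    if not use_corrected:
        return r.oi_mean_hu
    if corrected_source == "published":
        return r.corrected_mean_hu
    if corrected_source == "recompute":
        cal = build_calibration(
            r.cv_mean_hu, r.dv_max_hu, reference, literal_equation=literal_equation
        )
        return correct_hu(r.oi_mean_hu, cal)
    raise ValueError(f"unknown corrected_source: {corrected_source!r}")


def density_trend(
    records: Sequence[ImplantRecord],
    group_map: Mapping[str, str] | None = None,
    *,
    use_corrected: bool = True,
    corrected_source: str = "recompute",
    reference: MsctReference | None = None,
    literal_equation: bool = True,
    exclude: Sequence[str] = (),
    days_per_year: float = DAYS_PER_YEAR,
) -> dict[str, TrendFit]:
    """Per-group OLS trend of implant density against lifespan.

    ``group_map`` maps record IDs to group names (e.g. implant material);
    without it a single pooled fit is returned under :data:`POOLED_GROUP`.
    Records with ``included=False`` or listed in ``exclude`` are dropped.
    ``use_corrected`` selects corrected density (recomputed from each
    record's own anchors, or the published column, per
    ``corrected_source``) versus the raw uncalibrated mean.
    """
    reference = reference if reference is not None else MsctReference()
    excluded = set(exclude)
    active = [r for r in records if r.included and r.id_label not in excluded]
    if group_map is not None:
        known = {r.id_label for r in records}
        unknown = sorted(set(group_map) - known)
        if unknown:
            raise KeyError(f"group_map contains unknown record IDs: {unknown}")
    groups: dict[str, list[ImplantRecord]] = {}
    for r in active:
        if group_map is None:
            groups.setdefault(POOLED_GROUP, []).append(r)
        elif r.id_label in group_map:
            groups.setdefault(group_map[r.id_label], []).append(r)
    fits: dict[str, TrendFit] = {}
    for name, members in sorted(groups.items()):
        if len(members) < 3:
            raise InsufficientDataError(
                f"group {name!r} has {len(members)} records; need >= 3"
            )
        x = [r.lifespan_days for r in members]
        y = [
            _record_value(
                r, use_corrected, corrected_source, reference, literal_equation
            )
            for r in members
        ]
        fits[name] = ols_fit(x, y, days_per_year=days_per_year)
    return fits
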