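"""Predicted trajectories and age-at-peak estimation.

Predicted curves are produced by marginal standardization: at each grid age
the model prediction is averaged (with the analysis weights) over every
participant's observed covariates, so the curve describes the weighted
population rather than one reference demographic cell.

Peak ages come from the first derivative of the fitted age polynomial:

* quadratic models:  peak = MeanAge - a1 / (2 * a2)       (vertex formula)
* cubic models:      roots of a1 + 2*a2*x + 3*a3*x^2 via the quadratic
  formula, keeping the root where the second derivative is negative
  (the local maximum), reported as MeanAge + root.

For head-size-adjusted (ICV) models the peak is instead read off the
predicted curve by averaging within consecutive 2-year age bins and taking
the best bin's midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DEFAULT_AGE_RANGE
from .models import DesignInfo, FitResult, build_design
from .raking import WeightSet

__all__ = [
    "TrajectoryCurve",
    "PeakEstimate",
    "default_age_grid",
    "predict_curve",
    "peak_age_quadratic",
    "peak_age_cubic",
    "peak_age_binned",
    "peak_difference",
]


@dataclass(frozen=True)
class TrajectoryCurve:
    """A predicted outcome trajectory on an age grid."""

    ages: np.ndarray
    values: np.ndarray
    outcome: str = ""
    condition: str = "unweighted"
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("age grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    def to_frame(self) -> pd.DataFrame:
        extr = (
            np.zeros(len(self.ages), dtype=bool)
            if self.extrapolated is None
            else self.extrapolated
        )
        return pd.DataFrame(
            {
                "outcome": self.outcome,
                "condition": self.condition,
                "age": self.ages,
                "predicted": self.values,
                "extrapolated": extr,
            }
        )


@dataclass(frozen=True)
class PeakEstimate:
    """Estimated age at peak with how it was obtained."""

    peak_age: float
    method: str  # analytic-quadratic | analytic-cubic | binned-2yr
    interior: bool
    curvature_ok: bool
    outcome: str = ""
    condition: str = "unweighted"


def default_age_grid(
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE, step: float = 0.05
) -> np.ndarray:
    lo, hi = age_range
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def predict_curve(
    fit: FitResult,
    cohort: pd.DataFrame,
    weights: WeightSet | np.ndarray | None = None,
    age_grid: np.ndarray | None = None,
) -> TrajectoryCurve:
    """Marginally standardized predicted values by age.

    At each grid age every participant's age is set to that value (their
    other covariates unchanged), predictions are averaged with the analysis
    weights, and grid points outside the observed age support are flagged as
    extrapolation.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    grid = default_age_grid() if age_grid is None else np.asarray(age_grid, float)
    w = None
    if weights is not None:
        w = (
            weights.final
            if isinstance(weights, WeightSet)
            else np.asarray(weights, float)
        )
    X, _ = build_design(cohort, fit.info.spec, info=fit.info)
    beta = fit.params
    age_cols = [f"age_c{p}" for p in range(1, fit.order + 1)]
    base = X.drop(columns=age_cols).to_numpy() @ beta.drop(age_cols).to_numpy()
    base_mean = float(np.average(base, weights=w))
    centered = grid - fit.mean_age
    values = base_mean + sum(
        fit.age_coefficient(p) * centered**p for p in range(1, fit.order + 1)
    )
    observed = cohort["age"].to_numpy(float)
    extrapolated = (grid < observed.min()) | (grid > observed.max())
    return TrajectoryCurve(
        ages=grid,
        values=np.asarray(values, float),
        outcome=fit.outcome,
        condition=fit.condition,
        extrapolated=extrapolated,
    )


def peak_age_quadratic(
    fit: FitResult, age_range: tuple[float, float] = DEFAULT_AGE_RANGE
) -> PeakEstimate:
    """Vertex of the fitted parabola: MeanAge - a1 / (2 * a2)."""
    if fit.order != 2:
        raise ValueError("peak_age_quadratic requires an order-2 fit")
    a1, a2 = fit.age_coefficient(1), fit.age_coefficient(2)
    if a2 == 0:
        raise ValueError("degenerate quadratic: a2 = 0")
    if a2 > 0:
        raise ValueError(
            "fitted curve is convex (a2 > 0): no interior maximum exists"
        )
    peak = fit.mean_age - a1 / (2.0 * a2)
    lo, hi = age_range
    return PeakEstimate(
        peak_age=float(peak),
        method="analytic-quadratic",
        interior=bool(lo < peak < hi),
        curvature_ok=True,
        outcome=fit.outcome,
        condition=fit.condition,
    )


def peak_age_cubic(
    fit: FitResult, age_range: tuple[float, float] = DEFAULT_AGE_RANGE
) -> PeakEstimate:
    """Local maximum of the fitted cubic via the derivative's quadratic roots.

    Solves a1 + 2*a2*x + 3*a3*x^2 = 0 in centered age x and keeps the root
    where the second derivative 2*a2 + 6*a3*x is negative.  If that local
    maximum falls outside ``age_range``, the in-range argmax of the fitted
    cubic is reported instead with ``interior=False``.
    """
    if fit.order != 3:
        raise ValueError("peak_age_cubic requires an order-3 fit")
    a1 = fit.age_coefficient(1)
    a2 = fit.age_coefficient(2)
    a3 = fit.age_coefficient(3)
    if a3 == 0:
        raise ValueError("degenerate cubic: a3 = 0")
    disc = (2.0 * a2) ** 2 - 4.0 * (3.0 * a3) * a1
    if disc < 0:
        direction = "increasing" if a1 > 0 else "decreasing"
        raise ValueError(
            f"no interior peak: the fitted cubic is monotone ({direction}) "
            "— the derivative has no real roots"
        )
    # stable quadratic roots of (3*a3) x^2 + (2*a2) x + a1: avoids
    # cancellation when a3 is tiny (near-quadratic fits)
    b = 2.0 * a2
    q = -0.5 * (b + math.copysign(math.sqrt(disc), b if b != 0 else 1.0))
    roots = [q / (3.0 * a3)]
    if q != 0:
        roots.append(a1 / q)
    maxima = [x for x in roots if 2.0 * a2 + 6.0 * a3 * x < 0]
    lo, hi = age_range
    if not maxima:
        raise ValueError("no local maximum: both derivative roots are not maxima")
    peak = fit.mean_age + maxima[0]
    if lo < peak < hi:
        return PeakEstimate(
            peak_age=float(peak),
            method="analytic-cubic",
            interior=True,
            curvature_ok=True,
            outcome=fit.outcome,
            condition=fit.condition,
        )
    # local maximum lies outside the age range: report the in-range argmax
    grid = np.arange(lo, hi + 5e-5, 1e-4)
    poly = fit.age_polynomial()
    vals = poly(grid - fit.mean_age)
    return PeakEstimate(
        peak_age=float(grid[int(np.argmax(vals))]),
        method="analytic-cubic",
        interior=False,
        curvature_ok=True,
        outcome=fit.outcome,
        condition=fit.condition,
    )


def peak_age_binned(curve: TrajectoryCurve, bin_width: float = 2.0) -> PeakEstimate:
    """Midpoint of the age bin with the highest mean predicted value.

    Bins are consecutive ``[start, start + bin_width)`` intervals from the
    grid minimum (the last bin is closed).  Ties break toward the younger
    bin.
    """
    lo, hi = float(curve.ages.min()), float(curve.ages.max())
    n_bins = int(math.ceil((hi - lo) / bin_width - 1e-9))
    if n_bins < 2:
        raise ValueError("curve must span at least two bins")
    means = []
    for b in range(n_bins):
        start = lo + b * bin_width
        end = start + bin_width
        mask = (
            (curve.ages >= start) & (curve.ages < end)
            if b < n_bins - 1
            else (curve.ages >= start) & (curve.ages <= end)
        )
        if not mask.any():
            raise ValueError(
                f"age bin [{start}, {end}) contains no grid points; "
                "use a finer age grid"
            )
        means.append(float(curve.values[mask].mean()))
    best = int(np.argmax(means))  # argmax takes the first (youngest) on ties
    midpoint = lo + best * bin_width + bin_width / 2.0
    return PeakEstimate(
        peak_age=float(midpoint),
        method="binned-2yr",
        interior=0 < best < n_bins - 1,
        curvature_ok=True,
        outcome=curve.outcome,
        condition=curve.condition,
    )


def peak_difference(unweighted: PeakEstimate, weighted: PeakEstimate) -> float:
    """Unweighted minus weighted peak age, on one-decimal-rounded peaks."""
    if unweighted.outcome != weighted.outcome:
        raise ValueError(
            f"peak estimates are for different outcomes: "
            f"{unweighted.outcome!r} vs {weighted.outcome!r}"
        )
    return round(round(unweighted.peak_age, 1) - round(weighted.peak_age, 1), 1)
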