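"""Synthetic cohort generator.

Emulates a multi-site child neuroimaging cohort: categorical demographics
drawn to match specified margins, uniform ages over a configured range,
lognormal intracranial volume, and continuous brain-structure outcomes that
follow polynomial-in-age trajectories.  Trajectory shape may differ by
demographic group — by default lower-income groups peak earlier, encoding
the hypothesis of earlier/faster brain maturation in low-SES children — so
that reweighting the sample toward a target population measurably shifts the
population-level trajectory.  The ground-truth peak age of any margin-
weighted mixture of group trajectories is available analytically via
:func:`true_population_peak`, which makes parameter-recovery testing of the
whole weighting-and-fitting pipeline possible without any real data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DEFAULT_AGE_RANGE, validate_cohort
from .margins import MarginSpec, child_cohort_margins

__all__ = [
    "OutcomeSpec",
    "TrajectorySpec",
    "generate_demographics",
    "generate_outcomes",
    "generate_cohort",
    "true_population_peak",
    "default_trajectory_spec",
    "write_fixture",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative trajectory for one outcome.

    The noiseless value for a participant in group ``g`` (a category of
    ``modifier_variable``) at age ``a`` is::

        amplitude[g] * P(a - age_center - peak_shift[g])
        + covariate effects + icv_effect * (icv - mean icv)

    where ``P`` is the cubic polynomial with ``coefficients``
    (intercept, b1, b2, b3) in centered-age units.  A peak shift of -2.0
    moves the group's trajectory peak two years earlier; an amplitude
    multiplier scales the whole curve without moving its peak.
    """

    name: str
    coefficients: tuple[float, float, float, float]
    age_center: float = 10.5
    modifier_variable: str | None = None
    peak_shifts: dict[str, float] = field(default_factory=dict)
    amplitudes: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    icv_effect: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g, m in self.amplitudes.items():
            if m <= 0:
                raise ValueError(f"amplitude multiplier for {g!r} must be > 0")

    def base_curve(self, age: np.ndarray, group: str | None = None) -> np.ndarray:
        """Noiseless group trajectory at the given ages (no covariate/ICV terms)."""
        shift = self.peak_shifts.get(group, 0.0) if group is not None else 0.0
        amp = self.amplitudes.get(group, 1.0) if group is not None else 1.0
        x = np.asarray(age, dtype=float) - self.age_center - shift
        b0, b1, b2, b3 = self.coefficients
        return amp * (b0 + b1 * x + b2 * x**2 + b3 * x**3)


@dataclass(frozen=True)
class TrajectorySpec:
    """A collection of outcome trajectories generated on the same cohort."""

    outcomes: tuple[OutcomeSpec, ...]

    def outcome(self, name: str) -> OutcomeSpec:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def outcome_names(self) -> list[str]:
        return [o.name for o in self.outcomes]


def _sample_pair(
    rng: np.random.Generator,
    n: int,
    margins: MarginSpec,
    var_a: str,
    var_b: str,
    log_odds: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample two variables jointly with an exponential-tilt association.

    Joint cells start at ``p_a * p_b * exp(log_odds * s_a * s_b)`` with
    centered category scores ``s``, then are re-fit to the exact margins by
    iterative proportional fitting, so the association knob never perturbs
    the marginal distributions.
    """
    cats_a = margins.categories(var_a)
    cats_b = margins.categories(var_b)
    pa = np.array([margins.proportion(var_a, c) for c in cats_a])
    pb = np.array([margins.proportion(var_b, c) for c in cats_b])

    def scores(k: int) -> np.ndarray:
        if k == 1:
            return np.zeros(1)
        return (np.arange(k) - (k - 1) / 2) / (k - 1)

    joint = np.outer(pa, pb) * np.exp(
        log_odds * np.outer(scores(len(cats_a)), scores(len(cats_b)))
    )
    for _ in range(200):
        row = joint.sum(axis=1)
        joint *= np.where(row > 0, pa / np.where(row > 0, row, 1.0), 0.0)[:, None]
        col = joint.sum(axis=0)
        joint *= np.where(col > 0, pb / np.where(col > 0, col, 1.0), 0.0)[None, :]
        if (
            np.abs(joint.sum(axis=1) - pa).max() < 1e-12
            and np.abs(joint.sum(axis=0) - pb).max() < 1e-12
        ):
            break
    flat = joint.ravel() / joint.sum()
    idx = rng.choice(flat.size, size=n, p=flat)
    ia, ib = np.unravel_index(idx, joint.shape)
    return (
        np.array(cats_a, dtype=object)[ia],
        np.array(cats_b, dtype=object)[ib],
    )


def generate_demographics(
    margins: MarginSpec,
    n: int,
    seed: int,
    association: dict[tuple[str, str], float] | None = None,
    *,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    n_scanners: int = 10,
    include_icv: bool = True,
    icv_median: float = 1.45e6,
    icv_sigma: float = 0.08,
) -> pd.DataFrame:
    """Draw a cohort's demographics from marginal category probabilities.

    Variables are independent unless ``association`` supplies a pairwise
    log-odds tilt for disjoint variable pairs.  Ages are uniform on
    ``age_range``, scanner assignment is uniform over ``n_scanners`` sites,
    and intracranial volume (mm^3) is lognormal with the given median and
    log-scale spread.  Deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    paired: set[str] = set()
    if association:
        for (va, vb), lam in association.items():
            for v in (va, vb):
                if v not in margins.variables:
                    raise ValueError(f"unknown variable in association settings: {v!r}")
                if v in paired:
                    raise ValueError(
                        f"variable {v!r} appears in more than one association pair"
                    )
            columns[va], columns[vb] = _sample_pair(rng, n, margins, va, vb, lam)
            paired.update((va, vb))
    for var in margins.variable_names:
        if var in paired:
            continue
        cats = margins.categories(var)
        p = np.array([margins.proportion(var, c) for c in cats])
        columns[var] = rng.choice(np.array(cats, dtype=object), size=n, p=p)

    lo, hi = age_range
    out = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "age": rng.uniform(lo, hi, size=n),
        }
    )
    for var in margins.variable_names:
        out[var] = columns[var]
    out["scanner"] = np.array(
        [f"site{j + 1:02d}" for j in rng.integers(0, n_scanners, size=n)],
        dtype=object,
    )
    if include_icv:
        out["icv"] = icv_median * np.exp(rng.normal(0.0, icv_sigma, size=n))
    return out


def generate_outcomes(
    cohort: pd.DataFrame,
    spec: TrajectorySpec | OutcomeSpec,
    seed: int,
) -> pd.DataFrame:
    """Append outcome columns generated from polynomial age trajectories.

    Each outcome value is the group-modified polynomial at the participant's
    centered age, plus additive covariate main effects, an optional centered
    ICV slope, and Gaussian noise.  Deterministic given ``seed``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if isinstance(spec, OutcomeSpec):
        spec = TrajectorySpec((spec,))
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    age = out["age"].to_numpy(dtype=float)
    for ospec in spec.outcomes:
        if ospec.name in out.columns:
            raise ValueError(f"outcome {ospec.name!r} already present in cohort")
        values = np.zeros(len(out))
        if ospec.modifier_variable is not None:
            groups = out[ospec.modifier_variable].astype(str).to_numpy()
            known = set(groups)
            for g in set(ospec.peak_shifts) | set(ospec.amplitudes):
                if g not in known:
                    raise ValueError(
                        f"modifier references category {g!r} absent from "
                        f"cohort variable {ospec.modifier_variable!r}"
                    )
            for g in np.unique(groups):
                mask = groups == g
                values[mask] = ospec.base_curve(age[mask], g)
        else:
            values = ospec.base_curve(age)
        for var, effects in ospec.covariate_effects.items():
            labels = out[var].astype(str)
            values += labels.map(lambda c: effects.get(c, 0.0)).to_numpy(dtype=float)
        if ospec.icv_effect is not None:
            if "icv" not in out.columns:
                raise ValueError(f"outcome {ospec.name!r} requires an icv column")
            icv = out["icv"].to_numpy(dtype=float)
            values += ospec.icv_effect * (icv - icv.mean())
        if ospec.noise_sd > 0:
            values = values + rng.normal(0.0, ospec.noise_sd, size=len(out))
        out[ospec.name] = values
    return out


def true_population_peak(
    spec: OutcomeSpec,
    target_margins: MarginSpec,
    age_grid_step: float = 0.001,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> float:
    """Peak age of the margin-weighted mixture of noiseless group trajectories.

    Covariate main effects and ICV terms shift the mixture by constants and
    cannot move its argmax, so the peak depends only on the group curves and
    the mixture weights.  A monotone mixture (no interior peak) returns the
    boundary age with a warning.
    """
    lo, hi = age_range
    grid = np.arange(lo, hi + age_grid_step / 2, age_grid_step)
    if spec.modifier_variable is None:
        mixture = spec.base_curve(grid)
    else:
        cats = target_margins.categories(spec.modifier_variable)
        weights = np.array(
            [target_margins.proportion(spec.modifier_variable, c) for c in cats]
        )
        mixture = np.zeros_like(grid)
        for w, c in zip(weights, cats):
            mixture += w * spec.base_curve(grid, c)
    k = int(np.argmax(mixture))
    peak = float(grid[k])
    if k == 0 or k == len(grid) - 1:
        warnings.warn(
            f"mixture trajectory for {spec.name!r} is monotone over "
            f"[{lo}, {hi}]; returning the boundary age",
            stacklevel=2,
        )
    return peak


def default_trajectory_spec() -> TrajectorySpec:
    """Default generative trajectories for the shipped demonstration.

    Two outcomes: a total-cortical-surface-area-like measure (mm^2) with a
    concave quadratic age trajectory peaking near age 12, and a subcortical-
    volume-like measure (mm^3, head-size dependent via an ICV slope) peaking
    near age 11.75.  Both have income-keyed peak shifts that move the
    lowest-income group's peak 3 years earlier and the middle group's 1.5
    years earlier, so a sample that under-represents low-income families
    shows a later population-level peak than a correctly weighted one.
    """
    income_shifts = {"<40k": -3.0, "40-100k": -1.5, ">=100k": 0.0}
    return TrajectorySpec(
        (
            OutcomeSpec(
                name="total_surface_area",
                coefficients=(180000.0, 806.14, -242.64, 0.0),
                age_center=10.44,
                modifier_variable="income",
                peak_shifts=income_shifts,
                covariate_effects={"sex": {"Female": -7000.0}},
                noise_sd=4000.0,
            ),
            OutcomeSpec(
                name="subcortical_volume",
                coefficients=(60000.0, 150.0, -60.0, 0.0),
                age_center=10.5,
                modifier_variable="income",
                peak_shifts=income_shifts,
                covariate_effects={"sex": {"Female": -2500.0}},
                noise_sd=1500.0,
                icv_effect=0.02,
            ),
        )
    )


def generate_cohort(
    n: int = 1162,
    seed: int = 0,
    margins: MarginSpec | None = None,
    spec: TrajectorySpec | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Demographics plus outcomes in one call (the shipped study conditions).

    Defaults: n = 1162 participants with the child-cohort margins and the
    :func:`default_trajectory_spec` outcomes.
    """
    margins = margins if margins is not None else child_cohort_margins()
    spec = spec if spec is not None else default_trajectory_spec()
    demo = generate_demographics(margins, n, seed, **kwargs)
    if n == 0:
        for name in spec.outcome_names:
            demo[name] = pd.Series(dtype=float)
        return demo
    return generate_outcomes(demo, spec, seed=seed + 1)


def write_fixture(
    directory,
    n: int = 1162,
    seed: int = 0,
    margins: MarginSpec | None = None,
    target_margins: MarginSpec | None = None,
    spec: TrajectorySpec | None = None,
) -> dict:
    """Write cohort CSV, margin CSVs and a ground-truth JSON into *directory*.

    The JSON records each outcome's true group peak ages and the margin-
    weighted population peaks under both the sample and target margins.
    """
    from .margins import acs_margins

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    margins = margins if margins is not None else child_cohort_margins()
    target_margins = target_margins if target_margins is not None else acs_margins()
    spec = spec if spec is not None else default_trajectory_spec()
    cohort = generate_cohort(n=n, seed=seed, margins=margins, spec=spec)
    validate_cohort(cohort)
    cohort.to_csv(directory / "cohort.csv", index=False)
    margins.to_csv(directory / "sample_margins.csv")
    target_margins.to_csv(directory / "target_margins.csv")
    truth: dict = {"seed": seed, "n": n, "outcomes": {}}
    for ospec in spec.outcomes:
        entry: dict = {
            "age_center": ospec.age_center,
            "coefficients": list(ospec.coefficients),
            "modifier_variable": ospec.modifier_variable,
            "peak_shifts": ospec.peak_shifts,
            "population_peak_sample_margins": true_population_peak(ospec, margins),
            "population_peak_target_margins": true_population_peak(
                ospec, target_margins
            ),
        }
        truth["outcomes"][ospec.name] = entry
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
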