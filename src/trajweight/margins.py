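"""Target-population margin specifications for calibration weighting.

A :class:`MarginSpec` holds, per categorical variable, the proportion of the
target population in each category.  These margins are what raking /
calibration estimators try to reproduce in the weighted sample.  Two specs
ship with the package: the demographic composition of a multi-site child
cohort (ages 3-18) and the corresponding U.S. population composition from
the American Community Survey (ACS) 2009-2011 public-use microdata, covering
the four weighting variables sex, race/ethnicity, parental education and
family income.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MarginSpec",
    "load_margins",
    "child_cohort_margins",
    "acs_margins",
]

_SUM_TOL_STRICT = 1e-9
_SUM_TOL_LOAD = 1e-3


@dataclass(frozen=True)
class MarginSpec:
    """Per-variable target category proportions.

    Parameters
    ----------
    variables
        Mapping ``variable name -> {category label: proportion}``.  Insertion
        order is meaningful: it fixes the cycling order of iterative
        proportional fitting and the dummy-coding order downstream.

    Raises
    ------
    ValueError
        If any variable's proportions do not sum to 1 (within 1e-9), a
        proportion is negative, or names/labels collide.
    """

    variables: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, cats in self.variables.items():
            if len(cats) == 0:
                raise ValueError(f"variable {var!r} has no categories")
            total = sum(cats.values())
            if abs(total - 1.0) > _SUM_TOL_STRICT:
                raise ValueError(
                    f"proportions for {var!r} sum to {total!r}, not 1"
                )
            for cat, p in cats.items():
                if p < 0:
                    raise ValueError(f"negative proportion for {var!r}/{cat!r}")

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    def categories(self, variable: str) -> list[str]:
        return list(self.variables[variable])

    def proportion(self, variable: str, category: str) -> float:
        return self.variables[variable][category]

    def n_categories(self) -> int:
        return sum(len(c) for c in self.variables.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (var, cat, p)
            for var, cats in self.variables.items()
            for cat, p in cats.items()
        ]
        return pd.DataFrame(rows, columns=["variable", "category", "proportion"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarginSpec":
        required = {"variable", "category", "proportion"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"margin table missing columns: {sorted(missing)}")
        variables: dict[str, dict[str, float]] = {}
        for _, row in frame.iterrows():
            var, cat = str(row["variable"]), str(row["category"])
            cats = variables.setdefault(var, {})
            if cat in cats:
                raise ValueError(f"duplicate category {cat!r} for variable {var!r}")
            cats[cat] = float(row["proportion"])
        # renormalize small deviations (file rounding); reject large ones
        for var, cats in variables.items():
            total = sum(cats.values())
            if abs(total - 1.0) > _SUM_TOL_LOAD:
                raise ValueError(
                    f"proportions for {var!r} sum to {total:.6f}; "
                    f"must be within {_SUM_TOL_LOAD} of 1"
                )
            if abs(total - 1.0) > _SUM_TOL_STRICT:
                variables[var] = {c: p / total for c, p in cats.items()}
        return cls(variables)


def load_margins(path) -> MarginSpec:
    """Read a ``variable,category,proportion`` CSV into a :class:`MarginSpec`.

    Proportions within 1e-3 of summing to one are renormalized; larger
    deviations and duplicate (variable, category) pairs raise ``ValueError``.
    """
    return MarginSpec.from_frame(pd.read_csv(path))


def child_cohort_margins() -> MarginSpec:
    """Demographic margins of the multi-site child cohort (unweighted sample)."""
    return MarginSpec(
        {
            "race": {
                "White": 0.423,
                "Black": 0.104,
                "Hispanic": 0.238,
                "Other": 0.088,
                "2+ Races": 0.147,
            },
            "sex": {"Male": 0.529, "Female": 0.471},
            "parental_education": {
                "HS or less": 0.138,
                "Some college": 0.248,
                "College degree": 0.267,
                "More than college": 0.347,
            },
            "income": {"<40k": 0.248, "40-100k": 0.373, ">=100k": 0.379},
        }
    )


def acs_margins() -> MarginSpec:
    """U.S. population margins for children aged 3-18, ACS 2009-2011 PUMS."""
    return MarginSpec(
        {
            "race": {
                "White": 0.699,
                "Black": 0.136,
                "Hispanic": 0.075,
                "Other": 0.055,
                "2+ Races": 0.035,
            },
            "sex": {"Male": 0.513, "Female": 0.487},
            "parental_education": {
                "HS or less": 0.372,
                "Some college": 0.326,
                "College degree": 0.189,
                "More than college": 0.113,
            },
            "income": {"<40k": 0.335, "40-100k": 0.405, ">=100k": 0.260},
        }
    )
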