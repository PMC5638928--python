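"""Weighted polynomial age-trajectory models with AIC order selection.

The outcome is regressed on centered-age powers (age - MeanAge)^p for
p = 1..order plus dummy-coded demographic covariates (and optionally
centered intracranial volume), by weighted least squares.  Model fit across
polynomial orders 1-3 is compared with a pseudo-likelihood Gaussian AIC

    AIC = n * ln(RSS_w / n) + 2 * (p + 1),

with the weights normalized to sum to n so weighted and unweighted fits are
scored identically in form.  A higher polynomial order is adopted only when
it lowers the AIC of the best simpler model by at least 2.5 points — the
conventional threshold for preferring added polynomial complexity in
developmental trajectory modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .raking import WeightSet

__all__ = [
    "DesignSpec",
    "DesignInfo",
    "FitResult",
    "SelectionResult",
    "DEFAULT_COVARIATES",
    "DEFAULT_REFERENCES",
    "build_design",
    "fit_wls",
    "aic",
    "select_order",
    "PolynomialAgeModel",
    "TrajectorySelector",
]

DEFAULT_COVARIATES = ("sex", "race", "parental_education", "income", "scanner")

DEFAULT_REFERENCES = {
    "sex": "Male",
    "race": "White",
    "parental_education": "HS or less",
    "income": "<40k",
}

SELECTION_THRESHOLD = 2.5


@dataclass(frozen=True)
class DesignSpec:
    """What goes into the design matrix for one model."""

    outcome: str
    order: int = 2
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_icv: bool = False
    references: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError("order must be 1, 2 or 3")


@dataclass(frozen=True)
class DesignInfo:
    """Centering constants and coding choices frozen at design-build time.

    Needed to rebuild the design at counterfactual ages (trajectory
    prediction) exactly as it was built at fit time.
    """

    spec: DesignSpec
    mean_age: float
    icv_center: float | None
    references: dict[str, str]
    columns: tuple[str, ...]


def _weight_vector(
    weights: WeightSet | np.ndarray | None, n: int
) -> np.ndarray | None:
    if weights is None:
        return None
    w = weights.final if isinstance(weights, WeightSet) else np.asarray(weights, float)
    if len(w) != n:
        raise ValueError("weights length does not match data")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w


def _age_columns(age: np.ndarray, mean_age: float, order: int) -> dict[str, np.ndarray]:
    centered = age - mean_age
    return {f"age_c{p}": centered**p for p in range(1, order + 1)}


def build_design(
    cohort: pd.DataFrame,
    spec: DesignSpec,
    weights: WeightSet | np.ndarray | None = None,
    info: DesignInfo | None = None,
    age_override: float | np.ndarray | None = None,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Design matrix: intercept, centered age powers, dummies, centered ICV.

    MeanAge is the weighted mean age when weights are given.  Passing a
    previously returned ``info`` reuses its centering constants and coding
    (for prediction); ``age_override`` substitutes a fixed age for every row.
    """
    n = len(cohort)
    w = _weight_vector(weights, n)
    age = np.asarray(cohort["age"], dtype=float)
    if info is None:
        mean_age = float(np.average(age, weights=w))
        icv_center = None
        if spec.include_icv:
            if "icv" not in cohort.columns:
                raise ValueError("include_icv requested but cohort has no icv column")
            icv_center = float(np.average(cohort["icv"].to_numpy(float), weights=w))
        refs: dict[str, str] = {}
        for var in spec.covariates:
            if var not in cohort.columns:
                raise ValueError(f"covariate {var!r} not in cohort")
            observed = sorted(set(cohort[var].astype(str)))
            if len(observed) < 2:
                raise ValueError(
                    f"covariate {var!r} has a single observed level "
                    f"({observed[0]!r}): constant column"
                )
            configured = (spec.references or {}).get(var, DEFAULT_REFERENCES.get(var))
            refs[var] = configured if configured in observed else observed[0]
    else:
        mean_age, icv_center, refs = info.mean_age, info.icv_center, info.references

    if age_override is not None:
        age = np.broadcast_to(np.asarray(age_override, dtype=float), (n,))

    data: dict[str, np.ndarray] = {"const": np.ones(n)}
    data.update(_age_columns(age, mean_age, spec.order))
    for var in spec.covariates:
        labels = cohort[var].astype(str).to_numpy()
        if info is None:
            levels = [c for c in sorted(set(labels)) if c != refs[var]]
        else:
            levels = [
                name.split("[", 1)[1][:-1]
                for name in info.columns
                if name.startswith(f"{var}[")
            ]
        unseen = set(labels) - set(levels) - {refs[var]}
        if info is not None and unseen:
            raise ValueError(f"unseen categories for {var!r}: {sorted(unseen)}")
        for cat in levels:
            data[f"{var}[{cat}]"] = (labels == cat).astype(float)
    if spec.include_icv:
        data["icv_c"] = cohort["icv"].to_numpy(float) - icv_center
    X = pd.DataFrame(data, index=cohort.index)
    out_info = DesignInfo(
        spec=spec,
        mean_age=mean_age,
        icv_center=icv_center,
        references=refs,
        columns=tuple(X.columns),
    )
    if info is not None:
        X = X.reindex(columns=list(info.columns), fill_value=0.0)
        out_info = info
    return X, out_info


@dataclass(frozen=True)
class FitResult:
    """A fitted weighted polynomial trajectory model."""

    info: DesignInfo
    params: pd.Series
    bse: pd.Series
    n: int
    rss_w: float
    aic: float
    condition: str = "unweighted"

    @property
    def order(self) -> int:
        return self.info.spec.order

    @property
    def outcome(self) -> str:
        return self.info.spec.outcome

    @property
    def mean_age(self) -> float:
        return self.info.mean_age

    def age_coefficient(self, power: int) -> float:
        """Coefficient on (age - MeanAge)^power (a1, a2, a3 betas)."""
        return float(self.params[f"age_c{power}"])

    def age_polynomial(self) -> np.polynomial.Polynomial:
        """Fitted age polynomial in centered-age units (including intercept)."""
        coefs = [float(self.params["const"])]
        coefs += [self.age_coefficient(p) for p in range(1, self.order + 1)]
        return np.polynomial.Polynomial(coefs)


def aic_from_rss(rss_w: float, n: int, n_params: int) -> float:
    """Gaussian pseudo-likelihood AIC: n*ln(RSS_w/n) + 2*(p+1)."""
    if rss_w <= 0:
        raise ValueError(
            "weighted RSS is zero: degenerate (perfectly interpolating) fit"
        )
    return float(n * np.log(rss_w / n) + 2 * (n_params + 1))


def aic(fit: FitResult) -> float:
    """AIC of a fitted model (recomputed from its weighted RSS)."""
    return aic_from_rss(fit.rss_w, fit.n, len(fit.params))


def fit_wls(
    design: tuple[pd.DataFrame, DesignInfo],
    y: np.ndarray | pd.Series,
    weights: WeightSet | np.ndarray | None = None,
    condition: str = "unweighted",
    robust: bool = False,
) -> FitResult:
    """Weighted least squares on a built design.

    Weights are normalized to sum to n (coefficients and AIC are invariant
    to their scale); absent weights mean ordinary least squares.  Standard
    errors are model-based from the weighted information matrix, or
    HC1-sandwich when ``robust=True``.
    """
    X, info = design
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome values")
    n = len(y)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if n <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    w = _weight_vector(weights, n)
    w = np.ones(n) if w is None else w * (n / w.sum())
    res = sm.WLS(y, X, weights=w).fit(cov_type="HC1" if robust else "nonrobust")
    resid = y - res.fittedvalues
    rss_w = float(np.sum(w * resid**2))
    return FitResult(
        info=info,
        params=res.params,
        bse=res.bse,
        n=n,
        rss_w=rss_w,
        aic=aic_from_rss(rss_w, n, X.shape[1]),
        condition=condition,
    )


@dataclass(frozen=True)
class SelectionResult:
    """AIC comparison across polynomial orders and the selected order."""

    outcome: str
    aic_by_order: dict[int, float]
    selected_order: int
    threshold: float = SELECTION_THRESHOLD
    condition: str = "unweighted"

    @property
    def selected_aic(self) -> float:
        return self.aic_by_order[self.selected_order]


def select_order(
    aics: dict[int, float],
    threshold: float = SELECTION_THRESHOLD,
    outcome: str = "",
    condition: str = "unweighted",
) -> SelectionResult:
    """Pick the polynomial order by the 2.5-point AIC improvement rule.

    The selected order is the highest order whose AIC is at least
    ``threshold`` points below the minimum AIC among all strictly simpler
    models; if no higher order clears that bar, the linear model is kept.
    """
    for order in (1, 2, 3):
        if order not in aics:
            raise ValueError(f"missing AIC for order {order}")
        if not np.isfinite(aics[order]):
            raise ValueError(f"non-finite AIC for order {order}")
    selected = 1
    for order in (3, 2):
        best_lower = min(aics[o] for o in range(1, order))
        if aics[order] <= best_lower - threshold:
            selected = order
            break
    return SelectionResult(
        outcome=outcome,
        aic_by_order=dict(aics),
        selected_order=selected,
        threshold=threshold,
        condition=condition,
    )


class PolynomialAgeModel(BaseEstimator, RegressorMixin):
    """Scikit-learn-style weighted polynomial age-trajectory regressor.

    ``fit(X, y, sample_weight=...)`` takes the cohort frame as ``X`` and the
    outcome values as ``y``.  Fitted attributes: ``coef_`` (pd.Series of all
    coefficients), ``bse_``, ``aic_``, ``rss_``, ``mean_age_``,
    ``fit_result_``.
    """

    def __init__(
        self,
        order: int = 2,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        include_icv: bool = False,
        references: dict[str, str] | None = None,
        robust: bool = False,
        condition: str = "unweighted",
    ) -> None:
        self.order = order
        self.covariates = covariates
        self.include_icv = include_icv
        self.references = references
        self.robust = robust
        self.condition = condition

    def _spec(self, outcome: str = "") -> DesignSpec:
        return DesignSpec(
            outcome=outcome,
            order=self.order,
            covariates=tuple(self.covariates),
            include_icv=self.include_icv,
            references=self.references,
        )

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> "PolynomialAgeModel":
        outcome = y.name if isinstance(y, pd.Series) and y.name else ""
        design = build_design(X, self._spec(outcome), weights=sample_weight)
        fr = fit_wls(
            design,
            y,
            weights=sample_weight,
            condition=self.condition,
            robust=self.robust,
        )
        self.fit_result_ = fr
        self.coef_ = fr.params
        self.bse_ = fr.bse
        self.aic_ = fr.aic
        self.rss_ = fr.rss_w
        self.mean_age_ = fr.mean_age
        return self

    def predict(self, X: pd.DataFrame, age=None) -> np.ndarray:
        """Fitted values; ``age`` substitutes a counterfactual age for all rows."""
        fr = self.fit_result_
        design, _ = build_design(
            X, fr.info.spec, info=fr.info, age_override=age
        )
        return design.to_numpy() @ fr.params.to_numpy()


class TrajectorySelector(BaseEstimator):
    """Fit polynomial orders 1-3 and select by the AIC improvement rule.

    Fitted attributes: ``fits_`` (order -> FitResult), ``aic_by_order_``,
    ``selected_order_``, ``selection_``, ``best_fit_``.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        include_icv: bool = False,
        references: dict[str, str] | None = None,
        threshold: float = SELECTION_THRESHOLD,
        robust: bool = False,
        condition: str = "unweighted",
    ) -> None:
        self.covariates = covariates
        self.include_icv = include_icv
        self.references = references
        self.threshold = threshold
        self.robust = robust
        self.condition = condition

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> "TrajectorySelector":
        outcome = y.name if isinstance(y, pd.Series) and y.name else ""
        self.fits_ = {}
        for order in (1, 2, 3):
            spec = DesignSpec(
                outcome=outcome,
                order=order,
                covariates=tuple(self.covariates),
                include_icv=self.include_icv,
                references=self.references,
            )
            design = build_design(X, spec, weights=sample_weight)
            self.fits_[order] = fit_wls(
                design,
                y,
                weights=sample_weight,
                condition=self.condition,
                robust=self.robust,
            )
        self.aic_by_order_ = {o: f.aic for o, f in self.fits_.items()}
        self.selection_ = select_order(
            self.aic_by_order_,
            threshold=self.threshold,
            outcome=outcome,
            condition=self.condition,
        )
        self.selected_order_ = self.selection_.selected_order
        self.best_fit_ = self.fits_[self.selected_order_]
        return self
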