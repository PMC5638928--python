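"""Post-stratification weighting by raking and bounded-logit calibration.

Given a cohort and target-population category proportions (margins), these
routines construct per-participant weights theta_k so that the weighted
sample reproduces the target margins:

* :func:`ipf_rake` — classic raking (iterative proportional fitting): the
  weights are multiplied by per-category correction factors, cycling over
  the margin variables until every weighted proportion matches its target
  within tolerance.

* :func:`calibrate_logit` — generalized raking via a bounded-logit link, the
  model-based calibration used by survey packages such as SUDAAN's WTADJUST.
  Each final weight is

      theta_k = gamma_k * alpha_k,
      alpha_k = [l(u - c) + u(c - l) exp(A x_k' beta)]
                / [(u - c) + (c - l) exp(A x_k' beta)],

  where gamma_k is a trimming factor (1 before trimming), x_k stacks the
  category indicators of the weighting variables, and l < c < u bound the
  adjustment factor.  beta solves the calibration moment equations
  sum_k theta_k x_k = target totals by damped Newton iteration.  With wide
  bounds this reproduces classic raking.

* :func:`trim_and_rerake` — 3-IQR weight trimming: weights outside the
  quartile fences [Q1 - m*IQR, Q3 + m*IQR] of the initial-pass weights are
  clipped, and the clipped weights are re-calibrated (with per-unit bounds
  that keep the result inside the fence) so the margins are restored.

:class:`RakingWeighter` wraps all of this in a scikit-learn-style estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .margins import MarginSpec

__all__ = [
    "CalibrationConfig",
    "WeightSet",
    "InfeasibleMarginsError",
    "RakingWeighter",
    "adjustment_factor",
    "ipf_rake",
    "calibrate_logit",
    "trim_and_rerake",
    "margin_report",
]


class InfeasibleMarginsError(ValueError):
    """A target category with positive proportion has no sample support."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Tuning constants for calibration weighting.

    ``lower_bound`` (l), ``upper_bound`` (u), ``center`` (c) and ``scale``
    (A) may be scalars or per-participant arrays; they bound and shape the
    bounded-logit adjustment factor.  ``trim_multiplier`` is the IQR
    multiple for weight-trimming fences.  ``tolerance`` is the maximum
    absolute margin error (in proportion units) accepted as convergence.
    ``normalization`` is ``"sample-size"`` (weights sum to n) or a numeric
    population total.
    """

    lower_bound: float | np.ndarray = 0.0
    upper_bound: float | np.ndarray = 100.0
    center: float | np.ndarray = 1.0
    scale: float | np.ndarray = 1.0
    trim_multiplier: float = 3.0
    tolerance: float = 1e-8
    max_iterations: int = 1000
    normalization: str | float = "sample-size"

    def __post_init__(self) -> None:
        l, u, c = (
            np.asarray(self.lower_bound),
            np.asarray(self.upper_bound),
            np.asarray(self.center),
        )
        if not (np.all(l < c) and np.all(c < u)):
            raise ValueError("bounds must satisfy l < c < u")
        if not np.all(np.asarray(self.scale) > 0):
            raise ValueError("scale A must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.trim_multiplier <= 0:
            raise ValueError("trim_multiplier must be > 0")

    def total(self, n: int) -> float:
        if self.normalization == "sample-size":
            return float(n)
        return float(self.normalization)


@dataclass(frozen=True)
class WeightSet:
    """Per-participant weights with provenance and convergence diagnostics."""

    participant_ids: np.ndarray
    initial: np.ndarray
    final: np.ndarray
    method: str
    converged: bool
    iterations: int
    max_residual: float
    beta: np.ndarray | None = None
    beta_names: tuple[str, ...] | None = None
    residuals: dict[str, float] = field(default_factory=dict)
    trimming_applied: bool = False
    fences: tuple[float, float] | None = None
    gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.final <= 0):
            raise ValueError("all final weights must be > 0")

    def __len__(self) -> int:
        return len(self.final)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "initial_weight": self.initial,
                "final_weight": self.final,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def diagnostics(self) -> dict:
        return {
            "method": self.method,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "max_residual": float(self.max_residual),
            "beta": None if self.beta is None else list(map(float, self.beta)),
            "beta_names": None if self.beta_names is None else list(self.beta_names),
            "residuals": {k: float(v) for k, v in self.residuals.items()},
            "trimming_applied": bool(self.trimming_applied),
            "fences": None if self.fences is None else list(map(float, self.fences)),
        }


def adjustment_factor(
    eta: float | np.ndarray, config: CalibrationConfig
) -> float | np.ndarray:
    """Bounded-logit adjustment alpha(eta) for eta = A * x'beta.

    Strictly increasing, with alpha(0) = c and limits l (eta -> -inf) and
    u (eta -> +inf).  Written via the logistic function for numerical
    stability at large |eta|.
    """
    l = np.asarray(config.lower_bound, dtype=float)
    u = np.asarray(config.upper_bound, dtype=float)
    c = np.asarray(config.center, dtype=float)
    # alpha = l + (u - l) * sigmoid(eta + log((c - l)/(u - c)))
    out = l + (u - l) * expit(np.asarray(eta, dtype=float) + np.log((c - l) / (u - c)))
    if np.isscalar(eta) and out.ndim == 0:
        return float(out)
    return out


def _adjustment_derivative(eta: np.ndarray, config: CalibrationConfig) -> np.ndarray:
    l = np.asarray(config.lower_bound, dtype=float)
    u = np.asarray(config.upper_bound, dtype=float)
    c = np.asarray(config.center, dtype=float)
    s = expit(np.asarray(eta, dtype=float) + np.log((c - l) / (u - c)))
    return (u - l) * s * (1.0 - s)


def _check_support(cohort: pd.DataFrame, margins: MarginSpec) -> None:
    for var in margins.variable_names:
        if var not in cohort.columns:
            raise ValueError(f"margin variable {var!r} not in cohort")
        observed = set(cohort[var].astype(str))
        for cat in margins.categories(var):
            if margins.proportion(var, cat) > 0 and cat not in observed:
                raise InfeasibleMarginsError(
                    f"target category {var!r}/{cat!r} has positive proportion "
                    f"but no sample members"
                )
        extra = observed - set(margins.categories(var))
        if extra:
            raise ValueError(
                f"cohort categories {sorted(extra)} of {var!r} missing from margins"
            )


def _margin_residuals(
    weights: np.ndarray, cohort: pd.DataFrame, margins: MarginSpec
) -> dict[str, float]:
    total = weights.sum()
    res: dict[str, float] = {}
    for var in margins.variable_names:
        labels = cohort[var].astype(str).to_numpy()
        for cat in margins.categories(var):
            achieved = weights[labels == cat].sum() / total
            res[f"{var}/{cat}"] = achieved - margins.proportion(var, cat)
    return res


def _initial_vector(
    cohort: pd.DataFrame, initial_weights: WeightSet | np.ndarray | None
) -> np.ndarray:
    n = len(cohort)
    if initial_weights is None:
        return np.ones(n)
    vec = (
        initial_weights.final
        if isinstance(initial_weights, WeightSet)
        else np.asarray(initial_weights, dtype=float)
    )
    if len(vec) != n:
        raise ValueError("initial weights length does not match cohort")
    if np.any(vec <= 0):
        raise ValueError("initial weights must be > 0")
    return vec.astype(float)


def ipf_rake(
    cohort: pd.DataFrame,
    margins: MarginSpec,
    config: CalibrationConfig | None = None,
    initial_weights: WeightSet | np.ndarray | None = None,
) -> WeightSet:
    """Classic raking: cyclic multiplicative margin adjustment of the weights.

    Cycles over the margin variables in spec order, scaling each category's
    weights so its weighted proportion matches the target, until the maximum
    absolute margin error falls below ``config.tolerance`` or
    ``config.max_iterations`` full cycles have run.
    """
    config = config or CalibrationConfig()
    _check_support(cohort, margins)
    init = _initial_vector(cohort, initial_weights)
    n = len(cohort)
    total = config.total(n)
    w = init * (total / init.sum())

    labels = {v: cohort[v].astype(str).to_numpy() for v in margins.variable_names}
    converged = False
    iterations = 0
    max_resid = np.inf
    for iterations in range(1, config.max_iterations + 1):
        for var in margins.variable_names:
            wsum = w.sum()
            for cat in margins.categories(var):
                mask = labels[var] == cat
                cur = w[mask].sum()
                tgt = margins.proportion(var, cat) * wsum
                if cur > 0:
                    w[mask] *= tgt / cur
        res = _margin_residuals(w, cohort, margins)
        max_resid = max(abs(v) for v in res.values())
        if max_resid < config.tolerance:
            converged = True
            break
    w *= total / w.sum()
    return WeightSet(
        participant_ids=cohort["participant_id"].to_numpy(),
        initial=init,
        final=w,
        method="ipf",
        converged=converged,
        iterations=iterations,
        max_residual=float(max_resid),
        residuals=_margin_residuals(w, cohort, margins),
    )


def _calibration_design(
    cohort: pd.DataFrame, margins: MarginSpec, total: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stacked indicator matrix (intercept + non-reference dummies) and totals."""
    n = len(cohort)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    targets: list[float] = [total]
    for var in margins.variable_names:
        labels = cohort[var].astype(str).to_numpy()
        for cat in margins.categories(var)[1:]:  # first category is redundant
            cols.append((labels == cat).astype(float))
            names.append(f"{var}/{cat}")
            targets.append(margins.proportion(var, cat) * total)
    return np.column_stack(cols), np.asarray(targets), names


def calibrate_logit(
    cohort: pd.DataFrame,
    margins: MarginSpec,
    config: CalibrationConfig | None = None,
    initial_weights: WeightSet | np.ndarray | None = None,
) -> WeightSet:
    """Generalized raking with the bounded-logit link (damped Newton solve).

    Solves sum_k init_k * alpha(A x_k' beta) * x_k = target totals for beta;
    final weights theta_k = init_k * alpha_k.  With non-binding bounds the
    achieved margins match the targets within ``config.tolerance``; binding
    bounds or otherwise infeasible targets yield ``converged = False`` with
    per-category residuals.
    """
    config = config or CalibrationConfig()
    _check_support(cohort, margins)
    init = _initial_vector(cohort, initial_weights)
    n = len(cohort)
    total = config.total(n)
    init = init * (total / init.sum())
    X, targets, names = _calibration_design(cohort, margins, total)
    A = np.broadcast_to(np.asarray(config.scale, dtype=float), (n,))

    c = np.asarray(config.center, dtype=float)
    # centre the link so beta = 0 leaves the initial weights unchanged:
    # with c = 1 alpha(0) = 1 already; a non-unit centre rescales uniformly.
    beta = np.zeros(X.shape[1])

    def moments(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eta = A * (X @ b)
        theta = init * adjustment_factor(eta, config)
        return X.T @ theta - targets, theta

    F, theta = moments(beta)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        eta = A * (X @ beta)
        dalpha = _adjustment_derivative(eta, config)
        Jdiag = init * dalpha * A
        J = X.T @ (X * Jdiag[:, None])
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError as exc:
            if iterations == 1:
                raise np.linalg.LinAlgError(
                    "singular calibration system: the category indicators are "
                    "collinear; drop one reference category per variable"
                ) from exc
            # bounds binding hard: adjustment derivatives vanished; stop with
            # the best weights found and report non-convergence
            break
        # step-halving damping on the moment-equation norm
        t = 1.0
        f0 = np.linalg.norm(F)
        for _ in range(40):
            cand = beta + t * step
            Fc, theta_c = moments(cand)
            if np.linalg.norm(Fc) < f0 or t < 1e-12:
                break
            t /= 2.0
        beta, F, theta = cand, Fc, theta_c
        max_resid = np.abs(F).max() / total
        if max_resid < config.tolerance:
            converged = True
            break
    max_resid = float(np.abs(F).max() / total)
    theta = np.maximum(theta, np.finfo(float).tiny)
    return WeightSet(
        participant_ids=cohort["participant_id"].to_numpy(),
        initial=init,
        final=theta,
        method="logit",
        converged=converged,
        iterations=iterations,
        max_residual=max_resid,
        beta=beta,
        beta_names=tuple(names),
        residuals=_margin_residuals(theta, cohort, margins),
    )


def trim_and_rerake(
    weights: WeightSet,
    cohort: pd.DataFrame,
    margins: MarginSpec,
    config: CalibrationConfig | None = None,
) -> WeightSet:
    """Clip weights to 3-IQR quartile fences and re-calibrate.

    Fences are [Q1 - m*IQR, Q3 + m*IQR] of the initial-pass weights (m =
    ``config.trim_multiplier``), floored at a small positive value.  If the
    WeightSet already records fences (a previous trimming pass), those are
    reused, which makes the operation idempotent.  Re-calibration runs the
    bounded-logit solver with the clipped weights as initial weights and
    per-unit bounds that keep every final weight inside the fence.
    """
    config = config or CalibrationConfig()
    w = weights.final
    if weights.fences is not None:
        lo, hi = weights.fences
    else:
        q1, q3 = np.percentile(w, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            return weights
        lo = max(q1 - config.trim_multiplier * iqr, 1e-8)
        hi = q3 + config.trim_multiplier * iqr
    inside = (w >= lo) & (w <= hi)
    if inside.all():
        return weights
    clipped = np.clip(w, lo, hi)
    gamma = clipped / weights.initial
    # per-unit bounds so the re-calibrated weights stay inside the fence
    eps = 1e-9
    unit_l = np.minimum(lo / clipped, 1.0 - eps)
    unit_u = np.maximum(hi / clipped, 1.0 + eps)
    cfg = replace(
        config, lower_bound=unit_l, upper_bound=unit_u, center=1.0, scale=1.0
    )
    recal = calibrate_logit(cohort, margins, cfg, initial_weights=clipped)
    return replace(
        recal,
        initial=weights.initial,
        trimming_applied=True,
        fences=(float(lo), float(hi)),
        gamma=gamma,
    )


def margin_report(
    cohort: pd.DataFrame,
    weights: WeightSet | np.ndarray,
    margins: MarginSpec,
) -> pd.DataFrame:
    """Target vs unweighted vs weighted percentages per category.

    Percentages are rounded to one decimal and the difference columns are
    computed from the rounded values, matching how such comparisons are
    conventionally tabulated.
    """
    w = weights.final if isinstance(weights, WeightSet) else np.asarray(weights, float)
    if len(w) != len(cohort):
        raise ValueError("weights length does not match cohort")
    rows = []
    for var in margins.variable_names:
        labels = cohort[var].astype(str).to_numpy()
        for cat in margins.categories(var):
            mask = labels == cat
            target = round(100.0 * margins.proportion(var, cat), 1)
            unw = round(100.0 * mask.mean(), 1)
            wtd = round(100.0 * w[mask].sum() / w.sum(), 1)
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "target_pct": target,
                    "unweighted_pct": unw,
                    "weighted_pct": wtd,
                    "unweighted_minus_target": round(unw - target, 1),
                    "weighted_minus_target": round(wtd - target, 1),
                }
            )
    return pd.DataFrame(rows)


class RakingWeighter(BaseEstimator):
    """Scikit-learn-style post-stratification weighting estimator.

    Parameters
    ----------
    margins
        Target-population :class:`MarginSpec`.
    method
        ``"logit"`` (bounded-logit generalized raking, default) or ``"ipf"``
        (classic iterative proportional fitting).
    trim
        If True, apply 3-IQR trimming with re-calibration after the initial
        pass.
    lower_bound, upper_bound, center, scale, trim_multiplier, tolerance,
    max_iterations, normalization
        See :class:`CalibrationConfig`.

    Attributes
    ----------
    weights_ : ndarray of shape (n,)
        Final per-participant weights theta_k.
    weight_set_ : WeightSet
        Full provenance (initial weights, beta, residuals, fences).
    converged_ : bool
    n_iter_ : int
    max_residual_ : float
    """

    def __init__(
        self,
        margins: MarginSpec | None = None,
        method: str = "logit",
        trim: bool = False,
        lower_bound: float = 0.0,
        upper_bound: float = 100.0,
        center: float = 1.0,
        scale: float = 1.0,
        trim_multiplier: float = 3.0,
        tolerance: float = 1e-8,
        max_iterations: int = 100,
        normalization: str | float = "sample-size",
    ) -> None:
        self.margins = margins
        self.method = method
        self.trim = trim
        self.lower_bound = lower_bound
        self.upper_bound = upper_bound
        self.center = center
        self.scale = scale
        self.trim_multiplier = trim_multiplier
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self.normalization = normalization

    def _config(self) -> CalibrationConfig:
        return CalibrationConfig(
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            center=self.center,
            scale=self.scale,
            trim_multiplier=self.trim_multiplier,
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
            normalization=self.normalization,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "RakingWeighter":
        """Compute calibration weights for the cohort ``X``."""
        if self.margins is None:
            raise ValueError("margins must be provided")
        if self.method not in ("logit", "ipf"):
            raise ValueError(f"unknown method {self.method!r}")
        config = self._config()
        solver = calibrate_logit if self.method == "logit" else ipf_rake
        ws = solver(X, self.margins, config)
        if self.trim:
            ws = trim_and_rerake(ws, X, self.margins, config)
        self.weight_set_ = ws
        self.weights_ = ws.final
        self.converged_ = ws.converged
        self.n_iter_ = ws.iterations
        self.max_residual_ = ws.max_residual
        return self

    def margin_report(self, X: pd.DataFrame) -> pd.DataFrame:
        """Margin comparison table for a fitted weighter."""
        return margin_report(X, self.weight_set_, self.margins)
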