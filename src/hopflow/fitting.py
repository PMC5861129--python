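"""Global kinetic-model fitting and leave-one-out cross-validation.

The kinetic model is fit by differential evolution (rand/1/bin, seeded,
box-constrained) on the sum of squared residuals between predicted and
replicate-mean titers; free-parameter bounds default to one decade centered
in log space on the nominal values.  Leave-one-out cross-validation refits
any of the three models on all-but-one strain and records the held-out
residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import differential_evolution

from .core_io import GENES, StrainDataset
from .metrics import DEFAULT_TITER_FLOOR
from .pathway_model import (
    KineticParameterSet,
    loglinear_fit,
    predict_titers_batch,
    smooth_regressor_fit,
)

__all__ = [
    "FitSpec",
    "ModelFit",
    "LooResult",
    "sse_cost",
    "bounds_from_nominal",
    "fit_kinetic",
    "loo_cv",
]

#: Default free parameters: the relative→absolute protein conversion
#: factors, the endogenous/engineered FPPS ratio, and the flux→titer yield.
DEFAULT_FREE = ("alpha_H", "alpha_F", "alpha_L", "alpha_G", "beta", "yield_T")


def bounds_from_nominal(
    nominals: dict[str, float], span_decades: float = 1.0
) -> dict[str, tuple[float, float]]:
    """Log-centered box bounds: nominal·10^(±span/2), one decade total by default."""
    if span_decades < 0:
        raise ValueError("span_decades must be >= 0")
    out = {}
    for name, v in nominals.items():
        if v <= 0:
            raise ValueError(f"nominal for {name!r} must be > 0 to take log bounds")
        half = 10.0 ** (span_decades / 2.0)
        out[name] = (v / half, v * half)
    return out


@dataclass
class FitSpec:
    """Differential-evolution fit specification.

    ``free`` lists the parameters optimized; all others stay at ``base``.
    Bounds default to one decade centered on the base value.  ``space``
    selects the residual space ("linear" or "log10").
    """

    free: tuple[str, ...] = DEFAULT_FREE
    base: KineticParameterSet = field(default_factory=KineticParameterSet)
    bounds: dict[str, tuple[float, float]] | None = None
    span_decades: float = 1.0
    popsize: int = 15  # population multiplier per free parameter
    maxiter: int = 300
    mutation: float = 0.7
    recombination: float = 0.9
    seed: int = 0
    space: str = "linear"
    stall_generations: int = 50
    stall_tol: float = 1e-10
    titer_floor: float = DEFAULT_TITER_FLOOR

    def __post_init__(self) -> None:
        valid = set(asdict(self.base))
        unknown = set(self.free) - valid
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")
        if self.space not in ("linear", "log10"):
            raise ValueError("space must be 'linear' or 'log10'")
        if self.popsize < 5:
            raise ValueError("population multiplier must be >= 5")
        if self.bounds is None:
            nominals = {p: getattr(self.base, p) for p in self.free}
            self.bounds = bounds_from_nominal(nominals, self.span_decades)
        for p in self.free:
            lo, hi = self.bounds[p]
            if lo > hi:
                raise ValueError(f"bounds for {p!r}: lower {lo} > upper {hi}")
            v = getattr(self.base, p)
            if not (lo <= v <= hi):
                raise ValueError(f"bounds for {p!r} do not contain nominal {v}")


@dataclass
class ModelFit:
    """Result of a model fit: parameters, cost, trace, and LOO residuals."""

    params: KineticParameterSet
    cost: float
    trace: list[float]
    free: tuple[str, ...]
    x: np.ndarray
    loo_residuals: dict[str, tuple[float, float]] | None = None


@dataclass
class LooResult:
    """Leave-one-out residuals (pred − obs, per species) and summary RMSE."""

    residuals: dict[str, tuple[float, float]]
    rmse_linalool: float
    rmse_geraniol: float
    warnings: list[str] = field(default_factory=list)


def _dataset_arrays(dataset: StrainDataset) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids, rows = dataset.abundance_matrix()
    means = dataset.mean_titers()
    obs = np.array([means[s] for s in ids])  # (n, 2)
    return ids, np.array(rows), obs


def sse_cost(
    params: KineticParameterSet,
    dataset: StrainDataset,
    space: str = "linear",
    titer_floor: float = DEFAULT_TITER_FLOOR,
) -> float:
    """Sum of squared residuals of kinetic predictions vs replicate-mean titers.

    Residuals over both monoterpenes and all strains, in linear titer space
    by default or in log10(titer + floor) space when ``space='log10'``.
    """
    _, A, obs = _dataset_arrays(dataset)
    lin, ger = predict_titers_batch(params, A)
    pred = np.column_stack([lin, ger])
    if space == "log10":
        pred = np.log10(pred + titer_floor)
        obs = np.log10(obs + titer_floor)
    elif space != "linear":
        raise ValueError("space must be 'linear' or 'log10'")
    return float(np.sum((pred - obs) ** 2))


def fit_kinetic(dataset: StrainDataset, spec: FitSpec) -> ModelFit:
    """Fit free kinetic parameters by seeded differential evolution.

    Uses the rand/1/bin update rule with box constraints from the spec;
    the best-cost trace is monotone non-increasing (elitist best member).
    Deterministic given ``spec.seed``.
    """
    if len(dataset) < len(spec.free):
        warnings.warn(
            f"{len(dataset)} strains for {len(spec.free)} free parameters; "
            "fit may be poorly constrained",
            stacklevel=2,
        )
    ids, A, obs = _dataset_arrays(dataset)
    obs_cost = obs.copy()
    if spec.space == "log10":
        obs_cost = np.log10(obs + spec.titer_floor)

    def objective(x: np.ndarray) -> float:
        params = spec.base.with_updates(**dict(zip(spec.free, x)))
        lin, ger = predict_titers_batch(params, A)
        pred = np.column_stack([lin, ger])
        if spec.space == "log10":
            pred = np.log10(pred + spec.titer_floor)
        return float(np.sum((pred - obs_cost) ** 2))

    trace: list[float] = []

    def callback(xk, convergence=None):  # per-generation best member
        trace.append(objective(np.asarray(xk, dtype=float)))
        if len(trace) > spec.stall_generations:
            if trace[-spec.stall_generations - 1] - trace[-1] < spec.stall_tol:
                return True
        return False

    bounds = [spec.bounds[p] for p in spec.free]
    result = differential_evolution(
        objective,
        bounds,
        strategy="rand1bin",
        popsize=spec.popsize,
        maxiter=spec.maxiter,
        mutation=spec.mutation,
        recombination=spec.recombination,
        seed=spec.seed,
        tol=0.0,
        init="latinhypercube",
        polish=True,
        callback=callback,
    )
    x = np.clip(result.x, [b[0] for b in bounds], [b[1] for b in bounds])
    cost = objective(x)
    # elitist best-so-far trace, terminated by the polished optimum
    best_trace = list(np.minimum.accumulate(trace + [cost])) if trace else [cost]
    params = spec.base.with_updates(**dict(zip(spec.free, x)))
    return ModelFit(params=params, cost=cost, trace=best_trace, free=spec.free, x=x)


def _predict_for_kind(kind, fitted, profile_row: np.ndarray) -> tuple[float, float]:
    if kind == "kinetic":
        lin, ger = predict_titers_batch(fitted.params, profile_row[None, :])
    else:
        lin, ger = fitted.predict(profile_row[None, :])
    return float(lin[0]), float(ger[0])


def loo_cv(
    dataset: StrainDataset,
    model_kind: str = "kinetic",
    spec: FitSpec | None = None,
    kernel_scale: float = 1.0,
) -> LooResult:
    """Leave-one-out cross-validation of one of the three models.

    For each strain the model is refit on the remaining strains and the
    held-out strain's (pred − obs) residual pair recorded; the summary is
    the RMSE over strains per species.  Kinetic refits are seeded per fold
    (spec.seed + fold index) so the procedure is reproducible.
    """
    if model_kind not in ("kinetic", "loglinear", "smooth"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    ids, A, obs = _dataset_arrays(dataset)
    if len(ids) < 3:
        raise ValueError("loo_cv needs at least 3 strains")
    if model_kind == "kinetic" and spec is None:
        spec = FitSpec()
    residuals: dict[str, tuple[float, float]] = {}
    notes: list[str] = []
    for k, sid in enumerate(ids):
        sub = dataset.drop_strain(sid)
        n_free = len(spec.free) if spec is not None else 5
        if len(sub) < n_free:
            notes.append(f"fold {sid}: {len(sub)} strains < {n_free} free parameters")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if model_kind == "kinetic":
                fold_spec = FitSpec(**{**asdict_spec(spec), "seed": spec.seed + k})
                fitted = fit_kinetic(sub, fold_spec)
            elif model_kind == "loglinear":
                fitted = loglinear_fit(sub)
            else:
                fitted = smooth_regressor_fit(sub, kernel_scale=kernel_scale)
        pred = _predict_for_kind(model_kind, fitted, A[k])
        residuals[sid] = (pred[0] - obs[k, 0], pred[1] - obs[k, 1])
    res = np.array(list(residuals.values()))
    return LooResult(
        residuals=residuals,
        rmse_linalool=float(np.sqrt(np.mean(res[:, 0] ** 2))),
        rmse_geraniol=float(np.sqrt(np.mean(res[:, 1] ** 2))),
        warnings=notes,
    )


def asdict_spec(spec: FitSpec) -> dict:
    """FitSpec fields as a plain dict (KineticParameterSet kept intact)."""
    return {
        "free": spec.free,
        "base": spec.base,
        "bounds": spec.bounds,
        "span_decades": spec.span_decades,
        "popsize": spec.popsize,
        "maxiter": spec.maxiter,
        "mutation": spec.mutation,
        "recombination": spec.recombination,
        "seed": spec.seed,
        "space": spec.space,
        "stall_generations": spec.stall_generations,
        "stall_tol": spec.stall_tol,
        "titer_floor": spec.titer_floor,
    }
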