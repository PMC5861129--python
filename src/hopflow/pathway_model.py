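"""Production-prediction models mapping protein profiles to monoterpene titers.

Three models of increasing mechanistic content:

1. A steady-state Michaelis–Menten branch-point model of GPP flux
   competition.  Truncated HMG-CoA reductase (tHMGR) sets precursor supply
   into the prenyl-phosphate pool; the low-processivity FPP-synthase mutant
   (FPPS*) controls what fraction of that flux is released as free GPP
   rather than committed to FPP; linalool synthase, geraniol synthase and
   FPP synthase itself then compete for the single GPP pool, alongside a
   first-order loss term (dephosphorylation/dilution).  The steady-state
   GPP concentration balances supply against total consumption, and branch
   fluxes times a yield factor give titers.
2. A log-linear regression of log10 titers on the four log10 protein
   abundances (ordinary least squares, one model per monoterpene).
3. A Gaussian-process smooth regressor on the same log-abundance features.

The kinetic model is authored here; the two regression models wrap
scikit-learn estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .core_io import GENES, ProteinProfile, StrainDataset
from .metrics import DEFAULT_TITER_FLOOR

__all__ = [
    "NoSteadyStateError",
    "FitError",
    "KineticParameterSet",
    "Prediction",
    "steady_state_gpp",
    "predict_titers",
    "predict_titers_batch",
    "LogLinearModel",
    "loglinear_fit",
    "SmoothRegressor",
    "smooth_regressor_fit",
]

#: Basal relative-abundance floor: 1e-3 keeps ratios finite when a synthase
#: is effectively absent.
ABUNDANCE_FLOOR = 1e-3


class NoSteadyStateError(RuntimeError):
    """Supply exceeds what consumption can balance; no finite steady state."""


class FitError(ValueError):
    """A regression fit failed (e.g. rank-deficient design matrix)."""


@dataclass(frozen=True)
class KineticParameterSet:
    """Parameters of the branch-point kinetic model.

    The nominal values below are order-of-magnitude placeholders that define
    the synthetic ground truth used throughout the package; they are this
    package's own choices, not literature measurements.

    Attributes
    ----------
    v_H : supply-rate coefficient per unit tHMGR abundance (flux / abundance).
    rho_wt, rho_star : GPP release fractions of wild-type FPPS and FPPS*,
        both in [0, 1] with ``rho_star > rho_wt`` (the mutant's reduced
        processivity releases more GPP).
    kcat_L, kcat_G, kcat_F2 : turnover coefficients of linalool synthase,
        geraniol synthase, and the GPP→FPP reaction of FPP synthase.
    K_L, K_G, K_F : Michaelis constants for GPP (concentration units).
    k_d : first-order GPP loss rate (per time).
    alpha_H, alpha_F, alpha_L, alpha_G : free conversion factors from
        relative protein counts to absolute enzyme levels.
    beta : ratio of endogenous FPPS to the engineered FPPS*.
    yield_T : conversion from branch flux to end-of-fermentation titer
        (mg/L per flux unit), absorbing fermentation time and losses.
    """

    v_H: float = 10.0
    rho_wt: float = 0.05
    rho_star: float = 0.5
    kcat_L: float = 20.0
    kcat_G: float = 20.0
    kcat_F2: float = 5.0
    K_L: float = 50.0
    K_G: float = 50.0
    K_F: float = 20.0
    k_d: float = 0.1
    alpha_H: float = 1.0
    alpha_F: float = 1.0
    alpha_L: float = 1.0
    alpha_G: float = 1.0
    beta: float = 1.0
    yield_T: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"kinetic parameter {name}={v!r} must be finite and >= 0")
        if not self.rho_star > self.rho_wt:
            raise ValueError("rho_star must exceed rho_wt (the mutant releases more GPP)")
        for name in ("K_L", "K_G", "K_F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Michaelis constant {name} must be > 0")

    def with_updates(self, **kwargs: float) -> "KineticParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Prediction:
    """Model output: titers, the steady-state GPP level and the flux split."""

    linalool: float
    geraniol: float
    gpp_ss: float
    fluxes: Mapping[str, float] = field(default_factory=dict)


def _enzymes(params: KineticParameterSet, profile: ProteinProfile) -> tuple[float, float, float, float]:
    a = profile.abundance
    return (
        params.alpha_H * a["tHMGR"],
        params.alpha_F * a["FPPS_star"],
        params.alpha_L * a["LIS"],
        params.alpha_G * a["GES"],
    )


def _release_fraction(params: KineticParameterSet, E_F: float) -> float:
    """Effective GPP release fraction θ of the mixed FPPS pool.

    The cell carries both endogenous FPPS (relative level β·E_F) and FPPS*
    (level E_F); the release fraction of the mixture is the abundance-weighted
    mean of the two per-enzyme fractions, which is independent of E_F itself.
    With no FPPS* (E_F = 0) supply is routed through the endogenous enzyme at
    its basal release fraction rho_wt.
    """
    if E_F == 0:
        return params.rho_wt
    if params.beta == 0:
        return params.rho_star
    return (params.rho_star + params.rho_wt * params.beta) / (1.0 + params.beta)


def _supply(params: KineticParameterSet, E_H: float, E_F: float) -> float:
    return params.v_H * E_H * _release_fraction(params, E_F)


def _consumption(params: KineticParameterSet, E_F, E_L, E_G, G):
    """Total GPP consumption rate at concentration G (scalar or array)."""
    p = params
    return (
        p.kcat_L * E_L * G / (p.K_L + G)
        + p.kcat_G * E_G * G / (p.K_G + G)
        + p.kcat_F2 * (1.0 + p.beta) * E_F * G / (p.K_F + G)
        + p.k_d * G
    )


def steady_state_gpp(params: KineticParameterSet, profile: ProteinProfile) -> float:
    """Unique steady-state GPP concentration balancing supply and consumption.

    Supply is zeroth-order in metabolites (upstream substrate treated as
    saturating): supply = v_H · E_H · θ.  Consumption is the sum of three
    saturable branches (LIS, GES, FPPS continuing to FPP) plus first-order
    loss k_d·G, which is strictly increasing in G, so the root is unique.
    Solved by Brent bracketing to 1e-12 relative tolerance.

    Raises
    ------
    NoSteadyStateError
        If supply is positive but no consumption route can balance it
        (k_d = 0 with all saturable capacity below supply).
    """
    E_H, E_F, E_L, E_G = _enzymes(params, profile)
    supply = _supply(params, E_H, E_F)
    if supply == 0.0:
        return 0.0

    def f(G: float) -> float:
        return supply - _consumption(params, E_F, E_L, E_G, G)

    if params.k_d > 0:
        hi = supply / params.k_d  # consumption(hi) >= k_d*hi = supply
    else:
        vmax = (
            params.kcat_L * E_L
            + params.kcat_G * E_G
            + params.kcat_F2 * (1.0 + params.beta) * E_F
        )
        if vmax <= supply:
            raise NoSteadyStateError(
                "positive supply with k_d = 0 and saturable capacity "
                f"{vmax:.4g} <= supply {supply:.4g}"
            )
        hi = max(params.K_L, params.K_G, params.K_F)
        while f(hi) > 0:
            hi *= 2.0
    if f(hi) == 0.0:
        return hi
    return float(brentq(f, 0.0, hi, rtol=1e-12, xtol=1e-300, maxiter=200))


def predict_titers(params: KineticParameterSet, profile: ProteinProfile) -> Prediction:
    """Predict linalool/geraniol titers (mg/L) from one protein profile."""
    E_H, E_F, E_L, E_G = _enzymes(params, profile)
    G = steady_state_gpp(params, profile)
    p = params
    flux_L = p.kcat_L * E_L * G / (p.K_L + G)
    flux_G = p.kcat_G * E_G * G / (p.K_G + G)
    flux_F = p.kcat_F2 * (1.0 + p.beta) * E_F * G / (p.K_F + G)
    flux_d = p.k_d * G
    return Prediction(
        linalool=p.yield_T * flux_L,
        geraniol=p.yield_T * flux_G,
        gpp_ss=G,
        fluxes={"linalool": flux_L, "geraniol": flux_G, "fpp": flux_F, "leak": flux_d},
    )


def predict_titers_batch(
    params: KineticParameterSet, abundance: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized titer prediction for an (n, 4) abundance matrix.

    Columns follow the canonical gene order (tHMGR, FPPS*, LIS, GES).  The
    steady state is found per row by vectorized bisection on the exact
    bracket [0, supply/k_d] (requires k_d > 0; rows with zero supply yield
    zero).  120 bisection iterations put the root far below the 1e-10
    relative tolerance of the scalar solver.
    """
    A = np.asarray(abundance, dtype=float)
    if A.ndim != 2 or A.shape[1] != len(GENES):
        raise ValueError(f"abundance must be (n, {len(GENES)})")
    if params.k_d <= 0:
        # fall back to the scalar solver row by row
        out = [
            predict_titers(params, ProteinProfile("_", dict(zip(GENES, row))))
            for row in A
        ]
        return (
            np.array([o.linalool for o in out]),
            np.array([o.geraniol for o in out]),
        )
    p = params
    E_H = p.alpha_H * A[:, 0]
    E_F = p.alpha_F * A[:, 1]
    E_L = p.alpha_L * A[:, 2]
    E_G = p.alpha_G * A[:, 3]
    theta = np.where(
        E_F == 0,
        p.rho_wt,
        p.rho_star if p.beta == 0 else (p.rho_star + p.rho_wt * p.beta) / (1.0 + p.beta),
    )
    supply = p.v_H * E_H * theta

    lo = np.zeros_like(supply)
    hi = supply / p.k_d
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        excess = supply - _consumption(p, E_F, E_L, E_G, mid)
        take_hi = excess < 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    G = 0.5 * (lo + hi)
    lin = p.yield_T * p.kcat_L * E_L * G / (p.K_L + G)
    ger = p.yield_T * p.kcat_G * E_G * G / (p.K_G + G)
    return lin, ger


# ---------------------------------------------------------------------------
# Log-linear model
# ---------------------------------------------------------------------------


def _log_features(abundance: np.ndarray, floor: float) -> np.ndarray:
    return np.log10(np.asarray(abundance, dtype=float) + floor)


@dataclass
class LogLinearModel:
    """Per-monoterpene OLS of log10(titer + floor) on log10(abundance + floor)."""

    coef: np.ndarray  # shape (2, 5): [species, (intercept, 4 slopes)]
    titer_floor: float
    abundance_floor: float

    def predict(self, abundance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted (linalool, geraniol) arrays, mapped back to linear scale."""
        X = _log_features(np.atleast_2d(abundance), self.abundance_floor)
        Xd = np.hstack([np.ones((X.shape[0], 1)), X])
        logt = Xd @ self.coef.T
        t = np.maximum(10.0 ** logt - self.titer_floor, 0.0)
        return t[:, 0], t[:, 1]

    def predict_profile(self, profile: ProteinProfile) -> Prediction:
        row = np.array([[profile.abundance[g] for g in GENES]])
        lin, ger = self.predict(row)
        return Prediction(linalool=float(lin[0]), geraniol=float(ger[0]), gpp_ss=float("nan"))


def loglinear_fit(
    dataset: StrainDataset,
    titer_floor: float = DEFAULT_TITER_FLOOR,
    abundance_floor: float = ABUNDANCE_FLOOR,
) -> LogLinearModel:
    """Fit the log-linear model on replicate-mean titers.

    With 5 coefficients per monoterpene, at least 6 strains are recommended;
    an underdetermined fit warns and returns the minimum-norm solution.
    A rank-deficient design matrix (collinear abundance columns) raises
    :class:`FitError` naming the collinear genes.
    """
    ids, rows = dataset.abundance_matrix()
    X = _log_features(np.array(rows), abundance_floor)
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])
    n, pdim = Xd.shape
    if n < pdim + 1:
        warnings.warn(
            f"log-linear fit with {n} strains for {pdim} coefficients is underdetermined",
            stacklevel=2,
        )
    if n >= pdim and np.linalg.matrix_rank(Xd) < pdim:
        full_rank = np.linalg.matrix_rank(Xd)
        collinear = [
            GENES[j - 1]
            for j in range(1, pdim)
            if np.linalg.matrix_rank(np.delete(Xd, j, axis=1)) == full_rank
        ]
        raise FitError(f"rank-deficient design matrix; collinear columns: {collinear}")
    means = dataset.mean_titers()
    Y = np.log10(np.array([means[s] for s in ids]) + titer_floor)
    coef, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    return LogLinearModel(coef=coef.T, titer_floor=titer_floor, abundance_floor=abundance_floor)


# ---------------------------------------------------------------------------
# Smooth (Gaussian-process) regressor
# ---------------------------------------------------------------------------


@dataclass
class SmoothRegressor:
    """GP regressors (RBF kernel) on log-abundance features, one per species.

    Trained in log10 titer space with the prior mean pinned to the training
    mean (``normalize_y``), so predictions far from all training points
    revert toward the training-set mean.
    """

    gps: tuple[GaussianProcessRegressor, GaussianProcessRegressor]
    titer_floor: float
    abundance_floor: float

    def predict(self, abundance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = _log_features(np.atleast_2d(abundance), self.abundance_floor)
        preds = [np.maximum(10.0 ** gp.predict(X) - self.titer_floor, 0.0) for gp in self.gps]
        return preds[0], preds[1]

    def predict_profile(self, profile: ProteinProfile) -> Prediction:
        row = np.array([[profile.abundance[g] for g in GENES]])
        lin, ger = self.predict(row)
        return Prediction(linalool=float(lin[0]), geraniol=float(ger[0]), gpp_ss=float("nan"))


def smooth_regressor_fit(
    dataset: StrainDataset,
    kernel_scale: float = 1.0,
    noise: float = 1e-10,
    titer_floor: float = DEFAULT_TITER_FLOOR,
    abundance_floor: float = ABUNDANCE_FLOOR,
) -> SmoothRegressor:
    """Fit the GP smooth regressor; ``kernel_scale`` is the RBF length scale."""
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be > 0")
    if len(dataset) < 4:
        raise FitError("smooth regressor needs at least 4 strains")
    ids, rows = dataset.abundance_matrix()
    X = _log_features(np.array(rows), abundance_floor)
    means = dataset.mean_titers()
    Y = np.log10(np.array([means[s] for s in ids]) + titer_floor)
    gps = []
    for col in range(2):
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0, "fixed") * RBF(kernel_scale, "fixed"),
            alpha=noise,
            normalize_y=True,
            optimizer=None,
        )
        gp.fit(X, Y[:, col])
        gps.append(gp)
    return SmoothRegressor(
        gps=(gps[0], gps[1]), titer_floor=titer_floor, abundance_floor=abundance_floor
    )
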