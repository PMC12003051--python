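"""Decorrelation-time estimation from speckle contrast.

Two estimators link the measured spatial contrast Ks to the field
decorrelation time tau_c (inversely related to scatterer speed, the basis of
the blood flow index BFI = 1 / tau_c):

* the single-exposure LSCI asymptotic approximation, BFI = 1 / (T Ks^2),
  valid when T / tau_c > 100;
* nonlinear regression of the multi-exposure (MESI) model

      K(T)^2 = beta rho^2 (e^{-2x} - 1 + 2x) / (2 x^2)
             + 4 beta rho (1 - rho) (e^{-x} - 1 + x) / x^2
             + v_ne + v_noise,        x = T / tau_c,

  where beta is the instrumental coherence factor, rho the dynamic-scatterer
  fraction, and v_ne / v_noise additive nonergodic and noise variance
  offsets.  Parameters are constrained to the physical box
  0.05 <= beta <= 0.5, 0.1 <= rho <= 1, 0 < tau_c < 10 ms,
  0 <= v_noise < 0.30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, NamedTuple, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_BOUNDS",
    "MESIFit",
    "mesi_model",
    "fit_mesi",
    "lsci_asymptotic_tau",
    "bfi",
]

_PARAM_ORDER = ("beta", "rho", "tau_c", "v_ne", "v_noise")

#: Physical box constraints for the MESI regression (tau_c in ms).
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "beta": (0.05, 0.5),
    "rho": (0.1, 1.0),
    "tau_c": (1e-4, 10.0),
    "v_ne": (0.0, 0.30),
    "v_noise": (0.0, 0.30),
}

_SERIES_CUTOFF = 0.05


def _h(y: np.ndarray) -> np.ndarray:
    """(e^-y - 1 + y) / y^2, series-expanded below the cancellation cutoff.

    The direct form loses ~eps/y^2 relative accuracy as y -> 0; below the
    cutoff the alternating series sum_k (-y)^k / (k+2)! truncated at y^6
    keeps both branches accurate to ~1e-13, so they agree at the switchover.
    """
    y = np.asarray(y, dtype=float)
    small = y < _SERIES_CUTOFF
    ysafe = np.where(small, 1.0, y)
    direct = (np.exp(-ysafe) - 1.0 + ysafe) / (ysafe * ysafe)
    series = 1.0 / 2 + y * (
        -1.0 / 6 + y * (1.0 / 24 + y * (-1.0 / 120 + y * (1.0 / 720 + y * (-1.0 / 5040 + y / 40320))))
    )
    return np.where(small, series, direct)


def mesi_model(T, beta, rho, tau_c, v_ne=0.0, v_noise=0.0):
    """Model contrast K(T) for exposure(s) ``T`` (ms).

    Numerically stable from x = T/tau_c ~ 1e-12 (series branch) to the deep
    asymptote; K -> sqrt(beta rho (2 - rho) + v) as T -> 0 and
    K^2 -> beta rho^2 tau_c / T as T -> infinity (for v = 0).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("exposure times must be positive")
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    x = T / tau_c
    k2 = (
        beta * rho * rho * 2.0 * _h(2.0 * x)
        + 4.0 * beta * rho * (1.0 - rho) * _h(x)
        + v_ne
        + v_noise
    )
    return np.sqrt(np.maximum(k2, 0.0))


@dataclass
class MESIFit:
    """Result of a bounded MESI regression."""

    beta: float
    rho: float
    tau_c: float
    v_ne: float
    v_noise: float
    residual_rms: float
    n_points: int
    fixed_mask: Tuple[str, ...]
    identifiable: bool = True

    @property
    def params(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_ORDER}

    def predict(self, T):
        return mesi_model(T, **self.params)


def fit_mesi(
    points,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    fixed: Optional[Dict[str, float]] = None,
    n_starts: int = 8,
) -> MESIFit:
    """Fit the MESI model to ``points`` = sequence of (T_ms, Ks) pairs.

    Minimizes the sum of squared residuals in K (the observable, not K^2)
    with a bounded trust-region least-squares solver, multi-started over a
    log-spaced tau_c grid; deterministic for a given point set.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        Exposure times (ms) and measured mean contrasts.
    bounds : dict, optional
        Per-parameter (lo, hi) overrides of :data:`DEFAULT_BOUNDS`.
    fixed : dict, optional
        Parameters held at given values, e.g. ``{"rho": 1, "v_ne": 0,
        "v_noise": 0}`` for noise-free, purely dynamic simulations.  By
        default ``v_ne`` is held at 0 (pooled into ``v_noise``).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (T, Ks) pairs")
    T, K = pts[:, 0], pts[:, 1]
    if np.any(T <= 0):
        raise ValueError("exposure times must be positive")
    if len(np.unique(T)) != len(T):
        raise ValueError("exposure times must be distinct")
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    fixed = {"v_ne": 0.0, **(fixed or {})}
    for name in fixed:
        if name not in _PARAM_ORDER:
            raise ValueError(f"unknown parameter {name!r}")
    free = [p for p in _PARAM_ORDER if p not in fixed]
    if len(T) < max(2, len(free)):
        raise ValueError(f"need at least {max(2, len(free))} points to fit {free}")
    identifiable = bool(np.ptp(K) > 0)
    if not identifiable:
        warnings.warn("all contrast values identical; fit is non-identifiable", stacklevel=2)

    lo = np.array([box[p][0] for p in free])
    hi = np.array([box[p][1] for p in free])

    def residual(theta):
        params = dict(fixed)
        params.update(zip(free, theta))
        return mesi_model(T, **params) - K

    init = {"beta": 0.25, "rho": 0.9, "v_ne": 0.01, "v_noise": 0.01}
    tau_grid = np.geomspace(max(0.01, box["tau_c"][0]), min(10.0, box["tau_c"][1]), n_starts)
    best = None
    for tau0 in tau_grid if "tau_c" in free else [None]:
        x0 = []
        for p in free:
            v = tau0 if p == "tau_c" else init[p]
            x0.append(np.clip(v, box[p][0], box[p][1]))
        sol = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    params = dict(fixed)
    params.update(zip(free, best.x))
    rms = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    return MESIFit(
        beta=float(params.get("beta")),
        rho=float(params.get("rho")),
        tau_c=float(params.get("tau_c")),
        v_ne=float(params.get("v_ne")),
        v_noise=float(params.get("v_noise")),
        residual_rms=rms,
        n_points=len(T),
        fixed_mask=tuple(sorted(fixed)),
        identifiable=identifiable,
    )


class AsymptoticTau(NamedTuple):
    tau_c: np.ndarray
    reliable: np.ndarray


def bfi(ks, T):
    """Blood flow index 1 / (T Ks^2) from a single exposure."""
    ks = np.asarray(ks, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("exposure time must be positive")
    if np.any(ks <= 0):
        raise ValueError("Ks must be positive (zero contrast has no defined BFI)")
    return 1.0 / (T * ks * ks)


def lsci_asymptotic_tau(ks, T, beta) -> AsymptoticTau:
    """Asymptotic single-exposure tau_c estimate T Ks^2 / beta (ms).

    Inverts the large-x limit K^2 = beta tau_c / T; the companion flag is
    False where the estimate violates its own validity condition
    T / tau_c >= 100.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    ks = np.asarray(ks, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("exposure time must be positive")
    if np.any(ks <= 0):
        raise ValueError("Ks must be positive")
    tau = T * ks * ks / beta
    reliable = (T / tau) >= 100.0
    return AsymptoticTau(tau, reliable)
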