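"""Closed-form moment solutions and derived analyses.

With the division rate choice ``k_d = 2/t`` both models predict
quadratic growth of the total cell number, ``N(t) = N̄0·t²``.  They
differ in the total ALP activity:

* progressive differentiation (PSCD): ``Φ(t) = Φ̄0·t²·e^{−d0·t}`` —
  rises, peaks at ``t* = 2/d0`` and decays, matching the observed
  rise-and-fall of ALP in osteogenic cultures;
* instantaneous differentiation (ISCD): ``Φ(t) = Φ̄0·t²`` — strictly
  increasing, which is what rules the model out against data with an
  interior ALP peak.

Eliminating time between ``k_d = 2/t`` and ``N = N̄0·t²`` with the
density relation ``ρ = N/V`` gives the division-rate/density curve
``k_d(ρ) = 2·sqrt(N̄0/(ρ·V))``: division slows as the culture grows
denser, with log–log slope exactly −1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .model_core import ISCDParams, PSCDParams

__all__ = [
    "pscd_total_cells",
    "pscd_total_alp",
    "pscd_peak_time",
    "iscd_moments",
    "DensityRateCurve",
    "density_rate_curve",
]

ArrayLike = Union[float, np.ndarray]


def _check_time(t: ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def pscd_total_cells(t: ArrayLike, params: PSCDParams) -> ArrayLike:
    """Total cell number ``N(t) = N̄0·t²`` (cells)."""
    t = _check_time(t)
    out = params.N_bar0 * t**2
    return float(out) if out.ndim == 0 else out


def pscd_total_alp(t: ArrayLike, params: PSCDParams) -> ArrayLike:
    """Total ALP activity ``Φ(t) = Φ̄0·t²·e^{−d0·t}`` (activity units)."""
    t = _check_time(t)
    if params.d0 <= 0:
        raise ValueError("d0 must be positive")
    out = params.Phi_bar0 * t**2 * np.exp(-params.d0 * t)
    return float(out) if out.ndim == 0 else out


def pscd_peak_time(params: PSCDParams) -> float:
    """Day of maximal total ALP activity: the unique stationary point
    ``t* = 2/d0`` of ``t²·e^{−d0·t}`` on ``t > 0``."""
    if params.d0 <= 0:
        raise ValueError("d0 must be positive")
    return 2.0 / params.d0


def iscd_moments(t: ArrayLike, params: ISCDParams) -> Tuple[ArrayLike, ArrayLike]:
    """ISCD moments ``(N, Φ) = (N̄0·t², Φ̄0·t²)``; both grow monotonically."""
    t = _check_time(t)
    N = params.N_bar0 * t**2
    Phi = params.Phi_bar0 * t**2
    if N.ndim == 0:
        return float(N), float(Phi)
    return N, Phi


@dataclass
class DensityRateCurve:
    """Division rate as a function of cell number density.

    ``rho`` in cells per volume unit of the (fixed, arbitrary-unit)
    scaffold volume ``V``; ``k_d`` per day, strictly decreasing in rho.
    """

    V: float
    N_bar0: float
    rho: np.ndarray
    k_d: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.k_d = np.asarray(self.k_d, dtype=float)
        if np.any(self.rho <= 0) or np.any(self.k_d <= 0):
            raise ValueError("rho and k_d must be positive")
        order = np.argsort(self.rho)
        if np.any(np.diff(self.k_d[order]) >= 0):
            raise ValueError("k_d must be strictly decreasing in rho")

    def loglog_slope(self) -> float:
        """Finite-difference slope of log k_d vs log rho (exactly −1/2)."""
        lr, lk = np.log(self.rho), np.log(self.k_d)
        slopes = np.diff(lk) / np.diff(lr)
        return float(np.mean(slopes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.rho, "k_d": self.k_d})


def density_rate_curve(params: PSCDParams, V: float,
                       rho_values: np.ndarray) -> DensityRateCurve:
    """Division-rate/density relation ``k_d(ρ) = 2·sqrt(N̄0/(ρ·V))``.

    Obtained by eliminating ``t`` between ``k_d = 2/t`` and
    ``N = N̄0·t²`` with ``ρ = N/V``.  Note the exact exponent is −1/2
    (a quadrupling of the density halves the division rate), i.e. an
    inverse-square-root, not inverse-proportional, dependence.
    """
    rho = np.asarray(rho_values, dtype=float)
    if V <= 0:
        raise ValueError("V must be positive")
    if rho.size == 0 or np.any(rho <= 0):
        raise ValueError("rho values must be positive")
    if params.N_bar0 <= 0:
        raise ValueError("N_bar0 must be positive for the density curve")
    k_d = 2.0 * np.sqrt(params.N_bar0 / (rho * V))
    return DensityRateCurve(V=float(V), N_bar0=params.N_bar0, rho=rho, k_d=k_d)
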