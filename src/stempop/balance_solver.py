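"""Numerical integration of the ALP-activity population-balance equation.

The state is the density ``n(a, t)`` of cells over ALP activity ``a``,
discretized on a fixed strictly increasing grid.  The dynamics combine

* division gain/loss (local term ``g(t)·k·n`` for symmetric
  non-conserved divisions; double-quadrature gain and single-quadrature
  loss for a general activity-conserving kernel),
* terminal differentiation loss ``−k_f(a)·n``,
* activity drift written in conservative form
  ``−∂[(s_i(a) − d_o(a))·n]/∂a``.

The degradation term enters through the conservative flux
``+∂(d_o(a)·n)/∂a``: with the activity-proportional choice
``d_o(a) = d0·a`` this yields the moment balance ``dΦ/dt ⊃ −d0·Φ``
while leaving the cell count untouched (no flux through ``a = 0``
because ``d_o(0) = 0``).

Numerics: finite-volume advection with first-order upwind fluxes
(default) or a van-Leer-limited MUSCL reconstruction; explicit Euler
(default) or Heun time stepping; fixed steps with a CFL guard.  The
activity grid may be uniform (default) or geometric.  A geometric grid
with the MUSCL flux is strongly recommended whenever degradation makes
the distribution contract toward ``a = 0`` over many e-foldings —
first-order upwind on a uniform grid then suffers severe numerical
diffusion and overestimates Φ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .model_core import DivisionMode, ModelSpec

__all__ = [
    "ALPDistribution",
    "MomentSeries",
    "compute_moments",
    "make_grid",
    "gamma_distribution",
    "solve_population_balance",
    "moment_rates",
]

_NEG_TOL = -1e-12


@dataclass
class ALPDistribution:
    """Discretized cell density over ALP activity at one time point.

    ``density[i]`` has units cells per activity unit; integrals over the
    grid give cell numbers.
    """

    grid: np.ndarray
    density: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 3:
            raise ValueError("grid must be 1-D with at least 3 points")
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid[0] < 0:
            raise ValueError("activities must be non-negative")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density contains non-finite values")
        if np.any(self.density < _NEG_TOL):
            raise ValueError("density has negative entries beyond tolerance")
        self.density = np.clip(self.density, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "a": self.grid, "n": self.density})


@dataclass
class MomentSeries:
    """Time courses of the total cell number N and total ALP activity Φ."""

    times: np.ndarray
    N: np.ndarray
    Phi: np.ndarray
    #: cumulative cells lost through the a=0 boundary (only nonzero when
    #: the degradation flux does not vanish at 0)
    boundary_loss: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.Phi = np.asarray(self.Phi, dtype=float)
        if not (self.times.shape == self.N.shape == self.Phi.shape):
            raise ValueError("times, N and Phi must have equal length")
        for arr, name in ((self.N, "N"), (self.Phi, "Phi")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "N": self.N, "Phi": self.Phi})


def compute_moments(dist: ALPDistribution) -> Tuple[float, float]:
    """Zeroth and first moments (N, Φ) by trapezoidal quadrature."""
    if not np.all(np.isfinite(dist.density)):
        raise ValueError("density contains NaN/inf")
    N = float(np.trapezoid(dist.density, dist.grid))
    Phi = float(np.trapezoid(dist.grid * dist.density, dist.grid))
    return N, Phi


def make_grid(a_max: float, n_points: int = 400, spacing: str = "uniform",
              a_min: float = 0.0) -> np.ndarray:
    """Activity grid on [a_min, a_max]; 'uniform' or 'geometric' spacing.

    A geometric grid needs ``a_min > 0``; if 0 is passed, ``a_max·1e-5``
    is used.
    """
    if a_max <= max(a_min, 0.0):
        raise ValueError("a_max must be positive and exceed a_min")
    if n_points < 3:
        raise ValueError("need at least 3 grid points")
    if spacing == "uniform":
        return np.linspace(a_min, a_max, n_points)
    if spacing == "geometric":
        lo = a_min if a_min > 0 else a_max * 1e-5
        return np.geomspace(lo, a_max, n_points)
    raise ValueError("spacing must be 'uniform' or 'geometric'")


def gamma_distribution(n_cells: float, mean_activity: float, grid: np.ndarray,
                       shape: float = 2.0, time: float = 0.0) -> ALPDistribution:
    """Gamma-shaped density with given total cell number and mean activity.

    The default shape 2 gives a broad unimodal profile vanishing at
    ``a = 0``; used as the demonstration initial condition since the
    assay constrains only the moments, not the distribution shape.
    """
    if n_cells < 0 or mean_activity <= 0:
        raise ValueError("need n_cells >= 0 and mean_activity > 0")
    scale = mean_activity / shape
    pdf = _gamma_dist.pdf(grid, shape, scale=scale)
    mass = np.trapezoid(pdf, grid)
    if mass <= 0:
        raise ValueError("grid does not cover the gamma distribution support")
    return ALPDistribution(grid=grid, density=pdf * (n_cells / mass), time=time)


def _auto_amax(dist: ALPDistribution) -> float:
    """Default domain cap: 10x the 99th percentile of the distribution."""
    w = _trapz_weights(dist.grid) * dist.density
    c = np.cumsum(w)
    if c[-1] <= 0:
        return float(dist.grid[-1])
    q = np.searchsorted(c / c[-1], 0.99)
    return 10.0 * float(dist.grid[min(q, dist.grid.size - 1)])


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


class _Advection:
    """Conservative finite-volume advection on a fixed node grid."""

    def __init__(self, model: ModelSpec, grid: np.ndarray, flux: str):
        self.grid = grid
        self.flux = flux
        faces = 0.5 * (grid[1:] + grid[:-1])
        self.v_face = model.drift_velocity(faces)
        self.v_bottom = float(model.drift_velocity(np.array([grid[0]]))[0])
        self.dx = _trapz_weights(grid)  # control-volume widths

    def max_stable_dt(self) -> float:
        widths = np.minimum.reduce([
            np.concatenate([[np.inf], np.abs(np.diff(self.grid))]),
            np.concatenate([np.abs(np.diff(self.grid)), [np.inf]]),
        ])
        face_w = np.minimum(widths[:-1], widths[1:])
        speed = np.abs(self.v_face)
        with np.errstate(divide="ignore"):
            dts = np.where(speed > 0, face_w / speed, np.inf)
        dt = float(np.min(dts)) if dts.size else math.inf
        if self.v_bottom < 0 and self.grid[0] > 0:
            dt = min(dt, self.dx[0] / abs(self.v_bottom))
        return dt

    def __call__(self, n: np.ndarray) -> Tuple[np.ndarray, float]:
        """Return (dn/dt from advection, instantaneous outflow rate at a=0)."""
        vf = self.v_face
        if self.flux == "upwind":
            F = np.where(vf > 0, vf * n[:-1], vf * n[1:])
        elif self.flux == "muscl":
            d = np.diff(n)
            s = np.zeros_like(n)
            num = 2.0 * d[1:] * d[:-1]
            den = d[1:] + d[:-1]
            s[1:-1] = np.where(num > 0, num / np.where(den == 0.0, 1.0, den), 0.0)
            F = np.where(vf > 0, vf * (n[:-1] + 0.5 * s[:-1]),
                         vf * (n[1:] - 0.5 * s[1:]))
        else:
            raise ValueError("flux must be 'upwind' or 'muscl'")
        dndt = np.zeros_like(n)
        dndt[1:-1] = -(F[1:] - F[:-1]) / self.dx[1:-1]
        # lower boundary: outflow only if drift is negative there
        F_bot = self.v_bottom * n[0] if self.v_bottom < 0 else 0.0
        dndt[0] = -(F[0] - F_bot) / self.dx[0]
        # upper boundary: zero inflow; outflow if drift positive
        F_top = vf[-1] * n[-1] if vf[-1] > 0 else 0.0
        dndt[-1] = -(F_top - F[-1]) / self.dx[-1]
        return dndt, -F_bot  # -F_bot >= 0 is the cell-loss rate at a=0


class _ConservedDivision:
    """Quadrature of the conserved-division gain and loss terms.

    Midpoint (rectangle) weights are used for both integrals so that,
    for a symmetric kernel, the discrete first moment is conserved
    exactly (the anti-diagonal pairing of gain and loss cancels term by
    term).  Requires a uniform grid.
    """

    def __init__(self, model: ModelSpec, grid: np.ndarray):
        h = np.diff(grid)
        if not np.allclose(h, h[0], rtol=1e-10, atol=0.0):
            raise ValueError("conserved division requires a uniform grid")
        self.da = float(h[0])
        A, Ap = np.meshgrid(grid, grid, indexing="ij")
        K = np.asarray(model.division_kernel(A, Ap), dtype=float)
        if np.any(K < 0) or not np.all(np.isfinite(K)):
            raise ValueError("division kernel must be finite and non-negative")
        if not np.allclose(K, K.T, rtol=1e-8, atol=1e-12):
            raise ValueError("division kernel must be symmetric in the daughters")
        self.K = K
        G = grid.size
        # loss_i = 0.5 * da * n_i * sum_{j<=i} K[i-j, j]
        flipped = K[::-1, :]
        self.loss_coeff = 0.5 * self.da * np.array(
            [np.trace(flipped, offset=G - 1 - i) for i in range(G)])

    def __call__(self, n: np.ndarray) -> np.ndarray:
        G = n.size
        gain = np.empty_like(n)
        for i in range(G):
            m = G - i
            gain[i] = self.da * float(np.dot(self.K[i, :m], n[i:]))
        return gain - self.loss_coeff * n


def solve_population_balance(
    model: ModelSpec,
    initial: ALPDistribution,
    t_start: float,
    t_end: float,
    n_steps: int,
    scheme: str = "euler",
    flux: str = "upwind",
    n_snapshots: int = 5,
) -> Tuple[List[ALPDistribution], MomentSeries]:
    """Time-march the population balance from ``t_start`` to ``t_end``.

    Parameters
    ----------
    scheme
        'euler' (first order) or 'heun' (second order) in time.
    flux
        'upwind' (first order) or 'muscl' (van-Leer-limited, second
        order) advection flux.
    n_snapshots
        Number of evenly spaced density snapshots to return (always
        includes the initial and final states).

    Returns
    -------
    snapshots, moments
        Density snapshots and the per-step moment series.

    Raises
    ------
    ValueError
        If the step size violates the advection CFL condition (the
        message names the largest stable step), or if rates are invalid.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    model.validate(a_probe=initial.grid[:: max(1, initial.grid.size // 16)],
                   t_probe=np.array([t_start, t_end]))
    try:
        model.division_time_factor(t_start)
    except ValueError as exc:
        raise ValueError(f"division_time_factor invalid at t_start={t_start}: {exc}")

    grid = initial.grid
    n = initial.density.copy()
    dt = (t_end - t_start) / n_steps

    adv = _Advection(model, grid, flux)
    dt_max = adv.max_stable_dt()
    if dt > dt_max:
        raise ValueError(
            f"CFL violation: step {dt:.4g} d exceeds the largest stable step "
            f"{dt_max:.4g} d for the advection speeds on this grid; "
            f"use n_steps >= {math.ceil((t_end - t_start) / dt_max)}")

    conserved = None
    if model.division_mode is DivisionMode.CONSERVED:
        conserved = _ConservedDivision(model, grid)

    k_f = np.asarray(model.differentiation_rate(grid), dtype=float)
    w = _trapz_weights(grid)

    def rhs(n, t):
        dndt, outflow = adv(n)
        if conserved is not None:
            dndt = dndt + model.division_time_factor(t) * conserved(n)
        else:
            dndt = dndt + model.division_time_factor(t) * model.division_rate * n
        dndt = dndt - k_f * n
        return dndt, outflow

    times = np.empty(n_steps + 1)
    Ns = np.empty(n_steps + 1)
    Phis = np.empty(n_steps + 1)
    lost = np.empty(n_steps + 1)
    times[0], Ns[0], Phis[0] = t_start, np.sum(w * n), np.sum(w * grid * n)
    lost[0] = 0.0

    snap_idx = set(np.unique(np.round(
        np.linspace(0, n_steps, max(2, n_snapshots))).astype(int)))
    snapshots = [ALPDistribution(grid=grid, density=n.copy(), time=t_start)]

    t = t_start
    for step in range(1, n_steps + 1):
        d1, out1 = rhs(n, t)
        if scheme == "euler":
            n_new = n + dt * d1
            out = out1
        elif scheme == "heun":
            pred = np.clip(n + dt * d1, 0.0, None)
            d2, out2 = rhs(pred, t + dt)
            n_new = n + 0.5 * dt * (d1 + d2)
            out = 0.5 * (out1 + out2)
        else:
            raise ValueError("scheme must be 'euler' or 'heun'")
        if np.any(n_new < _NEG_TOL * max(1.0, float(np.max(np.abs(n_new))))):
            n_new = np.clip(n_new, 0.0, None)
        n = np.clip(n_new, 0.0, None)
        t = t_start + step * dt
        times[step] = t
        Ns[step] = np.sum(w * n)
        Phis[step] = np.sum(w * grid * n)
        lost[step] = lost[step - 1] + dt * out
        if step in snap_idx:
            snapshots.append(ALPDistribution(grid=grid, density=n.copy(), time=t))

    moments = MomentSeries(times=times, N=Ns, Phi=Phis, boundary_loss=lost)
    return snapshots, moments


def moment_rates(model: ModelSpec, dist: ALPDistribution) -> Tuple[float, float]:
    """Instantaneous (dN/dt, dΦ/dt) implied by the balance relations.

    For conserved division the gain is the double quadrature
    ``(1/2)∫∫ k_d(a, a')·n(a + a') da da'``; for symmetric non-conserved
    division the division terms reduce to ``g(t)·k·N`` and ``g(t)·k·Φ``.
    Differentiation contributes ``−∫k_f·n`` to N and ``−∫a·k_f·n`` to Φ;
    the activity fluxes contribute ``∫(s_i − d_o)·n`` to Φ only.
    """
    grid, n = dist.grid, dist.density
    if not np.all(np.isfinite(n)):
        raise ValueError("density contains NaN/inf")
    N, Phi = compute_moments(dist)
    g = model.division_time_factor(dist.time)
    k_f = np.asarray(model.differentiation_rate(grid), dtype=float)
    diff_N = float(np.trapezoid(k_f * n, grid))
    diff_Phi = float(np.trapezoid(grid * k_f * n, grid))
    flux_Phi = float(np.trapezoid(model.drift_velocity(grid) * n, grid))
    if model.division_mode is DivisionMode.CONSERVED:
        cd = _ConservedDivision(model, grid)
        w = _trapz_weights(grid)
        dndt_div = g * cd(n)
        div_N = float(np.sum(w * dndt_div))
        div_Phi = float(np.sum(w * grid * dndt_div))
    else:
        div_N = g * model.division_rate * N
        div_Phi = g * model.division_rate * Phi
    return div_N - diff_N, div_Phi + flux_Phi - diff_Phi
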