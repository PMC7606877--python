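"""Model definitions for stem-cell population-balance kinetics.

A mesenchymal stem-cell population is described by the distribution
``n(a, t)`` of intracellular ALP (alkaline phosphatase) activity ``a``
across cells at time ``t``.  Four single-cell processes drive the
dynamics:

* **division** at rate ``k_d(a, a')`` — a cell is replaced by two
  daughters; in *conserved* mode the parent activity is split between
  the daughters, in *non-conserved symmetric* mode both daughters copy
  the parent activity (the Dirac-delta kernel ``k·δ(a − a')``, which we
  represent analytically by the scalar amplitude ``k`` rather than by
  discretizing a delta function);
* **terminal differentiation** (loss from the stem-cell pool) at rate
  ``k_f(a)``;
* **ALP biosynthesis** in-flux ``s_i(a)`` and **ALP degradation**
  out-flux ``d_o(a)``, which drift a cell's activity up or down.

Two concrete models are provided as presets:

* ``pscd_model`` — progressive stem-cell differentiation: symmetric
  non-conserved division with effective rate ``2/t`` and gradual ALP
  loss ``d_o(a) = d0·a`` (no explicit cell removal);
* ``iscd_model`` — instantaneous stem-cell differentiation: the same
  division process plus a constant whole-cell removal rate ``k_f``.

The time dependence of the division rate is kept separable: kernels are
time-independent and a scalar ``division_time_factor`` ``g(t)``
multiplies the division terms.  For the ``2/t`` choice the presets use
amplitude ``k = 1`` and ``g(t) = 2/t``, which diverges at ``t = 0`` —
solvers must therefore start at a strictly positive time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Mapping, Optional

import numpy as np

__all__ = [
    "DivisionMode",
    "ModelSpec",
    "PSCDParams",
    "ISCDParams",
    "pscd_model",
    "iscd_model",
    "conserved_model",
    "convert_params",
    "model_from_config",
]


class DivisionMode(str, Enum):
    """How a division event distributes ALP activity to the daughters."""

    CONSERVED = "conserved"
    NON_CONSERVED_SYMMETRIC = "non_conserved_symmetric"


def _zero(a):
    return np.zeros_like(np.asarray(a, dtype=float))


def _one_t(t):
    return 1.0


@dataclass(frozen=True)
class ModelSpec:
    """Full kernel-level specification of a population-balance model.

    Parameters
    ----------
    division_rate
        Scalar amplitude ``k`` (per day) of the delta-type division
        kernel ``k·δ(a − a')``; the rate actually applied at time ``t``
        is ``division_time_factor(t) * k``.  Used in
        ``non_conserved_symmetric`` mode.
    division_kernel
        General daughter-pair kernel ``k_d(a, a')`` (per day per
        activity unit), used in ``conserved`` mode; must be symmetric in
        its arguments and non-negative.
    division_mode
        See :class:`DivisionMode`.
    division_time_factor
        Dimensionless multiplier ``g(t)`` applied to all division
        terms; default constant 1.  ``g(t) = 2/t`` reproduces the
        density-dependent division slowdown inferred from quadratic
        cell growth.
    differentiation_rate, synthesis_flux, degradation_flux
        Vectorized callables of activity ``a``: removal rate ``k_f(a)``
        (per day), biosynthesis in-flux ``s_i(a)`` and degradation
        out-flux ``d_o(a)`` (activity units per day).
    drift_exact
        Optional exact integrator ``(a, t_start, t_end) -> a_new`` of
        the single-cell drift ``da/dt = s_i(a) − d_o(a)``; presets
        supply it where a closed form exists (agent-based simulation
        uses it to avoid substepping).
    """

    division_rate: float = 0.0
    division_mode: DivisionMode = DivisionMode.NON_CONSERVED_SYMMETRIC
    division_kernel: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    division_time_factor: Callable[[float], float] = _one_t
    differentiation_rate: Callable[[np.ndarray], np.ndarray] = _zero
    synthesis_flux: Callable[[np.ndarray], np.ndarray] = _zero
    degradation_flux: Callable[[np.ndarray], np.ndarray] = _zero
    drift_exact: Optional[Callable[[np.ndarray, float, float], np.ndarray]] = None
    label: str = ""

    def validate(self, a_probe: Optional[np.ndarray] = None,
                 t_probe: Optional[np.ndarray] = None) -> None:
        """Check non-negativity/finiteness of all rates on probe grids."""
        if self.division_rate < 0 or not math.isfinite(self.division_rate):
            raise ValueError("division_rate must be finite and non-negative")
        if a_probe is None:
            a_probe = np.linspace(0.0, 100.0, 11)
        if t_probe is None:
            t_probe = np.array([1e-3, 1.0, 7.0, 28.0])
        for name in ("differentiation_rate", "synthesis_flux", "degradation_flux"):
            vals = np.asarray(getattr(self, name)(a_probe), dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"{name} must be finite and non-negative for a >= 0")
        g = np.array([self.division_time_factor(t) for t in t_probe], dtype=float)
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValueError("division_time_factor must be finite and non-negative "
                             "for t > 0")
        if self.division_mode is DivisionMode.CONSERVED and self.division_kernel is None:
            raise ValueError("conserved mode requires a division_kernel")

    def drift_velocity(self, a: np.ndarray) -> np.ndarray:
        """Net activity drift ``v(a) = s_i(a) − d_o(a)`` (units/day)."""
        a = np.asarray(a, dtype=float)
        return np.asarray(self.synthesis_flux(a), dtype=float) - \
            np.asarray(self.degradation_flux(a), dtype=float)


# ---------------------------------------------------------------------------
# Parameter containers for the two closed-form models
# ---------------------------------------------------------------------------

_REL_TOL = 1e-9


@dataclass(frozen=True)
class PSCDParams:
    """Parameters of the progressive stem-cell differentiation model.

    The closed-form moments are ``N(t) = N̄0·t²`` and
    ``Φ(t) = Φ̄0·t²·e^{−d0·t}``.  The amplitude pair (N̄0, Φ̄0) is the
    primary parameterization; the equivalent initial-time form
    (N0, Φ0 at t0) satisfies ``N̄0 = N0/t0²`` and
    ``Φ̄0 = Φ0·e^{d0·t0}/t0²``.

    Units: N̄0 in cells/day², Φ̄0 in activity-units/day², d0 per day.
    """

    N_bar0: float
    Phi_bar0: float
    d0: float
    N0: Optional[float] = None
    Phi0: Optional[float] = None
    t0: Optional[float] = None

    def __post_init__(self):
        for name in ("N_bar0", "Phi_bar0", "d0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.N0 is not None and self.t0 is not None:
            if not math.isclose(self.N_bar0, self.N0 / self.t0**2,
                                rel_tol=_REL_TOL, abs_tol=0.0):
                raise ValueError("inconsistent (N_bar0, N0, t0)")
        if self.Phi0 is not None and self.t0 is not None:
            expect = self.Phi0 * math.exp(self.d0 * self.t0) / self.t0**2
            if not math.isclose(self.Phi_bar0, expect, rel_tol=_REL_TOL, abs_tol=0.0):
                raise ValueError("inconsistent (Phi_bar0, Phi0, d0, t0)")


@dataclass(frozen=True)
class ISCDParams:
    """Parameters of the instantaneous stem-cell differentiation model.

    Both moments grow quadratically: ``N(t) = N̄0·t²``,
    ``Φ(t) = Φ̄0·t²``.  ``k_bar`` is the net growth rate
    ``k_d − k_f`` and is only needed for the general-rate (non-2/t)
    form of the model.
    """

    N_bar0: float
    Phi_bar0: float
    k_bar: Optional[float] = None

    def __post_init__(self):
        for name in ("N_bar0", "Phi_bar0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


class ConvertDirection(str, Enum):
    TO_INITIAL = "to_initial"
    TO_AMPLITUDE = "to_amplitude"


#: First measurement day of the assay design; default reference time for
#: converting fitted amplitudes into initial-time parameters.
DEFAULT_T0 = 7.0


def convert_params(params: PSCDParams,
                   direction: str | ConvertDirection,
                   t0: Optional[float] = None) -> PSCDParams:
    """Fill in the missing parameterization of :class:`PSCDParams`.

    ``to_initial`` computes (N0, Phi0) at reference time ``t0`` from the
    amplitudes; ``to_amplitude`` computes the amplitudes from
    (N0, Phi0, t0).  The two directions are mutually inverse for any
    ``t0 > 0``.
    """
    direction = ConvertDirection(direction)
    if direction is ConvertDirection.TO_INITIAL:
        t0 = float(t0 if t0 is not None else (params.t0 or DEFAULT_T0))
        if t0 <= 0:
            raise ValueError("t0 must be positive")
        return replace(params,
                       N0=params.N_bar0 * t0**2,
                       Phi0=params.Phi_bar0 * t0**2 * math.exp(-params.d0 * t0),
                       t0=t0)
    # to_amplitude: recompute amplitudes from the initial-time fields
    if params.N0 is None or params.Phi0 is None or params.t0 is None:
        raise ValueError("to_amplitude requires N0, Phi0 and t0")
    t0 = params.t0
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    return PSCDParams(N_bar0=params.N0 / t0**2,
                      Phi_bar0=params.Phi0 * math.exp(params.d0 * t0) / t0**2,
                      d0=params.d0, N0=params.N0, Phi0=params.Phi0, t0=t0)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _two_over_t(t):
    if t <= 0:
        raise ValueError("division factor 2/t requires t > 0")
    return 2.0 / t


def pscd_model(d0: float) -> ModelSpec:
    """Progressive stem-cell differentiation model.

    Symmetric non-conserved division at effective rate ``2/t``; no
    explicit differentiation removal (``k_f ≡ 0``); no biosynthesis;
    activity-proportional ALP degradation ``d_o(a) = d0·a``, so every
    cell's activity decays exponentially at rate ``d0`` and
    differentiation is the gradual fade-out of ALP expression.
    """
    if d0 < 0 or not math.isfinite(d0):
        raise ValueError("d0 must be finite and non-negative")

    def d_o(a):
        return d0 * np.asarray(a, dtype=float)

    def drift(a, t_start, t_end):
        return np.asarray(a, dtype=float) * math.exp(-d0 * (t_end - t_start))

    return ModelSpec(
        division_rate=1.0,
        division_mode=DivisionMode.NON_CONSERVED_SYMMETRIC,
        division_time_factor=_two_over_t,
        degradation_flux=d_o,
        drift_exact=drift,
        label=f"pscd(d0={d0:g})",
    )


def iscd_model(k_f: float) -> ModelSpec:
    """Instantaneous stem-cell differentiation model.

    Symmetric non-conserved division at effective rate ``2/t``; cells
    leave the ALP-positive pool in one step at constant rate ``k_f``;
    activity fluxes are zero, so each surviving cell keeps its activity.
    """
    if k_f < 0 or not math.isfinite(k_f):
        raise ValueError("k_f must be finite and non-negative")

    def rate(a):
        return np.full_like(np.asarray(a, dtype=float), k_f)

    def drift(a, t_start, t_end):
        return np.asarray(a, dtype=float)

    return ModelSpec(
        division_rate=1.0,
        division_mode=DivisionMode.NON_CONSERVED_SYMMETRIC,
        division_time_factor=_two_over_t,
        differentiation_rate=rate,
        drift_exact=drift,
        label=f"iscd(k_f={k_f:g})",
    )


def conserved_model(kernel_amplitude: float) -> ModelSpec:
    """Activity-conserving division with a constant daughter-pair kernel.

    ``k_d(a, a') = c`` splits a parent of activity ``a + a'`` into the
    pair ``(a, a')``; the total first moment Φ is invariant under these
    divisions.  Mainly used to exercise the conserved branch of the
    solver and the agent simulator.
    """
    if kernel_amplitude < 0 or not math.isfinite(kernel_amplitude):
        raise ValueError("kernel amplitude must be finite and non-negative")
    c = float(kernel_amplitude)

    def kernel(a, ap):
        a = np.asarray(a, dtype=float)
        return np.full(np.broadcast(a, np.asarray(ap, dtype=float)).shape, c)

    return ModelSpec(
        division_rate=c,
        division_mode=DivisionMode.CONSERVED,
        division_kernel=kernel,
        label=f"conserved(c={c:g})",
    )


def model_from_config(config: Mapping) -> ModelSpec:
    """Build a preset model from a plain mapping (e.g. parsed YAML/JSON).

    Schema: ``{"model": "pscd"|"iscd"|"conserved", "d0"/"k_f"/"kernel_amplitude": x}``.
    Custom kernels cannot be expressed in config files; construct a
    :class:`ModelSpec` programmatically instead.
    """
    name = str(config.get("model", "")).lower()
    if name == "pscd":
        return pscd_model(float(config["d0"]))
    if name == "iscd":
        return iscd_model(float(config["k_f"]))
    if name == "conserved":
        return conserved_model(float(config["kernel_amplitude"]))
    raise ValueError(f"unknown model preset {name!r}; "
                     "use 'pscd', 'iscd' or 'conserved'")
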