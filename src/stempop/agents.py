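"""Event-driven stochastic simulation of single-cell ALP dynamics.

Each cell ``j`` carries an ALP activity ``a_j(t)``.  Between events the
activity drifts deterministically, ``da/dt = s_i(a) − d_o(a)``; at
random times a cell divides (copying or splitting its activity,
depending on the division mode) or leaves the stem-cell pool through
terminal differentiation at rate ``k_f(a)``.

This simulator is the microscopic counterpart of the mean-field
population balance: ensemble means of the cell count N and the summed
activity Φ converge to the deterministic moment solutions, which makes
it an independent oracle for the closed forms and the PDE solver.

Time-dependent division rates (e.g. the ``2/t`` slowdown) are handled
by Ogata thinning: candidate event times are drawn against a majorant
evaluated at the current time, which is valid because the supported
time factors are non-increasing; a violation of the majorant aborts the
run rather than silently biasing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .balance_solver import MomentSeries
from .model_core import DivisionMode, ModelSpec

__all__ = [
    "CellEnsemble",
    "EnsembleMoments",
    "gamma_ensemble",
    "simulate_agents",
    "simulate_replicates",
    "ensemble_moments",
]

_DRIFT_SUBSTEP = 0.01  # days, for models without an exact drift map


@dataclass
class CellEnsemble:
    """Per-cell ALP activities of a (possibly extinct) population."""

    activities: np.ndarray
    time: float = 0.0
    rng_seed: Optional[int] = None
    #: number of drift clamps at a=0 accumulated during simulation
    n_clamped: int = 0

    def __post_init__(self):
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 1:
            raise ValueError("activities must be a 1-D array")
        if self.activities.size and (
                not np.all(np.isfinite(self.activities))
                or np.any(self.activities < 0)):
            raise ValueError("activities must be finite and non-negative")

    @property
    def size(self) -> int:
        return int(self.activities.size)

    def moments(self) -> Tuple[float, float]:
        return float(self.activities.size), float(self.activities.sum())


def gamma_ensemble(n_cells: int, mean_activity: float, seed: int,
                   shape: float = 2.0, time: float = 0.0) -> CellEnsemble:
    """Ensemble of ``n_cells`` with gamma-distributed activities."""
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(seed)
    acts = rng.gamma(shape, mean_activity / shape, size=n_cells)
    return CellEnsemble(activities=acts, time=time, rng_seed=seed)


def _drift(model: ModelSpec, a: np.ndarray, t0: float, t1: float) -> Tuple[np.ndarray, int]:
    """Advance all activities from t0 to t1; returns (new a, #clamped)."""
    if t1 <= t0 or a.size == 0:
        return a, 0
    if model.drift_exact is not None:
        out = model.drift_exact(a, t0, t1)
    else:
        out = a.astype(float).copy()
        n_sub = max(1, math.ceil((t1 - t0) / _DRIFT_SUBSTEP))
        h = (t1 - t0) / n_sub
        for _ in range(n_sub):  # midpoint method
            half = out + 0.5 * h * model.drift_velocity(out)
            out = out + h * model.drift_velocity(np.clip(half, 0.0, None))
    clamped = int(np.sum(out < 0))
    return np.clip(out, 0.0, None), clamped


def simulate_agents(
    model: ModelSpec,
    initial: CellEnsemble,
    t_end: float,
    seed: int,
    record_times: Optional[Sequence[float]] = None,
) -> Tuple[CellEnsemble, MomentSeries]:
    """Exact stochastic simulation of one population trajectory.

    The same ``seed`` reproduces the trajectory bit-for-bit.  Division
    events use the scalar amplitude ``division_rate`` times the time
    factor as the per-cell rate; the mode controls whether daughters
    copy the parent activity (non-conserved symmetric) or share it via
    a uniform split (conserved).
    """
    t0 = float(initial.time)
    if t_end <= t0:
        raise ValueError("t_end must exceed initial.time")
    if record_times is None:
        record_times = np.linspace(t0, t_end, 8)
    rec = np.asarray(record_times, dtype=float)
    if rec.size == 0 or rec[0] < t0 - 1e-12 or np.any(np.diff(rec) <= 0) \
            or rec[-1] > t_end + 1e-12:
        raise ValueError("record_times must be increasing within [t0, t_end]")

    rng = np.random.default_rng(seed)
    a = initial.activities.astype(float).copy()
    k = float(model.division_rate)
    conserved = model.division_mode is DivisionMode.CONSERVED
    g = model.division_time_factor

    t = t0
    clamped = 0
    rec_N: List[float] = []
    rec_Phi: List[float] = []
    i_rec = 0
    # record any times coinciding with t0
    while i_rec < rec.size and rec[i_rec] <= t + 1e-12:
        rec_N.append(a.size)
        rec_Phi.append(float(a.sum()))
        i_rec += 1

    while i_rec < rec.size:
        target = rec[i_rec]
        if a.size == 0:
            t = target
        else:
            kf_vals = np.asarray(model.differentiation_rate(a), dtype=float)
            per_cell_bound = g(t) * k + float(kf_vals.max(initial=0.0))
            if not math.isfinite(per_cell_bound) or per_cell_bound < 0:
                raise ValueError("unbounded or invalid event-rate majorant")
            if per_cell_bound == 0.0:
                a, c = _drift(model, a, t, target)
                clamped += c
                t = target
            else:
                tau = rng.exponential(1.0 / (per_cell_bound * a.size))
                if t + tau >= target:
                    a, c = _drift(model, a, t, target)
                    clamped += c
                    t = target
                else:
                    a, c = _drift(model, a, t, t + tau)
                    clamped += c
                    t = t + tau
                    j = int(rng.integers(a.size))
                    div_rate = g(t) * k
                    diff_rate = float(np.asarray(
                        model.differentiation_rate(a[j:j + 1]), dtype=float)[0])
                    total = div_rate + diff_rate
                    if total > per_cell_bound * (1.0 + 1e-9):
                        raise ValueError(
                            "event-rate majorant violated: rates must be "
                            "non-increasing in time/along the drift")
                    u = rng.uniform(0.0, per_cell_bound)
                    if u < div_rate:
                        if conserved:
                            split = rng.uniform(0.0, a[j])
                            other = a[j] - split
                            a[j] = split
                            a = np.append(a, other)
                        else:
                            a = np.append(a, a[j])
                    elif u < total:
                        a = np.delete(a, j)
                    # else: thinned, no event
                    continue
        # reached the record time
        rec_N.append(a.size)
        rec_Phi.append(float(a.sum()))
        i_rec += 1

    final = CellEnsemble(activities=a, time=rec[-1], rng_seed=seed,
                         n_clamped=clamped)
    series = MomentSeries(times=rec, N=np.array(rec_N), Phi=np.array(rec_Phi))
    return final, series


def simulate_replicates(
    model: ModelSpec,
    initial_factory: Callable[[int], CellEnsemble],
    t_end: float,
    n_replicates: int,
    seed: int,
    record_times: Optional[Sequence[float]] = None,
) -> List[MomentSeries]:
    """Run ``n_replicates`` independent trajectories.

    Replicate ``r`` uses seed ``seed + r`` both for its initial
    ensemble (via ``initial_factory(seed + r)``) and its event stream.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for r in range(n_replicates):
        init = initial_factory(seed + r)
        _, series = simulate_agents(model, init, t_end, seed=seed + r,
                                    record_times=record_times)
        out.append(series)
    return out


@dataclass
class EnsembleMoments:
    """Pointwise mean and standard error of replicate moment series."""

    times: np.ndarray
    N_mean: np.ndarray
    N_se: np.ndarray
    Phi_mean: np.ndarray
    Phi_se: np.ndarray
    n_replicates: int


def ensemble_moments(replicates: Sequence[MomentSeries]) -> EnsembleMoments:
    """Mean and standard error (sample SD / sqrt(R)) across replicates."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    times = replicates[0].times
    for s in replicates[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("replicates must share a common time grid")
    R = len(replicates)
    N = np.stack([s.N for s in replicates])
    Phi = np.stack([s.Phi for s in replicates])
    return EnsembleMoments(
        times=times,
        N_mean=N.mean(axis=0), N_se=N.std(axis=0, ddof=1) / math.sqrt(R),
        Phi_mean=Phi.mean(axis=0), Phi_se=Phi.std(axis=0, ddof=1) / math.sqrt(R),
        n_replicates=R,
    )
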