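"""Synthetic assay time-course generator and CSV I/O.

Emulates the statistical design of the stimulation-chamber experiments:
measurements on days 7, 14, 21 and 28, four samples per condition, with
total cell counts following quadratic growth and total ALP activity
rising to an interior peak (around day 12 for the default parameters)
before decaying.  Replicate observations are Gaussian around the
closed-form moment curves with coefficient-of-variation–scaled spread,
truncated at zero.

The default CVs (10% for counts, 5% for ALP) are a package choice made
to resemble the relative error bars typical of LDH/ALP assays; the
replicate-level variance structure of the original measurements is not
published, so these are free parameters of the generator.
"""

from __future__ import annotations

import math
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .analytic import iscd_moments, pscd_total_alp, pscd_total_cells
from .fitting import AssayDataset
from .model_core import DEFAULT_T0, ISCDParams, PSCDParams

__all__ = [
    "DEFAULT_DAYS",
    "generate_assay_dataset",
    "generate_reference_pair",
    "reference_params",
    "read_assay_csv",
    "write_assay_csv",
]

#: assay schedule: measurement days of the stimulation experiments
DEFAULT_DAYS = (7.0, 14.0, 21.0, 28.0)
DEFAULT_N_SAMPLES = 4
DEFAULT_CV_COUNT = 0.10
DEFAULT_CV_ALP = 0.05

_SUMMARY_COLS = ["condition", "day", "cell_count_mean", "cell_count_sd",
                 "alp_mean", "alp_sd", "n"]
_LONG_COLS = ["condition", "day", "replicate", "cell_count", "alp_activity"]


def _truth_curves(truth: Union[PSCDParams, ISCDParams], days: np.ndarray):
    if isinstance(truth, PSCDParams):
        return pscd_total_cells(days, truth), pscd_total_alp(days, truth)
    if isinstance(truth, ISCDParams):
        return iscd_moments(days, truth)
    raise TypeError("truth must be PSCDParams or ISCDParams")


def generate_assay_dataset(
    truth: Union[PSCDParams, ISCDParams],
    days: Sequence[float] = DEFAULT_DAYS,
    n_samples: int = DEFAULT_N_SAMPLES,
    cv_count: float = DEFAULT_CV_COUNT,
    cv_alp: float = DEFAULT_CV_ALP,
    seed: int = 0,
    condition: str = "synthetic",
) -> AssayDataset:
    """Draw one synthetic assay time course from a known truth model.

    Per day ``d``, ``n_samples`` replicate observations are drawn as
    ``Normal(N(d), cv_count·N(d))`` and ``Normal(Φ(d), cv_alp·Φ(d))``,
    truncated at 0; the dataset stores their per-day mean and sample
    SD.  Deterministic given ``seed``.  ``cv = 0`` reproduces the
    closed-form curves exactly with zero SD.
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("days must be non-empty")
    if np.any(days <= 0) or np.any(np.diff(days) <= 0):
        raise ValueError("days must be positive and strictly increasing")
    if cv_count < 0 or cv_alp < 0:
        raise ValueError("CVs must be non-negative")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    N_true, Phi_true = _truth_curves(truth, days)
    rng = np.random.default_rng(seed)
    counts = np.clip(rng.normal(N_true, cv_count * N_true,
                                size=(n_samples, days.size)), 0.0, None)
    alps = np.clip(rng.normal(Phi_true, cv_alp * Phi_true,
                              size=(n_samples, days.size)), 0.0, None)
    ddof = 1 if n_samples > 1 else 0
    return AssayDataset(
        condition=condition,
        days=days,
        cell_count_mean=counts.mean(axis=0),
        cell_count_sd=counts.std(axis=0, ddof=ddof),
        alp_mean=alps.mean(axis=0),
        alp_sd=alps.std(axis=0, ddof=ddof),
        n_replicates=n_samples,
    )


def reference_params(t0: float = DEFAULT_T0) -> Tuple[PSCDParams, PSCDParams]:
    """Reference (control, stimulated) truth parameters.

    Quadratic-growth amplitude N̄0 = 535 cells/day² for both
    conditions (counts are field-independent); initial-time ALP
    activities Φ0 = 0.8007 (control) and 0.84 (stimulated) at reference
    day ``t0``, with ALP decay times 1/d0 = 5.84 and 6.2 days.
    """
    ctrl = PSCDParams(N_bar0=535.0,
                      Phi_bar0=0.8007 * math.exp((1.0 / 5.84) * t0) / t0**2,
                      d0=1.0 / 5.84,
                      N0=535.0 * t0**2, Phi0=0.8007, t0=t0)
    stim = PSCDParams(N_bar0=535.0,
                      Phi_bar0=0.84 * math.exp((1.0 / 6.2) * t0) / t0**2,
                      d0=1.0 / 6.2,
                      N0=535.0 * t0**2, Phi0=0.84, t0=t0)
    return ctrl, stim


def generate_reference_pair(
    seed: int = 0,
    cv_count: float = DEFAULT_CV_COUNT,
    cv_alp: float = DEFAULT_CV_ALP,
    t0: float = DEFAULT_T0,
) -> Tuple[AssayDataset, AssayDataset]:
    """Convenience (control, stimulated) synthetic pair.

    Uses :func:`reference_params`; qualitative picture: cell counts
    statistically indistinguishable between conditions, stimulated ALP
    higher with a later peak (≈12.4 vs ≈11.7 days)."""
    ctrl_p, stim_p = reference_params(t0=t0)
    ctrl = generate_assay_dataset(ctrl_p, seed=seed, cv_count=cv_count,
                                  cv_alp=cv_alp, condition="control")
    stim = generate_assay_dataset(stim_p, seed=seed + 1_000_003,
                                  cv_count=cv_count, cv_alp=cv_alp,
                                  condition="stimulated")
    return ctrl, stim


def write_assay_csv(data: AssayDataset, path) -> None:
    """Write a dataset in the summary-form CSV schema.

    Columns: condition, day, cell_count_mean, cell_count_sd, alp_mean,
    alp_sd, n.  SD columns are left empty when unavailable.
    """
    df = pd.DataFrame({
        "condition": data.condition,
        "day": data.days,
        "cell_count_mean": data.cell_count_mean,
        "cell_count_sd": data.cell_count_sd if data.cell_count_sd is not None
        else np.nan,
        "alp_mean": data.alp_mean,
        "alp_sd": data.alp_sd if data.alp_sd is not None else np.nan,
        "n": data.n_replicates,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_assay_csv(path) -> AssayDataset:
    """Read a summary- or long-form assay CSV into an :class:`AssayDataset`.

    Long-form files (condition, day, replicate, cell_count,
    alp_activity) are aggregated to per-day means and SDs.  Missing SD
    columns are accepted (the dataset then carries ``None`` and
    weighted fits refuse it).  Malformed files raise ``ValueError``
    naming the offending rows (1-based data rows, excluding the
    header).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"replicate", "cell_count", "alp_activity"} <= cols:
        return _read_long(df)
    required = {"condition", "day", "cell_count_mean", "alp_mean"}
    missing = required - cols
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    conds = df["condition"].unique()
    if len(conds) != 1:
        raise ValueError("file must contain exactly one condition; "
                         f"found {list(conds)}")
    days = df["day"].to_numpy(dtype=float)
    bad = [i + 1 for i in range(1, len(days)) if days[i] <= days[i - 1]]
    if bad:
        raise ValueError(f"days not strictly increasing at rows {bad}")
    for sd_col in ("cell_count_sd", "alp_sd"):
        if sd_col in cols:
            sd = df[sd_col].to_numpy(dtype=float)
            bad = [i + 1 for i, v in enumerate(sd) if np.isfinite(v) and v < 0]
            if bad:
                raise ValueError(f"negative {sd_col} at rows {bad}")

    def _opt(col):
        if col not in cols:
            return None
        v = df[col].to_numpy(dtype=float)
        return None if np.all(np.isnan(v)) else v

    n = int(df["n"].iloc[0]) if "n" in cols else 1
    return AssayDataset(
        condition=str(conds[0]),
        days=days,
        cell_count_mean=df["cell_count_mean"].to_numpy(dtype=float),
        cell_count_sd=_opt("cell_count_sd"),
        alp_mean=df["alp_mean"].to_numpy(dtype=float),
        alp_sd=_opt("alp_sd"),
        n_replicates=n,
    )


def _read_long(df: pd.DataFrame) -> AssayDataset:
    required = set(_LONG_COLS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    conds = df["condition"].unique()
    if len(conds) != 1:
        raise ValueError("file must contain exactly one condition; "
                         f"found {list(conds)}")
    neg = [i + 1 for i, v in enumerate(df["cell_count"]) if v < 0]
    neg += [i + 1 for i, v in enumerate(df["alp_activity"]) if v < 0]
    if neg:
        raise ValueError(f"negative measurements at rows {sorted(set(neg))}")
    g = df.groupby("day", sort=True)
    days = np.array(sorted(df["day"].unique()), dtype=float)
    n_rep = int(g.size().iloc[0])
    ddof = 1 if n_rep > 1 else 0
    return AssayDataset(
        condition=str(conds[0]),
        days=days,
        cell_count_mean=g["cell_count"].mean().to_numpy(),
        cell_count_sd=g["cell_count"].std(ddof=ddof).fillna(0.0).to_numpy(),
        alp_mean=g["alp_activity"].mean().to_numpy(),
        alp_sd=g["alp_activity"].std(ddof=ddof).fillna(0.0).to_numpy(),
        n_replicates=n_rep,
    )
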