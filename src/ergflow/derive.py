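"""Putative OER and IOP_M derived from simultaneous measurements.

When vitreal pO2, blood flow and ERG amplitude are recorded together on the
same eyes, the model's two internal components can be recovered directly
from data, without any curve fitting:

* treating tissue pO2 as a surrogate for oxygen consumption (extracted
  oxygen fully utilised), the putative oxygen extraction ratio is the ratio
  of relative pO2 to relative blood flow;
* the putative mechanical-stress term is relative ERG minus relative pO2,
  i.e. whatever attenuation of function the oxygen supply cannot explain.

Both derivations require all series normalised to the IOP = 10 mmHg
baseline step, so the baseline record maps to (OER, IOP_M) = (1, 0) by
construction.  Near-zero flow makes the OER ratio explode; points at or
below a configurable flow floor are flagged and carried as NaN rather than
silently dropped.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import GofResult, chi_square_gof
from .model import ModelParams, iopm_from_iop, oer_from_flow

__all__ = [
    "FLOW_FLOOR_PCT",
    "normalize_to_baseline",
    "derive_oer",
    "derive_iopm",
    "derive_table",
    "compare_derived_to_model",
]

#: Flow floor (% of baseline) below which the pO2/flow ratio is undefined.
FLOW_FLOOR_PCT = 2.0


def normalize_to_baseline(series) -> np.ndarray:
    """Express a raw series as % of its first (baseline) value.

    The series must be ordered by protocol step with the IOP = 10 mmHg
    baseline first; the baseline maps to exactly 100.
    """
    raw = np.asarray(series, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot normalize an empty series")
    baseline = raw.flat[0]
    if not baseline > 0:
        raise ValueError(f"baseline value must be > 0, got {baseline}")
    return raw * (100.0 / baseline)


def derive_oer(po2, flow, flow_floor: float = FLOW_FLOOR_PCT) -> np.ndarray:
    """Putative OER (fold): relative pO2 over relative flow.

    Both inputs in % of baseline, so the ratio is a fold change equal to 1
    at baseline.  Points with ``flow <= flow_floor`` are returned as NaN
    (undefined — the ratio diverges as flow vanishes).
    """
    po2, flow = np.broadcast_arrays(
        np.asarray(po2, dtype=float), np.asarray(flow, dtype=float)
    )
    valid = flow > flow_floor
    out = np.full(flow.shape, np.nan)
    out[valid] = po2[valid] / flow[valid]
    return out


def derive_iopm(erg, po2) -> np.ndarray:
    """Putative IOP_M (% baseline ERG): relative ERG minus relative pO2.

    Expected <= 0 above the mechanical threshold; small positive values
    produced by measurement noise are reported as-is, never clipped.
    """
    erg = np.asarray(erg, dtype=float)
    po2 = np.asarray(po2, dtype=float)
    return erg - po2


def derive_table(data, flow_floor: float = FLOW_FLOOR_PCT) -> pd.DataFrame:
    """Per-record derived quantities with flags, as a tidy table.

    ``data`` needs columns ``iop_mmHg``, ``flow_pct``, ``erg_pct`` and
    ``po2_pct`` (already normalised).  Adds ``oer_putative`` (NaN where the
    flow floor is hit), ``iopm_putative`` and ``oer_flag``
    ("ok" / "flow_below_floor").
    """
    df = pd.DataFrame(data).copy()
    for col in ("iop_mmHg", "flow_pct", "erg_pct", "po2_pct"):
        if col not in df.columns:
            raise KeyError(f"missing required column: {col}")
    flow = df["flow_pct"].to_numpy(float)
    df["oer_putative"] = derive_oer(df["po2_pct"].to_numpy(float), flow, flow_floor)
    df["iopm_putative"] = derive_iopm(
        df["erg_pct"].to_numpy(float), df["po2_pct"].to_numpy(float)
    )
    df["oer_flag"] = np.where(flow > flow_floor, "ok", "flow_below_floor")
    return df


def summarize_derived(table) -> pd.DataFrame:
    """Aggregate per-animal derived values to per-step means with SEMs.

    Input is a :func:`derive_table` output for several animals sharing the
    same protocol (``step`` column required).  Flagged OER points (NaN) are
    ignored in the OER statistics; a step keeps flag "ok" only if at least
    two unflagged animals contribute.  SEM = SD/sqrt(n), NaN when n < 2.
    """
    df = pd.DataFrame(table)
    for col in ("step", "iop_mmHg", "flow_pct", "oer_putative", "iopm_putative"):
        if col not in df.columns:
            raise KeyError(f"missing required column: {col}")
    grp = df.groupby("step", sort=True)

    def _sem(series: pd.Series) -> float:
        x = series.dropna()
        if len(x) < 2:
            return np.nan
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    out = pd.DataFrame(
        {
            "iop_mmHg": grp["iop_mmHg"].first(),
            "flow_pct": grp["flow_pct"].mean(),
            "oer_putative": grp["oer_putative"].mean(),
            "oer_sem": grp["oer_putative"].agg(_sem),
            "n_oer": grp["oer_putative"].count(),
            "iopm_putative": grp["iopm_putative"].mean(),
            "iopm_sem": grp["iopm_putative"].agg(_sem),
            "n_iopm": grp["iopm_putative"].count(),
        }
    ).reset_index()
    out["oer_flag"] = np.where(out["n_oer"] >= 2, "ok", "flow_below_floor")
    return out


def compare_derived_to_model(
    derived: pd.DataFrame,
    params: ModelParams,
    oer_sem: Optional[Sequence[float]] = None,
    iopm_sem: Optional[Sequence[float]] = None,
) -> tuple[GofResult, GofResult]:
    """Grade the agreement of derived OER and IOP_M with the model curves.

    The model parameters are held fixed (prediction mode, df = n): the
    derived OER points are compared with the exponential OER–flow curve and
    the derived IOP_M points with the two-line hinge.  Flagged OER points
    are excluded from the OER comparison.  SEMs default to the ``oer_sem``
    and ``iopm_sem`` columns when present (as written by
    :func:`summarize_derived`); otherwise unit SEMs are used, which reduces
    Q to a pure discrepancy scale.
    """
    df = pd.DataFrame(derived)
    if oer_sem is None and "oer_sem" in df.columns:
        oer_sem = df["oer_sem"].to_numpy(float)
    if iopm_sem is None and "iopm_sem" in df.columns:
        iopm_sem = df["iopm_sem"].to_numpy(float)
    ok = df["oer_flag"] == "ok" if "oer_flag" in df.columns else np.isfinite(
        df["oer_putative"].to_numpy(float)
    )
    oer_obs = df.loc[ok, "oer_putative"].to_numpy(float)
    oer_pred = np.asarray(oer_from_flow(df.loc[ok, "flow_pct"].to_numpy(float), params))
    if oer_sem is None:
        oer_sem_arr = np.ones_like(oer_obs)
    else:
        oer_sem_arr = np.asarray(oer_sem, dtype=float)[np.asarray(ok)]
    gof_oer = chi_square_gof(oer_obs, oer_pred, oer_sem_arr, n_free_params=0)

    iopm_obs = df["iopm_putative"].to_numpy(float)
    iopm_pred = np.asarray(iopm_from_iop(df["iop_mmHg"].to_numpy(float), params))
    iopm_sem_arr = (
        np.ones_like(iopm_obs) if iopm_sem is None else np.asarray(iopm_sem, dtype=float)
    )
    gof_iopm = chi_square_gof(iopm_obs, iopm_pred, iopm_sem_arr, n_free_params=0)
    return gof_oer, gof_iopm
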