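"""Connectivity calls and synaptic-conductance estimation from evoked currents.

The synaptic current obeys I = g (Vm - E_reversal), so a straight-line fit of
peak evoked current against holding potential yields the conductance g
(slope, pA/mV = nS) and the reversal potential (zero-current voltage).  Cells
whose own I-V relationship is degenerate fall back to the mean reversal
potential of the other cells: g is then the average of I(V)/(V - E_shared)
over that cell's holding potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from escapekit.core_io import IVRecording

LAYER_ORDER = {"superficial": 0, "intermediate": 1, "deep": 2}


@dataclass
class ConductanceFit:
    """Conductance estimate for one cell."""

    cell_id: str
    g_ns: float
    e_reversal_mv: float
    fit_method: str  # full_iv | shared_reversal
    residual_rms_pa: float = np.nan
    flags: tuple[str, ...] = ()


class DegenerateIVError(ValueError):
    """I-V data cannot identify both g and E_reversal; use the fallback."""


@dataclass
class ConnectivityTrials:
    """Per-trial evoked response summary used for the connectivity call."""

    peak_amplitudes_pa: np.ndarray  # baseline-subtracted |peak| per trial
    onset_latencies_ms: np.ndarray  # NaN where no response was detected
    baseline_sd_pa: float


def call_connected(
    trials: ConnectivityTrials,
    *,
    k_sd: float = 3.0,
    min_consistency: float = 0.8,
    max_latency_sd_ms: float = 2.0,
    max_mean_latency_ms: float = 15.0,
) -> bool:
    """Connected iff the cell responds consistently with short, reliable
    latency: evoked peak > ``k_sd`` baseline SDs in >= 80% of trials, latency
    SD < 2 ms and mean latency < 15 ms (defaults configurable)."""
    amps = np.asarray(trials.peak_amplitudes_pa, dtype=float)
    if len(amps) < 5:
        raise ValueError("need at least five stimulation trials")
    responded = amps > k_sd * trials.baseline_sd_pa
    if np.mean(responded) < min_consistency:
        return False
    lat = np.asarray(trials.onset_latencies_ms, dtype=float)[responded]
    lat = lat[np.isfinite(lat)]
    if len(lat) == 0:
        return False
    if np.std(lat) >= max_latency_sd_ms:
        return False
    return bool(np.mean(lat) < max_mean_latency_ms)


def fit_conductance(iv: IVRecording, min_slope_ns: float = 1e-9) -> ConductanceFit:
    """Least-squares line through the I-V points: g = slope, E_rev = zero
    crossing.  Degenerate data (fewer than two distinct potentials, or a flat
    line whose reversal is unidentifiable) raises :class:`DegenerateIVError`
    directing to the shared-reversal fallback."""
    v = iv.holding_potentials_mv
    i = iv.peak_currents_pa
    if len(np.unique(v)) < 2:
        raise DegenerateIVError("need >= 2 distinct holding potentials; use fallback")
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < min_slope_ns:
        raise DegenerateIVError("zero slope: reversal potential unidentifiable; use fallback")
    resid = i - (slope * v + intercept)
    return ConductanceFit(
        cell_id=iv.cell_id,
        g_ns=float(slope),
        e_reversal_mv=float(-intercept / slope),
        fit_method="full_iv",
        residual_rms_pa=float(np.sqrt(np.mean(resid**2))),
    )


def fallback_conductance(
    iv: IVRecording, shared_e_reversal_mv: float, min_driving_force_mv: float = 1e-6
) -> ConductanceFit:
    """Conductance from a shared reversal potential: the average over holding
    potentials of I(V) / (V - E_shared).  Potentials at the reversal are
    skipped (zero driving force), flagged."""
    v = iv.holding_potentials_mv
    i = iv.peak_currents_pa
    driving = v - shared_e_reversal_mv
    usable = np.abs(driving) > min_driving_force_mv
    flags: list[str] = []
    if not usable.all():
        flags.append("potentials_at_shared_reversal_skipped")
    if not usable.any():
        raise DegenerateIVError("all holding potentials sit at the shared reversal")
    g = float(np.mean(i[usable] / driving[usable]))
    return ConductanceFit(
        cell_id=iv.cell_id,
        g_ns=g,
        e_reversal_mv=float(shared_e_reversal_mv),
        fit_method="shared_reversal",
        flags=tuple(flags),
    )


def fit_population(ivs: list[IVRecording]) -> list[ConductanceFit]:
    """Fit every cell, using the mean reversal of the successfully fitted
    cells for those whose own I-V is degenerate."""
    fits: dict[str, ConductanceFit] = {}
    pending: list[IVRecording] = []
    for iv in ivs:
        try:
            fits[iv.cell_id] = fit_conductance(iv)
        except DegenerateIVError:
            pending.append(iv)
    if pending:
        if not fits:
            raise DegenerateIVError("no cell has a fittable I-V curve")
        shared = float(np.mean([f.e_reversal_mv for f in fits.values()]))
        for iv in pending:
            fits[iv.cell_id] = fallback_conductance(iv, shared)
    return [fits[iv.cell_id] for iv in ivs]


def connection_probability(
    cells: pd.DataFrame, group_key: str = "mouse_id"
) -> pd.DataFrame:
    """Per-mouse fraction of tested cells that are connected.

    ``cells`` needs boolean column ``connected`` plus the group key.  Mice
    with zero tested cells are simply absent.
    """
    grp = cells.groupby(group_key)["connected"]
    out = grp.agg(["mean", "size"]).reset_index()
    return out.rename(columns={"mean": "connection_probability", "size": "n_cells"})


def conductance_by_mouse(fits: pd.DataFrame) -> pd.DataFrame:
    """Median conductance per mouse with IQR (the display convention for the
    conductance panel)."""
    def _iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    grp = fits.groupby("mouse_id")["g_ns"]
    out = grp.agg(median="median", iqr=_iqr, n="size").reset_index()
    return out


def layer_conductance_regression(cells: pd.DataFrame) -> dict:
    """OLS of conductance on the ordinal layer code (superficial=0,
    intermediate=1, deep=2)."""
    df = cells.dropna(subset=["layer", "g_ns"])
    codes = df["layer"].map(LAYER_ORDER)
    if codes.nunique() < 2:
        raise ValueError("need cells from at least two layers")
    X = sm.add_constant(codes.to_numpy(dtype=float))
    res = sm.OLS(df["g_ns"].to_numpy(dtype=float), X).fit()
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r_squared": float(res.rsquared),
        "p_value": float(res.pvalues[1]),
        "n_cells": int(len(df)),
    }
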