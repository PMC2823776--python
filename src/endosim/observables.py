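"""Census, normalisation and outcome classification of simulation runs.

Tracked channels follow the aggregate definitions of the model: ``lps_total``
counts LPS both bound and free; ``tnf_free`` counts only free TNF-α;
``P`` is the circulating IL-12 count (the pro-inflammatory mediator);
``A`` the IL-4/anti-inflammatory agent count; ``E`` the summed macrophage
energy; activated NF-κB/IKK/IκBα are summed over all macrophages.

A run is classified *resolved* when the three channels the unresolved
figures show elevated — P, free TNF-α and activated NF-κB — each return to
within a relative tolerance band of their pre-dose (t = 0) baseline and hold
it for a minimum window through the simulation horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: CSV / DataFrame column order
COLUMNS = ["tick", "hours", "lps_total", "tnf_free", "P", "A", "E",
           "nfkb_active", "ikk_active", "ikba_active", "th0", "th1", "th2"]

#: channels whose return to baseline defines resolution
RESOLUTION_CHANNELS = ("P", "tnf_free", "nfkb_active")


def record(world) -> tuple:
    """One census row, matching a direct count of the agent registry."""
    nfkb_states = world.nfkb["state"] if world.nfkb.n else np.empty(0)
    ikk_states = world.ikk["state"] if world.ikk.n else np.empty(0)
    th_kinds = world.th["kind"] if world.th.n else np.empty(0)
    tnf_free = (int(np.count_nonzero(world.tnf["bound"] == 0))
                if world.tnf.n else 0)
    tph = world.params.engine.ticks_per_hour
    return (
        world.tick,
        world.tick / tph,
        world.lps.n,                                   # bound + free
        tnf_free,                                      # free only
        world.il12.n,                                  # P
        world.il4.n,                                   # A
        float(sum(m.energy for m in world.macrophages)),  # E
        int(np.count_nonzero(nfkb_states >= 2)),       # active (cyt+nuclear)
        int(np.count_nonzero(ikk_states >= 1)),        # active incl. bound
        world.ikba.n,                                  # activated free IkBa
        int(np.count_nonzero(th_kinds == 0)),
        int(np.count_nonzero(th_kinds == 1)),
        int(np.count_nonzero(th_kinds == 2)),
    )


def to_timeseries(history: list[tuple], *, seed: int | None = None,
                  scenario: str | None = None,
                  ticks_per_hour: int | None = None,
                  params_hash: str | None = None) -> pd.DataFrame:
    """Assemble recorded rows into a tick-indexed DataFrame with metadata."""
    df = pd.DataFrame(history, columns=COLUMNS)
    df.attrs["seed"] = seed
    df.attrs["scenario"] = scenario
    df.attrs["ticks_per_hour"] = ticks_per_hour
    df.attrs["params_hash"] = params_hash
    return df


def normalize(series: pd.DataFrame) -> pd.DataFrame:
    """Scale every channel by its own run maximum into (0, 1).

    All-zero channels map to all zeros (documented edge rule); ``tick`` and
    ``hours`` are left untouched.
    """
    if series.empty:
        raise ValueError("cannot normalize an empty series")
    out = series.copy()
    for col in series.columns:
        if col in ("tick", "hours"):
            continue
        peak = series[col].max()
        if peak > 0:
            out[col] = series[col] / peak
    return out


def _tph(series: pd.DataFrame, ticks_per_hour: Optional[int]) -> float:
    if ticks_per_hour is not None:
        return float(ticks_per_hour)
    if series.attrs.get("ticks_per_hour"):
        return float(series.attrs["ticks_per_hour"])
    raise ValueError("ticks_per_hour not given and absent from metadata")


def clearance_time(series: pd.DataFrame,
                   ticks_per_hour: Optional[int] = None) -> Optional[float]:
    """Hours at which total LPS first reaches zero and stays there.

    Returns ``None`` when LPS persists at the horizon (no durable clearance).
    """
    tph = _tph(series, ticks_per_hour)
    lps = series["lps_total"].to_numpy()
    nonzero = np.flatnonzero(lps > 0)
    if nonzero.size == 0:
        return 0.0
    last = nonzero[-1]
    if last == len(lps) - 1:
        return None
    return float(series["tick"].iloc[last + 1]) / tph


@dataclass
class OutcomeReport:
    """Replicate-level verdict on a simulated inflammatory trajectory."""

    resolved: bool
    clearance_time_hours: Optional[float]
    resolution_time_hours: Optional[float]
    horizon_hours: float
    peaks: dict = field(default_factory=dict)
    seed: Optional[int] = None
    scenario: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "resolved": self.resolved,
            "clearance_time_hours": self.clearance_time_hours,
            "resolution_time_hours": self.resolution_time_hours,
            "horizon_hours": self.horizon_hours,
            "peaks": self.peaks,
            "seed": self.seed,
            "scenario": self.scenario,
        }


def classify(series: pd.DataFrame, tol: float = 0.05,
             hold_hours: float = 1.0,
             ticks_per_hour: Optional[int] = None) -> OutcomeReport:
    """Classify a run as resolved or unresolved.

    Each resolution channel must return to within ``tol`` x (its run peak)
    of its t = 0 baseline and remain there for at least ``hold_hours``
    through the horizon.  The resolution time is when the last channel
    enters the band for good; a trajectory that plateaus away from baseline
    (the bistable sustained-elevated attractor) never satisfies the hold.
    """
    if not 0.0 < tol < 1.0:
        raise ValueError("tol must lie in (0, 1)")
    if hold_hours <= 0:
        raise ValueError("hold_hours must be positive")
    tph = _tph(series, ticks_per_hour)
    horizon_tick = int(series["tick"].iloc[-1])

    res_tick = 0
    peaks: dict[str, float] = {}
    for col in series.columns:
        if col not in ("tick", "hours"):
            peaks[col] = float(series[col].max())
    for col in RESOLUTION_CHANNELS:
        x = series[col].to_numpy(dtype=float)
        band = tol * peaks[col]
        outside = np.flatnonzero(np.abs(x - x[0]) > band)
        if outside.size:
            res_tick = max(res_tick, int(series["tick"].iloc[outside[-1]]) + 1)

    held = horizon_tick - res_tick >= hold_hours * tph
    resolved = held and res_tick <= horizon_tick
    return OutcomeReport(
        resolved=bool(resolved),
        clearance_time_hours=clearance_time(series, tph),
        resolution_time_hours=res_tick / tph if resolved else None,
        horizon_hours=horizon_tick / tph,
        peaks=peaks,
        seed=series.attrs.get("seed"),
        scenario=series.attrs.get("scenario"),
    )
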