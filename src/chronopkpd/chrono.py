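"""Dosing-time scan and optimal-window derivation.

For each administration time Ta in [0, 24) the treated model is simulated to
its post-last-dose cycle and compared with the untreated baseline on the same
clock grid (hours after awakening):

* dipper percentage: 100 * (awake mean - sleep mean) / awake mean of the
  treated profile (10-20% is the dipper target band, <10% non-dipper);
* BP_reduced: mean pre-minus-post difference over the full cycle;
* BP_peaks: the same difference restricted to clock times where the
  untreated profile exceeds its own mean.

Optimal windows combine the therapeutic BP target (cycle maxima strictly
below 130/80 mmHg) with the dipper band on the circular Ta axis; when a
criterion is unattainable the fallback reports the Ta minimizing SBP_max /
DBP_max or the Ta of the extreme dipper percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import ClockConvention, steady_state_bp
from .pkpd import ModelSpec, SteadyStateWarning, steady_state_window


def dipper_pct(tau: np.ndarray, values: np.ndarray,
               clock: ClockConvention | None = None) -> float:
    """Nocturnal dip of a 24-h profile, percent of the awake mean."""
    clock = clock or ClockConvention()
    tau = np.asarray(tau, dtype=float)
    values = np.asarray(values, dtype=float)
    awake = clock.is_awake(tau)
    m_aw = float(np.mean(values[awake]))
    m_sl = float(np.mean(values[~awake]))
    if m_aw <= 0:
        raise ValueError("awake mean must be positive")
    return 100.0 * (m_aw - m_sl) / m_aw


def bp_reduced(before: np.ndarray, after: np.ndarray) -> float:
    """Mean pre-vs-post BP reduction over a matched grid (mmHg)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after grids must match")
    return float(np.mean(before - after))


def bp_peaks(before: np.ndarray, after: np.ndarray) -> float:
    """Mean reduction restricted to times where the untreated profile exceeds
    its own mean; NaN when that peak set is empty (flat profile)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after grids must match")
    peaks = before > np.mean(before)
    if not peaks.any():
        return float("nan")
    return float(np.mean(before[peaks] - after[peaks]))


@dataclass
class TaScanResult:
    """Per-Ta metrics over a dosing-time grid (all 24-periodic in Ta)."""

    df: pd.DataFrame
    grid_step: float
    clock: ClockConvention

    @property
    def ta(self) -> np.ndarray:
        return self.df["ta"].to_numpy(float)


def scan_ta(
    m: ModelSpec,
    grid_step: float = 0.25,
    clock: ClockConvention | None = None,
    ss_tol: float = 1e-3,
    max_doses: int = 14,
    out_step: float = 0.05,
    method: str = "rk4",
) -> TaScanResult:
    """Evaluate all chronotherapy metrics over a Ta grid covering [0, 24).

    Per-Ta simulation failures are recorded as NaN rows; the scan continues.
    """
    clock = clock or ClockConvention()
    ta_grid = np.arange(0.0, 24.0, grid_step)
    rows = []
    for ta in ta_grid:
        row = {"ta": float(ta)}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SteadyStateWarning)
                window = steady_state_window(m, float(ta), tol=ss_tol,
                                             max_doses=max_doses,
                                             out_step=out_step, method=method)
            t = window.t[:-1]            # drop duplicate cycle endpoint
            tau = (t + ta) % 24.0
            s_before, d_before = steady_state_bp(m.baseline, t, ta)
            for label, after, before in (
                ("sbp", window.states["SBP"][:-1], s_before),
                ("dbp", window.states["DBP"][:-1], d_before),
            ):
                row[f"{label}_dip"] = dipper_pct(tau, after, clock)
                row[f"{label}_reduced"] = bp_reduced(before, after)
                row[f"{label}_peaks"] = bp_peaks(before, after)
                row[f"{label}_min"] = float(np.min(after))
                row[f"{label}_max"] = float(np.max(after))
        except Exception:  # noqa: BLE001 - recorded as NA, scan continues
            for label in ("sbp", "dbp"):
                for suffix in ("dip", "reduced", "peaks", "min", "max"):
                    row[f"{label}_{suffix}"] = np.nan
        rows.append(row)
    return TaScanResult(df=pd.DataFrame(rows), grid_step=grid_step,
                        clock=clock)


# ---------------------------------------------------------------------------
# Circular intervals and optimal windows
# ---------------------------------------------------------------------------

def intervals_from_mask(ta: np.ndarray, mask: np.ndarray,
                        step: float) -> list[tuple[float, float]]:
    """Maximal runs of True on the circular Ta axis.

    Intervals are (start, end) in hours after awakening; ``end < start``
    denotes a window wrapping through 24 -> 0.  A fully-True mask yields
    [(0.0, 24.0)].
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        return [(0.0, 24.0)]
    if not mask.any():
        return []
    runs = []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segs = np.split(idx, breaks + 1)
    if len(segs) > 1 and mask[0] and mask[-1]:
        # merge the wrap-around pair
        segs[0] = np.concatenate([segs[-1], segs[0]])
        segs = segs[:-1]
    for seg in segs:
        runs.append((float(ta[seg[0]]), float(ta[seg[-1]])))
    return runs


def _in_interval(x: float, iv: tuple[float, float]) -> bool:
    a, b = iv
    x = x % 24.0
    if a <= b:
        return a <= x <= b
    return x >= a or x <= b


def format_ta(ta: float) -> str:
    """Decimal hours after awakening -> hh:mm string."""
    ta = ta % 24.0
    hh = int(ta)
    mm = int(round((ta - hh) * 60.0))
    if mm == 60:
        hh, mm = (hh + 1) % 24, 0
    return f"{hh:02d}:{mm:02d}"


def format_intervals(ivs: list[tuple[float, float]]) -> str:
    if ivs == [(0.0, 24.0)]:
        return "0-24"
    return " and ".join(f"{format_ta(a)}-{format_ta(b)}" for a, b in ivs)


@dataclass
class OptimalWindow:
    """Ta windows meeting the BP target and dipper band, with fallbacks."""

    ta_ranges_bp: list[tuple[float, float]]
    ta_ranges_dip: list[tuple[float, float]]
    ta_optimal: list[tuple[float, float]]
    fallback: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def report(self, clock: ClockConvention | None = None) -> dict:
        clock = clock or ClockConvention()

        def chron(ivs):
            return [
                f"{format_ta(clock.to_chronological(a))}-"
                f"{format_ta(clock.to_chronological(b))}"
                for a, b in ivs
            ]

        return {
            "ta_bp_target": format_intervals(self.ta_ranges_bp),
            "ta_dip_10_20": format_intervals(self.ta_ranges_dip),
            "ta_optimal": format_intervals(self.ta_optimal),
            "ta_optimal_clock": chron(self.ta_optimal),
            "fallback": {
                k: (format_ta(v) if isinstance(v, (int, float))
                    and k.startswith("ta_") else v)
                for k, v in self.fallback.items()
            },
            **self.summary,
        }


def optimal_ta(
    scan: TaScanResult,
    target_sbp: float = 130.0,
    target_dbp: float = 80.0,
    dip_lo: float = 10.0,
    dip_hi: float = 20.0,
    dip_pressure: str = "sbp",
) -> OptimalWindow:
    """Derive dosing windows from a completed Ta scan.

    BP target uses the cycle maxima with strict inequality (< 130/80 mmHg);
    the dipper band is inclusive.  Empty windows are valid outputs: the
    fallback then carries the Ta of the minimal SBP_max / DBP_max or of the
    extreme dipper percentage.
    """
    df = scan.df
    ta = df["ta"].to_numpy(float)
    sbp_max = df["sbp_max"].to_numpy(float)
    dbp_max = df["dbp_max"].to_numpy(float)
    dip = df[f"{dip_pressure}_dip"].to_numpy(float)
    valid = np.isfinite(sbp_max) & np.isfinite(dbp_max) & np.isfinite(dip)

    sbp_ok = valid & (sbp_max < target_sbp)
    dbp_ok = valid & (dbp_max < target_dbp)
    bp_ok = sbp_ok & dbp_ok
    dip_ok = valid & (dip >= dip_lo) & (dip <= dip_hi)

    step = scan.grid_step
    ranges_bp = intervals_from_mask(ta, bp_ok, step)
    ranges_dip = intervals_from_mask(ta, dip_ok, step)
    ranges_opt = intervals_from_mask(ta, bp_ok & dip_ok, step)

    fallback: dict = {}
    if not sbp_ok.any():
        fallback["ta_min_sbp_max"] = float(ta[np.nanargmin(sbp_max)])
    if not dbp_ok.any():
        fallback["ta_min_dbp_max"] = float(ta[np.nanargmin(dbp_max)])
    if not bp_ok.any():
        if sbp_ok.any():
            fallback["sbp_ok_ranges"] = format_intervals(
                intervals_from_mask(ta, sbp_ok, step))
        if dbp_ok.any():
            fallback["dbp_ok_ranges"] = format_intervals(
                intervals_from_mask(ta, dbp_ok, step))
    if not dip_ok.any():
        if np.nanmax(dip) < dip_lo:
            fallback["ta_max_dip"] = float(ta[np.nanargmax(dip)])
            fallback["max_dip_pct"] = float(np.nanmax(dip))
        elif np.nanmin(dip) > dip_hi:
            fallback["ta_min_dip"] = float(ta[np.nanargmin(dip)])
            fallback["min_dip_pct"] = float(np.nanmin(dip))
        else:
            nearest = np.nanargmin(np.minimum(np.abs(dip - dip_lo),
                                              np.abs(dip - dip_hi)))
            fallback["ta_nearest_dip"] = float(ta[nearest])

    summary = {
        "sbp_min_range": (float(np.nanmin(df["sbp_min"])),
                          float(np.nanmax(df["sbp_min"]))),
        "sbp_max_range": (float(np.nanmin(sbp_max)), float(np.nanmax(sbp_max))),
        "dbp_min_range": (float(np.nanmin(df["dbp_min"])),
                          float(np.nanmax(df["dbp_min"]))),
        "dbp_max_range": (float(np.nanmin(dbp_max)), float(np.nanmax(dbp_max))),
        "dip_range": (float(np.nanmin(dip)), float(np.nanmax(dip))),
    }
    return OptimalWindow(ta_ranges_bp=ranges_bp, ta_ranges_dip=ranges_dip,
                         ta_optimal=ranges_opt, fallback=fallback,
                         summary=summary)
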