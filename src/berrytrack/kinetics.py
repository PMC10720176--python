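"""Single-berry ripening kinetics from tracked observations.

Per-berry volume series are smoothed with an 8-day moving median,
filtered on tracking coverage (>= 90% of the experiment duration) and
on smoothing residual (the 10% of berries with the highest raw-vs-
smoothed MAPE are excluded).  Each retained variable X (volume V or
centred hue H) is normalized to

    X_r = (X - X_0) / X_0          (relative)
    X_s = (X - X_0) / (X_max - X_0)  (scaled to [0, 1])

with X_0 the median over the first 8 days, and X_max the maximum of
the smoothed values over the last 8 days for V (median for H).  The
ripening descriptors are read off the scaled curves:

    RD = dt / (0.85 - 0.15),  dt = t(V_s = 0.85) - t(V_s = 0.15)
    RS = dV_r / dt            over the same interval

plus the growth-resumption time t(V_s = 0.15) and coloration start
time t(H_s = 0.15).  The same pipeline applied to the daily cross-berry
average produces the "mean berry", whose RD overestimates individual
durations whenever ripening is asynchronous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SMOOTH_WINDOW_DAYS",
    "MIN_COVERAGE",
    "MAPE_DROP",
    "LEVEL_LOW",
    "LEVEL_HIGH",
    "BerrySeries",
    "RipeningStats",
    "moving_median",
    "select_berries",
    "normalize",
    "crossing_time",
    "ripening_duration",
    "ripening_speed",
    "berry_stats",
    "mean_berry",
]

logger = logging.getLogger(__name__)

SMOOTH_WINDOW_DAYS = 8.0
MIN_COVERAGE = 0.90
MAPE_DROP = 0.10
LEVEL_LOW = 0.15
LEVEL_HIGH = 0.85
BASELINE_DAYS = 8.0   # span of the X_0 / X_max baselines


class KineticsError(RuntimeError):
    """Undefined kinetics quantity (missing crossing, degenerate range)."""


@dataclass
class BerrySeries:
    """One berry's time series of volume and centred hue."""

    label: int | str
    times: np.ndarray           # days, strictly increasing
    V: np.ndarray               # raw volumes
    H: np.ndarray | None = None # raw centred hues
    coverage: float = 1.0       # fraction of experiment frames observed
    V_smooth: np.ndarray = field(default=None)  # type: ignore[assignment]
    mape_fit: float = float("nan")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.H is not None:
            self.H = np.asarray(self.H, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.V_smooth is None:
            self.V_smooth = moving_median(self.times, self.V)
        if math.isnan(self.mape_fit):
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(self.V - self.V_smooth) / self.V_smooth
            self.mape_fit = float(np.nanmean(rel) * 100.0)


@dataclass
class RipeningStats:
    """Per-berry ripening descriptors (times in days)."""

    label: int | str
    V_0: float
    V_max: float
    H_0: float | None = None
    H_max: float | None = None
    RD: float | None = None
    RS: float | None = None
    t_resume: float | None = None
    t_color: float | None = None
    max_rel_expansion: float | None = None
    degenerate: bool = False


def moving_median(times, values, window_days: float = SMOOTH_WINDOW_DAYS) -> np.ndarray:
    """Centred moving median on the time axis; the window is truncated
    at the series ends."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    half = window_days / 2.0
    out = np.empty_like(v)
    for i, ti in enumerate(t):
        sel = (t >= ti - half) & (t <= ti + half)
        out[i] = np.median(v[sel])
    return out


def series_from_tracks(tracks: pd.DataFrame, n_frames: int | None = None) -> list[BerrySeries]:
    """Build per-label series from a track table (label -1 ignored)."""
    if n_frames is None:
        n_frames = tracks["frame"].nunique()
    out = []
    for label, grp in tracks[tracks["label"] >= 0].groupby("label"):
        grp = grp.sort_values("time_days")
        out.append(BerrySeries(
            label=int(label),
            times=grp["time_days"].to_numpy(),
            V=grp["V_px3"].to_numpy(),
            H=grp["H"].to_numpy() if grp["H"].notna().all() else None,
            coverage=len(grp) / n_frames,
        ))
    return out


def select_berries(series: list[BerrySeries], min_coverage: float = MIN_COVERAGE,
                   mape_drop: float = MAPE_DROP) -> list[BerrySeries]:
    """Demonstration-dataset filter: coverage >= 90% of the experiment,
    then exclude the 10% of berries with the highest raw-vs-smoothed
    MAPE (a quantile rule: the count dropped is floor(0.1 n), applied
    even when all berries are clean)."""
    covered = [s for s in series if s.coverage >= min_coverage]
    n_drop = int(len(covered) * mape_drop)
    if n_drop == 0:
        return covered
    order = sorted(covered, key=lambda s: s.mape_fit)
    return order[:len(covered) - n_drop]


def _baseline_windows(times: np.ndarray, span: float = BASELINE_DAYS):
    first = times <= times[0] + span
    last = times >= times[-1] - span
    return first, last


def normalize(s: BerrySeries, variable: str = "V"):
    """Baselines and normalized curves for one variable.

    Returns ``(X_0, X_max, X_r, X_s)``; raises :class:`KineticsError`
    when the dynamic range X_max - X_0 vanishes (degenerate berry).
    For V the scaled/relative curves are computed on the smoothed
    series; H is used raw (colour averages many pixels and is much
    less noisy than area).
    """
    if variable == "V":
        raw = s.V
        smooth = s.V_smooth
        x_curve = smooth
    elif variable == "H":
        if s.H is None:
            raise KineticsError("no hue data")
        raw = s.H
        smooth = moving_median(s.times, s.H)
        x_curve = raw
    else:
        raise ValueError(f"unknown variable {variable!r}")
    if s.times[-1] - s.times[0] <= 2 * BASELINE_DAYS:
        raise KineticsError("series must span more than 16 days")
    first, last = _baseline_windows(s.times)
    X0 = float(np.median(raw[first]))
    X_max = float(np.max(smooth[last])) if variable == "V" else float(np.median(raw[last]))
    if X0 == 0 or np.isclose(X_max, X0):
        raise KineticsError("degenerate scaling (no dynamic range)")
    X_r = (x_curve - X0) / X0
    X_s = (x_curve - X0) / (X_max - X0)
    return X0, X_max, X_r, X_s


def crossing_time(times, scaled, level: float) -> float:
    """First upward crossing of ``level``, linearly interpolated.

    A series starting at or above the level crosses at its first sample
    time; a series that never crosses raises :class:`KineticsError`.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(scaled, dtype=float)
    if x[0] >= level:
        return float(t[0])
    above = np.flatnonzero((x[1:] >= level) & (x[:-1] < level))
    if above.size == 0:
        raise KineticsError(f"series never crosses level {level}")
    i = int(above[0])
    frac = (level - x[i]) / (x[i + 1] - x[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def ripening_duration(times, scaled) -> float:
    """RD = dt / 0.7 with dt the 0.15 -> 0.85 rise interval."""
    t15 = crossing_time(times, scaled, LEVEL_LOW)
    t85 = crossing_time(times, scaled, LEVEL_HIGH)
    return (t85 - t15) / (LEVEL_HIGH - LEVEL_LOW)


def ripening_speed(times, relative, scaled) -> float:
    """RS = dV_r / dt over the 0.15 -> 0.85 interval of the scaled curve."""
    t15 = crossing_time(times, scaled, LEVEL_LOW)
    t85 = crossing_time(times, scaled, LEVEL_HIGH)
    if t85 <= t15:
        raise KineticsError("empty rise interval")
    v15 = float(np.interp(t15, times, relative))
    v85 = float(np.interp(t85, times, relative))
    return (v85 - v15) / (t85 - t15)


def berry_stats(s: BerrySeries) -> RipeningStats:
    """All ripening descriptors for one berry (degenerate-safe)."""
    stats = RipeningStats(label=s.label, V_0=float("nan"), V_max=float("nan"))
    try:
        V0, Vmax, V_r, V_s = normalize(s, "V")
    except KineticsError as exc:
        logger.info("berry %s: %s", s.label, exc)
        stats.degenerate = True
        return stats
    stats.V_0, stats.V_max = V0, Vmax
    stats.max_rel_expansion = (Vmax - V0) / V0
    try:
        stats.t_resume = crossing_time(s.times, V_s, LEVEL_LOW)
        stats.RD = ripening_duration(s.times, V_s)
        stats.RS = ripening_speed(s.times, V_r, V_s)
    except KineticsError as exc:
        logger.info("berry %s: %s", s.label, exc)
    if s.H is not None:
        try:
            H0, Hmax, _, H_s = normalize(s, "H")
            stats.H_0, stats.H_max = H0, Hmax
            stats.t_color = crossing_time(s.times, H_s, LEVEL_LOW)
        except KineticsError as exc:
            logger.info("berry %s (hue): %s", s.label, exc)
    return stats


def mean_berry(series: list[BerrySeries]) -> tuple[BerrySeries, RipeningStats]:
    """Daily cross-berry average series and its descriptors.

    Times are binned by calendar day (floor of time-in-days); each
    day's volume/hue is the mean over all berry observations of that
    day.  Days without data are skipped.
    """
    if len(series) < 2:
        raise ValueError("mean berry needs at least 2 berries")
    rows = []
    for s in series:
        for i, t in enumerate(s.times):
            rows.append((math.floor(t), s.V[i],
                         s.H[i] if s.H is not None else np.nan))
    df = pd.DataFrame(rows, columns=["day", "V", "H"])
    daily = df.groupby("day").mean().sort_index()
    have_hue = all(s.H is not None for s in series)
    mb = BerrySeries(
        label="mean",
        times=daily.index.to_numpy(dtype=float),
        V=daily["V"].to_numpy(),
        H=daily["H"].to_numpy() if have_hue else None,
    )
    return mb, berry_stats(mb)


def stats_frame(series: list[BerrySeries], include_mean: bool = True) -> pd.DataFrame:
    """Per-berry summary table (one row per berry, plus the mean berry)."""
    stats = [berry_stats(s) for s in series]
    if include_mean and len(series) >= 2:
        stats.append(mean_berry(series)[1])
    return pd.DataFrame([{
        "label": st.label, "V_0": st.V_0, "V_max": st.V_max,
        "RD": st.RD, "RS": st.RS, "t_resume": st.t_resume,
        "t_color": st.t_color, "max_rel_expansion": st.max_rel_expansion,
        "degenerate": st.degenerate,
    } for st in stats])
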