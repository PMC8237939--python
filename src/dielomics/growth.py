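"""Diurnal specific growth rate from turbidostat logs.

In a turbidostat the dilution rate D = feed / volume balances growth, so the
specific growth rate follows from the biomass mass balance

    mu(t) = (dOD/dt + D(t) * OD(t)) / OD(t)

with OD the optical density (a cell-mass proxy). Raw 30-second sensor logs
are noisy, so the estimator applies a cascade of robust moving filters
before and after differentiation:

1. dilution rate: 40% truncated moving average, 480-point window, two passes;
2. OD: 40% truncated average over 960 points, then a plain average over 360;
3. dOD/dt: ordinary least-squares slope in 1 h centered windows;
4. mu: 40% truncated average over 720 points, negatives clamped to zero.

Window sizes are in points; at the nominal 30 s sampling interval 480 points
span 4 h. The 40% truncation removes the 20% most extreme values from each
tail of the window. Windows shrink symmetrically at the series edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TurbidostatTrace",
    "GrowthFilterConfig",
    "GrowthRateModel",
    "GrowthRateResults",
    "truncated_mean_filter",
    "rolling_slope",
]


@dataclass
class TurbidostatTrace:
    """Turbidostat log: time (h), optical density, feed rate, volume.

    ``od`` is OD_730; logs recorded at another wavelength should be
    converted with a scalar factor before construction. Volume is constant
    (litres); feed rate is L/h.
    """

    time: np.ndarray
    od: np.ndarray
    feed_rate: np.ndarray
    volume: float = 1.6

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.od = np.asarray(self.od, float)
        self.feed_rate = np.asarray(self.feed_rate, float)
        if not (len(self.time) == len(self.od) == len(self.feed_rate)):
            raise ValueError("time, od and feed_rate must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("optical density must be > 0 everywhere")
        if np.any(self.feed_rate < 0):
            raise ValueError("feed rate must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    @property
    def dilution_rate(self) -> np.ndarray:
        """D(t) = feed rate / culture volume (h^-1)."""
        return self.feed_rate / self.volume

    @property
    def dt_hours(self) -> float:
        return float(np.median(np.diff(self.time)))

    @classmethod
    def from_csv(cls, path, volume: float | None = None) -> "TurbidostatTrace":
        """Read a CSV with columns time_s, od, feed_rate_lph [, volume_l]."""
        table = pd.read_csv(path)
        required = {"time_s", "od", "feed_rate_lph"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"turbidostat CSV missing columns: {sorted(missing)}")
        if volume is None:
            volume = (
                float(table["volume_l"].iloc[0]) if "volume_l" in table.columns else 1.6
            )
        return cls(
            time=table["time_s"].to_numpy() / 3600.0,
            od=table["od"].to_numpy(),
            feed_rate=table["feed_rate_lph"].to_numpy(),
            volume=volume,
        )


def truncated_mean_filter(
    series: np.ndarray,
    window_points: int,
    trim_fraction: float = 0.4,
    passes: int = 1,
) -> np.ndarray:
    """Centered moving trimmed mean.

    Each point is replaced by the mean of its window after dropping the
    ``trim_fraction/2`` most extreme values from each tail (so 0.4 drops 40%
    of the window in total). At the edges the window shrinks to the points
    available. ``passes`` repeats the whole filter.
    """
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    if window_points < 1:
        raise ValueError("window_points must be >= 1")
    if not (0 <= trim_fraction < 1):
        raise ValueError("trim_fraction must be in [0, 1)")
    half = window_points // 2
    for _ in range(passes):
        x = _trimmed_pass(x, half, trim_fraction)
    return x


def _trimmed_window_mean(values: np.ndarray, trim_fraction: float) -> float:
    n = len(values)
    g = int(n * trim_fraction / 2.0)
    if 2 * g >= n:
        g = (n - 1) // 2
    srt = np.sort(values)
    return float(srt[g : n - g].mean())


def _trimmed_pass(x: np.ndarray, half: int, trim_fraction: float) -> np.ndarray:
    n = len(x)
    out = np.empty_like(x)
    window = 2 * half + 1
    if n >= window:
        # interior: vectorized sort over sliding windows
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        g = int(window * trim_fraction / 2.0)
        srt = np.sort(sw, axis=1)
        core = srt[:, g : window - g] if window - 2 * g > 0 else srt[:, [window // 2]]
        out[half : n - half] = core.mean(axis=1)
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = _trimmed_window_mean(x[lo:hi], trim_fraction)
    return out


def rolling_slope(time: np.ndarray, values: np.ndarray, window_points: int) -> np.ndarray:
    """Least-squares slope of ``values`` vs ``time`` in centered windows.

    Edge windows shrink; a window degenerates to fewer than 2 points never
    occurs for window_points >= 2.
    """
    t = np.asarray(time, float)
    x = np.asarray(values, float)
    n = len(t)
    half = window_points // 2
    out = np.empty(n)
    window = 2 * half + 1
    if n >= window:
        tw = np.lib.stride_tricks.sliding_window_view(t, window)
        xw = np.lib.stride_tricks.sliding_window_view(x, window)
        tc = tw - tw.mean(axis=1, keepdims=True)
        xc = xw - xw.mean(axis=1, keepdims=True)
        out[half : n - half] = (tc * xc).sum(axis=1) / (tc * tc).sum(axis=1)
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        tc = t[lo:hi] - t[lo:hi].mean()
        xc = x[lo:hi] - x[lo:hi].mean()
        denom = (tc * tc).sum()
        out[i] = (tc * xc).sum() / denom if denom > 0 else 0.0
    return out


@dataclass
class GrowthFilterConfig:
    """Filter-cascade windows (in points at the trace's sampling interval)."""

    dilution_window: int = 480
    dilution_passes: int = 2
    od_trimmed_window: int = 960
    od_plain_window: int = 360
    slope_window_hours: float = 1.0
    mu_window: int = 720
    trim_fraction: float = 0.4


@dataclass
class GrowthRateResults:
    """Estimated specific growth rate series with daily summaries."""

    time: np.ndarray
    mu: np.ndarray
    od_smooth: np.ndarray
    dilution_smooth: np.ndarray
    daily_mean: float
    daily_max: float
    span: tuple[float, float]

    def summary(self) -> str:
        return "\n".join(
            [
                "Turbidostat growth-rate estimate",
                "================================",
                f"span                {self.span[0]:.2f}-{self.span[1]:.2f} h",
                f"daily mean mu       {self.daily_mean:8.4f} 1/h",
                f"daily max mu        {self.daily_max:8.4f} 1/h",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time, "mu_per_h": self.mu})


class GrowthRateModel:
    """Mass-balance growth-rate estimator for a turbidostat trace.

    ``fit()`` runs the filter cascade and returns :class:`GrowthRateResults`
    with mu clamped at zero (dark-period dilution can push the raw estimate
    slightly negative; biologically mu >= 0).
    """

    def __init__(
        self,
        trace: TurbidostatTrace,
        config: GrowthFilterConfig | None = None,
        summary_span: tuple[float, float] | None = None,
    ):
        self.trace = trace
        self.config = config or GrowthFilterConfig()
        self.summary_span = summary_span

    def fit(self) -> GrowthRateResults:
        trace, cfg = self.trace, self.config
        dilution = truncated_mean_filter(
            trace.dilution_rate,
            cfg.dilution_window,
            cfg.trim_fraction,
            passes=cfg.dilution_passes,
        )
        od = truncated_mean_filter(
            trace.od, cfg.od_trimmed_window, cfg.trim_fraction
        )
        od = truncated_mean_filter(od, cfg.od_plain_window, trim_fraction=0.0)
        slope_points = max(2, int(round(cfg.slope_window_hours / trace.dt_hours)))
        dod_dt = rolling_slope(trace.time, od, slope_points)
        mu = (dod_dt + dilution * od) / od
        mu = truncated_mean_filter(mu, cfg.mu_window, cfg.trim_fraction)
        mu = np.clip(mu, 0.0, None)

        span = self.summary_span or (float(trace.time[0]), float(trace.time[-1]))
        mask = (trace.time >= span[0]) & (trace.time <= span[1])
        return GrowthRateResults(
            time=trace.time,
            mu=mu,
            od_smooth=od,
            dilution_smooth=dilution,
            daily_mean=float(mu[mask].mean()),
            daily_max=float(mu[mask].max()),
            span=span,
        )
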