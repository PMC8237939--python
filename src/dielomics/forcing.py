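"""Periodic forcing functions for the protein mass-balance model.

Three kinds of time-dependent drivers appear in the diurnal turnover model:

* a *synthesis* forcing — the fraction of bulk protein synthesis devoted to a
  gene, oscillating around a mean of 1 with a prescribed peak-to-trough fold
  change;
* a *rate* forcing — a degradation (or growth) rate expressed directly as a
  sinusoid in h^-1;
* a *day-night* forcing — a sinusoid during the light half of the cycle and
  exactly zero during the dark half, the shape of the measured specific
  growth rate in a 12 h : 12 h light regime.

All forcings are evaluated vectorized over time (hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForcingSpec", "evaluate_forcing", "peak_trough_ratio"]

TWO_PI = 2.0 * np.pi


class ForcingConfigError(ValueError):
    """Raised for an invalid or unknown forcing configuration."""


@dataclass(frozen=True)
class ForcingSpec:
    """A periodic (or constant) scalar driver.

    Parameters
    ----------
    kind : {"constant", "sinusoid", "day_night_sinusoid"}
    mean_level : float
        Baseline level. Dimensionless for synthesis forcings (mean 1),
        h^-1 for rate forcings.
    amplitude_fold_change : float, optional
        For a synthesis sinusoid: the realized peak/trough ratio ``c`` over
        one period. The sine amplitude is then ``A = (c - 1) / (c + 1)``
        around a mean of 1, so that ``(1 + A) / (1 - A) == c``.
    sine_amplitude : float, optional
        For rate forcings: the sine amplitude in the same units as
        ``mean_level``. Mutually exclusive with ``amplitude_fold_change``.
    period : float
        Period in hours (> 0).
    phase : float
        Phase offset in radians.
    """

    kind: str = "constant"
    mean_level: float = 1.0
    amplitude_fold_change: float | None = None
    sine_amplitude: float | None = None
    period: float = 24.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid", "day_night_sinusoid"):
            raise ForcingConfigError(f"unknown forcing kind: {self.kind!r}")
        if self.period <= 0:
            raise ForcingConfigError("period must be > 0")
        if self.amplitude_fold_change is not None:
            if self.sine_amplitude is not None:
                raise ForcingConfigError(
                    "give either amplitude_fold_change or sine_amplitude, not both"
                )
            if self.amplitude_fold_change < 1:
                raise ForcingConfigError("amplitude_fold_change must be >= 1")

    # -- constructors -----------------------------------------------------

    @classmethod
    def constant(cls, level: float) -> "ForcingSpec":
        return cls(kind="constant", mean_level=level)

    @classmethod
    def synthesis_sinusoid(
        cls,
        fold_change: float = 3.05,
        period: float = 24.0,
        phase: float = 0.5 * np.pi,
    ) -> "ForcingSpec":
        """Synthesis-fraction sinusoid around mean 1.

        With the default fold change of 3.05 and phase pi/2 this is the
        median-amplitude forcing used for the average-gene scenarios:
        ``F_S(t) = (c-1)/(c+1) * sin(2*pi/period * t + phase) + 1``.
        """
        return cls(
            kind="sinusoid",
            mean_level=1.0,
            amplitude_fold_change=fold_change,
            period=period,
            phase=phase,
        )

    @classmethod
    def rate_sinusoid(
        cls,
        mean: float,
        amplitude: float,
        period: float = 24.0,
        phase: float = 0.0,
    ) -> "ForcingSpec":
        """A rate (h^-1) oscillating as ``mean + amplitude*sin(w t + phase)``."""
        return cls(
            kind="sinusoid",
            mean_level=mean,
            sine_amplitude=amplitude,
            period=period,
            phase=phase,
        )

    @classmethod
    def day_night(
        cls,
        amplitude: float = 0.05,
        period: float = 24.0,
        phase: float = 0.0,
    ) -> "ForcingSpec":
        """Sinusoid during the day half of the cycle, zero at night.

        Day is ``(t mod period) in [0, period/2)``, night the second half.
        With the defaults this is the measured diurnal growth-rate shape
        ``mu(t) = 0.05 * sin(2*pi/24 * t)`` during the day and 0 at night.
        """
        return cls(
            kind="day_night_sinusoid",
            mean_level=0.0,
            sine_amplitude=amplitude,
            period=period,
            phase=phase,
        )

    # -- evaluation --------------------------------------------------------

    @property
    def _sin_amp(self) -> float:
        if self.sine_amplitude is not None:
            return self.sine_amplitude
        if self.amplitude_fold_change is not None:
            c = self.amplitude_fold_change
            return self.mean_level * (c - 1.0) / (c + 1.0)
        return 0.0

    def __call__(self, t):
        return evaluate_forcing(self, t)

    def daily_mean(self, n: int = 4801) -> float:
        """Numerical average over one period (trapezoid on a dense grid)."""
        t = np.linspace(0.0, self.period, n)
        return float(np.trapezoid(self(t), t) / self.period)


def evaluate_forcing(spec: ForcingSpec, t):
    """Evaluate a forcing at time(s) ``t`` (hours).

    Returns a scalar for scalar input, else an ndarray of the same shape.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    omega = TWO_PI / spec.period
    if spec.kind == "constant":
        out = np.full_like(t, spec.mean_level)
    elif spec.kind == "sinusoid":
        out = spec.mean_level + spec._sin_amp * np.sin(omega * t + spec.phase)
    elif spec.kind == "day_night_sinusoid":
        # fold into one period first: keeps sin() exact at period boundaries
        tm = np.mod(t, spec.period)
        value = spec.mean_level + spec._sin_amp * np.sin(omega * tm + spec.phase)
        out = np.where(tm >= spec.period / 2.0, 0.0, value)
    else:  # pragma: no cover - guarded in __post_init__
        raise ForcingConfigError(f"unknown forcing kind: {spec.kind!r}")
    return out if out.ndim else float(out)


def peak_trough_ratio(spec: ForcingSpec, n: int = 4801) -> float:
    """Realized max/min ratio of the forcing over one full period.

    For a synthesis sinusoid built from fold change ``c`` this equals ``c``
    identically, since ``(1 + A) / (1 - A) = c`` with ``A = (c-1)/(c+1)``.
    """
    t = np.linspace(0.0, spec.period, n)
    values = evaluate_forcing(spec, t)
    lo = float(np.min(values))
    if lo <= 0:
        raise ValueError("peak/trough ratio undefined: forcing reaches <= 0")
    return float(np.max(values)) / lo
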