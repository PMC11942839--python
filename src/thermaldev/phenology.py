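"""Degree-day accumulation and emergence prediction.

Thermal time above the lower developmental threshold Tb is accumulated by the
rectangle method over daily mean temperatures:

    DD = sum_i max(T_i - Tb, 0) * dt,      dt = 1 day by default.

Days at or below Tb contribute nothing (no development occurs; increments are
never negative).  Emergence is predicted on the first day the running sum
reaches the degree-day requirement estimated from the linear rate model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable_io import TemperatureSeries

__all__ = ["DegreeDayTrace", "accumulate_degree_days", "predict_emergence"]


@dataclass(frozen=True)
class DegreeDayTrace:
    """Running degree-day sums over a daily temperature series."""

    series: TemperatureSeries
    t_b: float
    delta_t: float
    increments: tuple[float, ...]
    cumulative: tuple[float, ...]

    def emergence_day(self, dd_requirement: float) -> int | None:
        """First day_index whose cumulative sum reaches the requirement, or
        ``None`` if it is never reached within the series."""
        if not dd_requirement > 0:
            raise ValueError("degree-day requirement must be > 0")
        cum = np.asarray(self.cumulative)
        hit = np.nonzero(cum >= dd_requirement)[0]
        if hit.size == 0:
            return None
        return self.series.day_index[int(hit[0])]


def accumulate_degree_days(
    series: TemperatureSeries,
    t_b: float,
    delta_t: float = 1.0,
    t_l_cap: float | None = None,
) -> DegreeDayTrace:
    """Accumulate max(T_i - Tb, 0) * delta_t over a daily series.

    ``t_l_cap`` optionally enables a horizontal-cutoff variant in which daily
    temperatures are capped at an upper threshold before subtracting Tb; it is
    off by default (the plain formula subtracts only Tb).
    """
    if len(series) == 0:
        raise ValueError("temperature series is empty")
    if not delta_t > 0:
        raise ValueError("integration step must be > 0")
    t = np.asarray(series.t_mean, dtype=float)
    if t_l_cap is not None:
        t = np.minimum(t, t_l_cap)
    inc = np.maximum(t - t_b, 0.0) * delta_t
    return DegreeDayTrace(
        series=series,
        t_b=t_b,
        delta_t=delta_t,
        increments=tuple(inc),
        cumulative=tuple(np.cumsum(inc)),
    )


def predict_emergence(
    series: TemperatureSeries,
    t_b: float,
    dd_requirement: float,
    delta_t: float = 1.0,
    t_l_cap: float | None = None,
) -> int | None:
    """Day index on which accumulated degree-days first reach the
    requirement; ``None`` when the thermal sum is never reached."""
    trace = accumulate_degree_days(series, t_b, delta_t=delta_t, t_l_cap=t_l_cap)
    return trace.emergence_day(dd_requirement)
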