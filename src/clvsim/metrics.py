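"""Per-case performance endpoints for closed-loop blood-pressure control.

Band-time fractions (under / in / above the SAP target band), hypotension
burden (% case time MAP < 65 mmHg), pump activity, infusion-rate modification
frequency, dose summaries, and the Varvel controller-performance statistics
(MDPE, MDAPE, wobble, divergence) computed from per-sample performance error
``PE_i = 100·(SAP_i − target)/target``.

Conventions (documented, not universal):

* Time fractions are sample-weighted on the uniform recording grid; a sample
  exactly on a band edge counts as in-band (closed band), while the MAP
  criterion is a strict ``<``.
* Invalid samples are excluded from metric denominators, but the clock keeps
  running for duration-based quantities: dose totals integrate every sample's
  interval (duration = n·dt), and rate changes are normalized by the elapsed
  span between first and last sample.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core_io import CaseTimeSeries, ControllerConfig, TargetBand

__all__ = [
    "UndefinedMetricError",
    "PerformanceReport",
    "band_time_fractions",
    "pct_map_below",
    "pump_activity",
    "rate_change_count",
    "dose_summary",
    "performance_error",
    "varvel_metrics",
    "report_case",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (no valid samples / too few points)."""


@dataclass(frozen=True)
class PerformanceReport:
    """One case's endpoint set (units in field names' docstrings; % unless noted)."""

    case_id: str
    pct_under: float
    pct_in: float
    pct_over: float
    pct_map_lt65: float
    pct_pump_active: float
    rate_changes_per_min: float  # count/min
    total_dose: float  # µg
    mean_rate: float  # µg/min
    mdpe: float
    mdape: float
    wobble: float
    divergence: float  # %/h

    def as_dict(self) -> dict:
        return asdict(self)


def _valid_sap(series: CaseTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    if len(series) == 0:
        raise UndefinedMetricError("empty series")
    mask = series.valid
    if not mask.any():
        raise UndefinedMetricError("no valid samples")
    return series.sap[mask], series.t[mask]


def band_time_fractions(
    series: CaseTimeSeries, band: TargetBand
) -> tuple[float, float, float]:
    """(% under, % in, % over) the SAP band, over valid samples.

    Under iff SAP < lower, over iff SAP > upper, in otherwise; the three
    fractions sum to exactly 100 before any rounding.
    """
    sap, _ = _valid_sap(series)
    n = len(sap)
    under = np.count_nonzero(sap < band.lower)
    over = np.count_nonzero(sap > band.upper)
    return 100.0 * under / n, 100.0 * (n - under - over) / n, 100.0 * over / n


def pct_map_below(series: CaseTimeSeries, threshold: float = 65.0) -> float:
    """% of valid case time with MAP strictly below ``threshold`` mmHg."""
    if len(series) == 0:
        raise UndefinedMetricError("empty series")
    mask = series.valid
    if not mask.any():
        raise UndefinedMetricError("no valid samples")
    m = series.map[mask]
    return 100.0 * np.count_nonzero(m < threshold) / len(m)


def pump_activity(series: CaseTimeSeries) -> float:
    """% of samples with a non-zero commanded infusion rate."""
    if len(series) == 0:
        raise UndefinedMetricError("empty series")
    return 100.0 * np.count_nonzero(series.rate > 0) / len(series)


def rate_change_count(series: CaseTimeSeries, rate_epsilon: float = 0.05) -> float:
    """Infusion-rate modifications per minute, observed on the recording grid.

    A modification is a consecutive-sample pair whose rate differs by more
    than ``rate_epsilon`` µg/min; normalized by the elapsed span in minutes.
    Note the recording grid caps this at 60/dt_record per minute; the
    controller's own command-cycle counter (``SimResult.rate_changes_per_min``)
    sees every commanded change.
    """
    if len(series) < 2:
        raise UndefinedMetricError("need at least 2 samples")
    changes = np.count_nonzero(np.abs(np.diff(series.rate)) > rate_epsilon)
    return changes / (series.span_s / 60.0)


def dose_summary(series: CaseTimeSeries) -> tuple[float, float]:
    """(total dose µg, mean rate µg/min); each sample owns one dt interval."""
    if len(series) == 0:
        raise UndefinedMetricError("empty series")
    total = float(np.sum(series.rate) * series.dt_record / 60.0)
    return total, total / (series.duration_s / 60.0)


def performance_error(
    series: CaseTimeSeries, band: TargetBand
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample performance error PE (%) and its time stamps (valid samples)."""
    sap, t = _valid_sap(series)
    return 100.0 * (sap - band.target) / band.target, t


def varvel_metrics(
    pe: np.ndarray, t: np.ndarray, divergence_per: str = "h"
) -> tuple[float, float, float, float]:
    """Varvel controller-performance statistics from a PE sequence.

    MDPE = median(PE) (bias); MDAPE = median(|PE|) (inaccuracy);
    wobble = median(|PE − MDPE|) (intra-case variability);
    divergence = OLS slope of |PE| against time (%/h by default, or %/min
    with ``divergence_per='min'``) — drift of control quality over the case.
    """
    pe = np.asarray(pe, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(pe) < 2:
        raise UndefinedMetricError("divergence needs at least 2 points")
    if divergence_per not in ("h", "min"):
        raise ValueError("divergence_per must be 'h' or 'min'")
    mdpe = float(np.median(pe))
    mdape = float(np.median(np.abs(pe)))
    wobble = float(np.median(np.abs(pe - mdpe)))
    t_unit = t / (3600.0 if divergence_per == "h" else 60.0)
    slope = float(np.polyfit(t_unit, np.abs(pe), 1)[0])
    return mdpe, mdape, wobble, slope


def report_case(
    series: CaseTimeSeries,
    band: TargetBand | None = None,
    cfg: ControllerConfig | None = None,
    map_threshold: float = 65.0,
) -> PerformanceReport:
    """Assemble the full endpoint set for one case (no internal rounding)."""
    if band is None:
        band = cfg.band if cfg is not None else TargetBand()
    eps = cfg.rate_epsilon if cfg is not None else 0.05
    under, inb, over = band_time_fractions(series, band)
    total, mean_rate = dose_summary(series)
    pe, t = performance_error(series, band)
    mdpe, mdape, wobble, div = varvel_metrics(pe, t)
    return PerformanceReport(
        case_id=series.case_id,
        pct_under=under,
        pct_in=inb,
        pct_over=over,
        pct_map_lt65=pct_map_below(series, map_threshold),
        pct_pump_active=pump_activity(series),
        rate_changes_per_min=rate_change_count(series, eps),
        total_dose=total,
        mean_rate=mean_rate,
        mdpe=mdpe,
        mdape=mdape,
        wobble=wobble,
        divergence=div,
    )
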