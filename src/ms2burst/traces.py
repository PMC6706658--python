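"""Trace processing and burst calling for MS2 fluorescence time series.

Pipeline, in the order it runs on an ensemble of traces from one movie:

1. :func:`filter_tracked` — drop nuclei tracked for too few frames.
2. :func:`fit_baseline` — two-pass straight-line fit of the background:
   pass 1 fits the mean of *all* nuclei over time, classifies each nucleus
   active/inactive against that line, pass 2 refits using inactive nuclei
   only.  The inactive-nuclei decline doubles as the photobleaching
   estimate.
3. :func:`classify_active` — median-filter (window 3) each trace and mark
   frames ON where the filtered signal exceeds ``threshold_factor`` (1.2 by
   default) times the baseline; a nucleus is active iff some ON run lasts at
   least ``min_run`` (5) frames.
4. :func:`normalize_trace` — subtract the baseline and divide by the
   inactive-nuclei bleaching decay fraction.
5. :func:`call_bursts` / :func:`annotate_trace` — contiguous
   supra-threshold runs of at least ``min_run`` frames from
   ``analysis_start`` (15 min) onward are bursts; onset/end of transcription
   are the first burst's start and the last burst's end; "sustained" means
   at least one burst longer than 10 min.
6. :func:`summarize_bursting` — per-region distributions and summaries.

Thresholds are configuration, not constants: the defaults were chosen
empirically for MCP-GFP movies and real datasets may need different values.
Frames exactly at threshold count as OFF ("higher than" is strict).  A run
of untracked frames (NaN) breaks an ON run.

Note the resolution floor: with an elongation time ``T`` the nascent signal
cannot drop to zero faster than ``T`` after the promoter switches off, so
OFF gaps shorter than about 2 minutes are invisible to the burst caller.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import FluorescenceTrace

__all__ = [
    "BaselineModel",
    "Burst",
    "TraceAnnotation",
    "AllMissingTraceError",
    "DataQualityError",
    "median_filter3",
    "filter_tracked",
    "fit_baseline",
    "classify_active",
    "normalize_trace",
    "call_bursts",
    "annotate_trace",
    "annotate_ensemble",
    "burst_table",
    "summarize_bursting",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.2
DEFAULT_MIN_RUN = 5
DEFAULT_MIN_TRACKED = 10
DEFAULT_ANALYSIS_START = 900.0  # 15 min into nc14
DEFAULT_SUSTAINED_CUTOFF = 600.0  # bursts longer than 10 min


class AllMissingTraceError(ValueError):
    """Trace has no tracked frames at all."""


class DataQualityError(ValueError):
    """Baseline/bleaching estimate unusable (non-positive decay fraction)."""


@dataclass
class BaselineModel:
    """Straight-line background fit plus the bleaching decay it implies.

    ``baseline(t) = intercept + slope * t``; the decay fraction is the
    fitted inactive-nuclei line normalized to its value at t = 0, clamped
    to (0, 1].  When the fitted background at t = 0 is not positive there
    is no measurable background to estimate bleaching from and the decay
    is pinned at 1 (baseline subtraction only).
    """

    intercept: float
    slope: float
    n_inactive: int = 0
    fallback_pass1: bool = False

    def value(self, times: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(times, dtype=float)

    def decay_fraction(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.intercept <= 0:
            return np.ones_like(times)
        frac = self.value(times) / self.intercept
        if np.any(frac <= 0):
            raise DataQualityError(
                "bleaching decay fraction non-positive within the movie"
            )
        return np.minimum(frac, 1.0)


@dataclass
class Burst:
    """One contiguous ON period of a processed trace."""

    start_time: float
    end_time: float
    duration: float
    amplitude: float
    off_period_before: float | None = None

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("burst end must follow its start")


@dataclass
class TraceAnnotation:
    """Per-trace burst-calling result."""

    cell_id: str
    allele_id: str
    region_label: str
    active: bool
    bursts: list[Burst] = field(default_factory=list)
    onset_time: float | None = None
    end_time: float | None = None
    sustained: bool = False
    total_output: float = 0.0


def median_filter3(signal: np.ndarray) -> np.ndarray:
    """Median filter of window 3, NaN-aware.

    The median at each frame uses whichever of the three window values are
    tracked; an untracked frame stays untracked (gaps are preserved, never
    imputed).
    """
    x = np.asarray(signal, dtype=float)
    prev = np.concatenate([[np.nan], x[:-1]])
    nxt = np.concatenate([x[1:], [np.nan]])
    stacked = np.vstack([prev, x, nxt])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(stacked, axis=0)
    out[np.isnan(x)] = np.nan
    return out


def filter_tracked(
    traces: list[FluorescenceTrace], min_tracked: int = DEFAULT_MIN_TRACKED
) -> list[FluorescenceTrace]:
    """Keep only nuclei tracked for more than ``min_tracked`` frames."""
    return [t for t in traces if int(t.tracked.sum()) > min_tracked]


def _ensemble_mean(traces: list[FluorescenceTrace]) -> tuple[np.ndarray, np.ndarray]:
    times = traces[0].times
    stack = np.vstack([t.signal for t in traces])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return times, mean


def _linear_fit(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        raise DataQualityError("fewer than 2 frames with data for baseline fit")
    slope, intercept = np.polyfit(times[ok], values[ok], 1)
    return float(intercept), float(slope)


def fit_baseline(
    traces: list[FluorescenceTrace],
    threshold_factor: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
) -> BaselineModel:
    """Two-pass background fit.

    Pass 1 fits the per-frame mean of all nuclei to a straight line and
    classifies nuclei against it; pass 2 refits on the nuclei found
    inactive.  If pass 1 leaves no inactive nuclei the pass-1 fit is kept
    (with a logged warning) — there is then no independent background
    cohort.
    """
    if len(traces) < 2:
        raise DataQualityError("baseline fit needs at least 2 traces")
    times, mean_all = _ensemble_mean(traces)
    intercept1, slope1 = _linear_fit(times, mean_all)
    pass1 = BaselineModel(intercept1, slope1)

    inactive = []
    for trace in traces:
        try:
            active, _ = classify_active(
                trace, pass1, threshold_factor=threshold_factor, min_run=min_run
            )
        except AllMissingTraceError:
            continue
        if not active:
            inactive.append(trace)
    if not inactive:
        logger.warning(
            "no inactive nuclei in pass 2; keeping the all-nuclei baseline"
        )
        pass1.fallback_pass1 = True
        return pass1
    _, mean_inactive = _ensemble_mean(inactive)
    intercept2, slope2 = _linear_fit(times, mean_inactive)
    return BaselineModel(intercept2, slope2, n_inactive=len(inactive))


def _on_mask(
    trace: FluorescenceTrace,
    baseline: BaselineModel,
    threshold_factor: float,
) -> np.ndarray:
    filtered = median_filter3(trace.signal)
    base = baseline.value(trace.times)
    with np.errstate(invalid="ignore"):
        return filtered > threshold_factor * base


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start index, stop index exclusive)."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def classify_active(
    trace: FluorescenceTrace,
    baseline: BaselineModel,
    threshold_factor: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[bool, np.ndarray]:
    """Active flag plus the pointwise ON mask for one trace."""
    if not trace.tracked.any():
        raise AllMissingTraceError(f"trace {trace.cell_id}/{trace.allele_id} empty")
    mask = _on_mask(trace, baseline, threshold_factor)
    active = any(stop - start >= min_run for start, stop in _runs(mask))
    return active, mask


def normalize_trace(
    trace: FluorescenceTrace, baseline: BaselineModel
) -> FluorescenceTrace:
    """Baseline-subtract and bleach-correct one trace (NaNs propagate)."""
    decay = baseline.decay_fraction(trace.times)
    normalized = (trace.signal - baseline.value(trace.times)) / decay
    return FluorescenceTrace(
        cell_id=trace.cell_id,
        allele_id=trace.allele_id,
        region_label=trace.region_label,
        times=trace.times,
        signal=normalized,
        truth=trace.truth,
    )


def call_bursts(
    trace: FluorescenceTrace,
    baseline: BaselineModel,
    analysis_start: float = DEFAULT_ANALYSIS_START,
    threshold_factor: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[Burst]:
    """Call bursts on one trace.

    A burst is a supra-threshold run of at least ``min_run`` frames whose
    frames lie at or after ``analysis_start`` — a run straddling the start
    only counts the frames inside the window.  Shorter runs are dropped,
    never merged.  Burst end is exclusive (last ON frame + one frame
    interval) so that durations, off periods and margins tile the analyzed
    span exactly.  Amplitudes are means of the median-filtered, normalized
    signal within the burst.
    """
    if len(trace.times) < 2:
        return []
    dt = float(trace.times[1] - trace.times[0])
    mask = _on_mask(trace, baseline, threshold_factor)
    mask &= trace.times >= analysis_start

    normalized = normalize_trace(trace, baseline)
    filtered_norm = median_filter3(normalized.signal)

    bursts: list[Burst] = []
    prev_end: float | None = None
    for start, stop in _runs(mask):
        if stop - start < min_run:
            continue
        start_time = float(trace.times[start])
        end_time = float(trace.times[stop - 1]) + dt
        with np.errstate(invalid="ignore"):
            amplitude = float(np.nanmean(filtered_norm[start:stop]))
        bursts.append(
            Burst(
                start_time=start_time,
                end_time=end_time,
                duration=end_time - start_time,
                amplitude=amplitude,
                off_period_before=None if prev_end is None else start_time - prev_end,
            )
        )
        prev_end = end_time
    return bursts


def annotate_trace(
    trace: FluorescenceTrace,
    baseline: BaselineModel,
    analysis_start: float = DEFAULT_ANALYSIS_START,
    threshold_factor: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    sustained_cutoff: float = DEFAULT_SUSTAINED_CUTOFF,
) -> TraceAnnotation:
    """Full burst-property annotation for one trace."""
    bursts = call_bursts(
        trace,
        baseline,
        analysis_start=analysis_start,
        threshold_factor=threshold_factor,
        min_run=min_run,
    )
    normalized = normalize_trace(trace, baseline)
    window = normalized.times >= analysis_start
    with np.errstate(invalid="ignore"):
        total = float(np.nansum(normalized.signal[window]))
    return TraceAnnotation(
        cell_id=trace.cell_id,
        allele_id=trace.allele_id,
        region_label=trace.region_label,
        active=bool(bursts),
        bursts=bursts,
        onset_time=bursts[0].start_time if bursts else None,
        end_time=bursts[-1].end_time if bursts else None,
        sustained=any(b.duration > sustained_cutoff for b in bursts),
        total_output=total,
    )


def annotate_ensemble(
    traces: list[FluorescenceTrace],
    baseline: BaselineModel | None = None,
    min_tracked: int = DEFAULT_MIN_TRACKED,
    **kwargs,
) -> list[TraceAnnotation]:
    """Filter, fit the baseline if not supplied, and annotate every trace."""
    kept = filter_tracked(traces, min_tracked)
    if not kept:
        return []
    if baseline is None:
        baseline = fit_baseline(kept)
    return [annotate_trace(t, baseline, **kwargs) for t in kept]


def burst_table(annotations: list[TraceAnnotation]) -> pd.DataFrame:
    """Long-format table with one row per called burst."""
    rows = []
    for ann in annotations:
        for burst in ann.bursts:
            rows.append(
                {
                    "cell_id": ann.cell_id,
                    "allele_id": ann.allele_id,
                    "region_label": ann.region_label,
                    "start_time": burst.start_time,
                    "end_time": burst.end_time,
                    "duration": burst.duration,
                    "amplitude": burst.amplitude,
                    "off_period_before": burst.off_period_before,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "allele_id",
            "region_label",
            "start_time",
            "end_time",
            "duration",
            "amplitude",
            "off_period_before",
        ],
    )


def _quartiles(values: list[float]) -> dict[str, float]:
    if not values:
        return {"median": math.nan, "q1": math.nan, "q3": math.nan}
    arr = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
    }


def summarize_bursting(annotations: list[TraceAnnotation]) -> pd.DataFrame:
    """Per-region summary of burst properties and activity fractions.

    One row per region: medians/quartiles of burst amplitude, duration and
    off period across all bursts, the fraction of cells active at any point
    in the analysis window, the fraction with sustained transcription
    (a burst > 10 min), onset/end-time medians and mean total output.
    Empty regions yield a flagged all-NaN row.
    """
    regions = sorted({a.region_label for a in annotations})
    rows = []
    for region in regions:
        anns = [a for a in annotations if a.region_label == region]
        bursts = [b for a in anns for b in a.bursts]
        amplitudes = [b.amplitude for b in bursts]
        durations = [b.duration for b in bursts]
        offs = [
            b.off_period_before for b in bursts if b.off_period_before is not None
        ]
        onsets = [a.onset_time for a in anns if a.onset_time is not None]
        ends = [a.end_time for a in anns if a.end_time is not None]
        row = {
            "region_label": region,
            "n_cells": len(anns),
            "n_bursts": len(bursts),
            "fraction_active": float(np.mean([a.active for a in anns])) if anns else math.nan,
            "fraction_sustained": float(np.mean([a.sustained for a in anns])) if anns else math.nan,
            "mean_total_output": float(np.mean([a.total_output for a in anns])) if anns else math.nan,
            "empty": not anns,
        }
        for name, values in (
            ("amplitude", amplitudes),
            ("duration", durations),
            ("off_period", offs),
            ("onset", onsets),
            ("end", ends),
        ):
            for stat, value in _quartiles(values).items():
                row[f"{name}_{stat}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
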