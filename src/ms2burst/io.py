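"""Trace-table and configuration I/O.

Trace tables are long-format CSV, one row per (cell, allele, frame):

    cell_id,allele_id,region_label,time,signal,tracked[,true_count]

Missing (untracked) signals are written as empty fields, never 0 or a
sentinel; times must lie on one uniform grid per file.  Run configuration is
a flat YAML (or JSON) document mirroring :class:`RunConfig`, whose defaults
are the package's study conditions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import KineticParams
from .simulator import FluorescenceTrace, SimulationConfig
from .traces import TraceAnnotation

__all__ = [
    "TraceTableError",
    "RunConfig",
    "read_trace_table",
    "write_trace_table",
    "annotations_to_frame",
]

TRACE_COLUMNS = ["cell_id", "allele_id", "region_label", "time", "signal", "tracked"]


class TraceTableError(ValueError):
    """Malformed trace table; the message names the offending rows."""


def write_trace_table(traces: list[FluorescenceTrace], path: str | Path) -> None:
    """Write traces as a long-format CSV (lossless round-trip).

    Ground-truth noiseless counts and activation times, when the traces
    carry them, are preserved in ``true_count`` / ``true_onset`` columns.
    """
    rows = []
    for trace in traces:
        counts = None if trace.truth is None else trace.truth.get("counts")
        onset = None if trace.truth is None else trace.truth.get("onset")
        for i, (t, s) in enumerate(zip(trace.times, trace.signal)):
            row = {
                "cell_id": trace.cell_id,
                "allele_id": trace.allele_id,
                "region_label": trace.region_label,
                "time": t,
                "signal": s if np.isfinite(s) else np.nan,
                "tracked": bool(np.isfinite(s)),
            }
            if counts is not None:
                row["true_count"] = counts[i]
            if onset is not None:
                row["true_onset"] = onset
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trace_table(path: str | Path) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV back into trace objects.

    Validates the header, key uniqueness and the uniformity of the time
    grid; error messages cite 1-based file line numbers (header = line 1).
    Frames absent for a given trace are filled in as untracked (NaN).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceTableError(f"missing required column(s): {', '.join(missing)}")

    dup = df.duplicated(subset=["cell_id", "allele_id", "time"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        raise TraceTableError(
            f"duplicate (cell_id, allele_id, time) keys at line(s) {lines}"
        )

    times = np.sort(df["time"].unique().astype(float))
    if len(times) > 2:
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            bad_time = times[1:][~np.isclose(steps, steps[0], rtol=1e-6, atol=1e-9)][0]
            lines = (df.index[df["time"] == bad_time] + 2).tolist()[:10]
            raise TraceTableError(
                f"non-uniform time grid (offending time {bad_time}, line(s) {lines})"
            )

    has_truth = "true_count" in df.columns
    traces = []
    for (cell_id, allele_id), group in df.groupby(
        ["cell_id", "allele_id"], sort=True
    ):
        group = group.sort_values("time")
        signal = np.full(len(times), np.nan)
        idx = np.searchsorted(times, group["time"].to_numpy(dtype=float))
        sig = group["signal"].to_numpy(dtype=float)
        tracked = group["tracked"].astype(bool).to_numpy()
        sig[~tracked] = np.nan
        signal[idx] = sig
        truth = None
        if has_truth:
            counts = np.full(len(times), np.nan)
            counts[idx] = group["true_count"].to_numpy(dtype=float)
            truth = {"counts": counts}
            if "true_onset" in group.columns:
                truth["onset"] = float(group["true_onset"].iloc[0])
        traces.append(
            FluorescenceTrace(
                cell_id=str(cell_id),
                allele_id=str(allele_id),
                region_label=str(group["region_label"].iloc[0]),
                times=times.copy(),
                signal=signal,
                truth=truth,
            )
        )
    return traces


def annotations_to_frame(annotations: list[TraceAnnotation]) -> pd.DataFrame:
    """One row per trace with its burst-property annotation."""
    return pd.DataFrame(
        [
            {
                "cell_id": a.cell_id,
                "allele_id": a.allele_id,
                "region_label": a.region_label,
                "active": a.active,
                "n_bursts": len(a.bursts),
                "onset_time": a.onset_time,
                "end_time": a.end_time,
                "sustained": a.sustained,
                "total_output": a.total_output,
            }
            for a in annotations
        ]
    )


@dataclass
class RunConfig:
    """Flat run configuration with the package's default study conditions.

    Defaults with an experimental source: frame_interval 15 s (acquisition
    rate), T 120 s (elongation-time estimate 1.6-2.5 min), threshold_factor
    1.2 / min_run 5 / min_tracked 10 / analysis_start 900 s / sustained
    cutoff 600 s (empirical trace-processing rules), n_bootstrap 50,
    synchrony_window 300 s, slow/fast k_on 0.01/0.1 1/s.  Everything else
    (r, k_off, noise_sd, ensemble size, duration) is an implementation
    choice, exposed here.
    """

    # kinetics
    r: float = 0.2
    k_on: float = 0.01
    k_off: float = 0.01
    T: float = 120.0
    # simulation / observation
    duration: float = 3600.0
    frame_interval: float = 15.0
    noise_sd: float = 1.0
    calibration: float = 1.0
    background: float = 0.0
    bleaching_rate: float = 0.0
    n_cells: int = 200
    paired_alleles: bool = False
    extrinsic_onset_sd: float = 0.0
    intrinsic_onset_sd: float = 0.0
    onset_time: float = 0.0
    signal_model: str = "step"
    region_label: str = "SIM"
    # trace processing
    threshold_factor: float = 1.2
    min_run: int = 5
    min_tracked: int = 10
    analysis_start: float = 900.0
    sustained_cutoff: float = 600.0
    # noise / diagnosis
    n_bootstrap: int = 50
    max_lag: float = 600.0
    decorrelation_level: float = 0.5
    z_cutoff: float = 2.0
    shift_z: float = 2.0
    alpha: float = 2.0
    # alleles
    synchrony_window: float = 300.0
    # run
    seed: int = 0
    outdir: str = "."

    def kinetic_params(self) -> KineticParams:
        return KineticParams(r=self.r, k_on=self.k_on, k_off=self.k_off, T=self.T)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            params=self.kinetic_params(),
            duration=self.duration,
            frame_interval=self.frame_interval,
            noise_sd=self.noise_sd,
            calibration=self.calibration,
            background=self.background,
            bleaching_rate=self.bleaching_rate,
            n_cells=self.n_cells,
            seed=self.seed,
            paired_alleles=self.paired_alleles,
            extrinsic_onset_sd=self.extrinsic_onset_sd,
            intrinsic_onset_sd=self.intrinsic_onset_sd,
            onset_time=self.onset_time,
            signal_model=self.signal_model,  # type: ignore[arg-type]
            region_label=self.region_label,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (JSON is a subset of YAML and is accepted too)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short digest of the full configuration, for run logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
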