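"""Shared fixtures: small simulated ensembles reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ms2burst import KineticParams, SimulationConfig, simulate_ensemble

SLOW_PARAMS = KineticParams(r=0.5, k_on=0.002, k_off=0.002, T=120.0)


def mixed_cohort(
    noise_sd: float,
    seed: int,
    n_active: int = 60,
    n_inactive: int = 60,
    params: KineticParams = SLOW_PARAMS,
    background: float = 10.0,
    calibration: float = 10.0,
    bleaching_rate: float = 0.0,
    duration: float = 3600.0,
):
    """Active + transcriptionally silent nuclei sharing one background floor.

    Mirrors a real movie: the silent cells let the two-pass baseline find the
    MCP-GFP background, and every trace keeps its ground truth.
    """
    cfg_active = SimulationConfig(
        params=params,
        duration=duration,
        frame_interval=15.0,
        noise_sd=noise_sd,
        background=background,
        calibration=calibration,
        bleaching_rate=bleaching_rate,
        n_cells=n_active,
        seed=seed,
    )
    cfg_silent = dataclasses.replace(
        cfg_active,
        params=dataclasses.replace(params, r=0.0),
        n_cells=n_inactive,
        seed=seed + 10_000,
    )
    ensemble = simulate_ensemble(cfg_active) + simulate_ensemble(cfg_silent)
    for i, trace in enumerate(ensemble):
        trace.cell_id = f"c{i:03d}"
    return ensemble


@pytest.fixture(scope="session")
def noiseless_cohort():
    return mixed_cohort(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_cohort():
    return mixed_cohort(noise_sd=2.0, seed=7)


def truth_on_mask(trace, min_run: int = 0) -> np.ndarray:
    """Ground-truth ON mask (nascent count > 0), optionally dropping runs
    shorter than ``min_run`` frames."""
    mask = trace.truth["counts"] > 0
    if min_run <= 1:
        return mask
    out = mask.copy()
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out
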