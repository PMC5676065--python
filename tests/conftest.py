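"""Shared fixtures.

The acceptance-style checks run whole virtual experiments; those runs are
expensive, so they are produced once per session here and shared across
tests.  Validation problem sizes (cells per population, seeds per arm) are
reduced relative to the headline experiment; docs/methods.md records the
sizes and why they suffice for the assertions made on them.
"""

from __future__ import annotations

import numpy as np
import pytest

import mitosim
from mitosim.perturb import get_preset

#: reduced validation sizes for whole-experiment suites
ARM_N_CELLS = 24
ARM_SEEDS = (1, 2, 3)
CONTROL_N_CELLS = 65
CONTROL_SEEDS = (1, 2, 3)


def run_arm(preset: str, seeds=ARM_SEEDS, n_cells=ARM_N_CELLS, **overrides):
    return [
        mitosim.run_simulation(get_preset(preset, seed=s, n_cells=n_cells, **overrides))
        for s in seeds
    ]


def seed_mean(trajs, name: str) -> np.ndarray:
    return np.mean([np.nan_to_num(t.tissue_mean(name), nan=0.0) for t in trajs], axis=0)


def restricted_mean_survival(trajs) -> float:
    time = trajs[0].time
    surv = np.mean([1 - t.life_counts()["dead"] / t.n_cells for t in trajs], axis=0)
    return float(np.trapezoid(surv, time))


@pytest.fixture(scope="session")
def control_runs_full():
    """Control preset at the headline population size (65 cells)."""
    return run_arm("control", seeds=CONTROL_SEEDS, n_cells=CONTROL_N_CELLS)


@pytest.fixture(scope="session")
def arm_runs():
    """All perturbation arms at the reduced validation size."""
    presets = (
        "control",
        "rapamycin15nM",
        "bafilomycin10nM",
        "pq5uM",
        "pq100uM",
        "pt100uM",
        "sod2_90",
        "sod2_100",
        "daf16_90",
        "skn1_100",
    )
    return {p: run_arm(p) for p in presets}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
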