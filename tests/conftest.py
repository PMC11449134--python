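"""Shared fixtures: synthetic cohorts exercised through the full pipeline.

The two expensive fixtures (planted-recovery table, planted-structure table)
are session-scoped; everything else is cheap and local to its test module.
"""

import numpy as np
import pandas as pd
import pytest

from dmndyn import power, preprocess, simulate
from dmndyn.spectral import N_BINS


@pytest.fixture(scope="session")
def recovery_setup():
    """One subject, 40 trials per task, constant planted profiles:
    gamma +30% and theta -20% during the AUT stimulus stage."""
    cfg = simulate.SimConfig(
        n_subjects=1, n_probes_per_subject=2, contacts_per_probe=3,
        rate=500.0, n_blocks=1, mw_per_block=40, aut_per_block=40,
        att_per_block=0, stimulus_s=16.0, response_s=16.0, seed=11)
    truth = simulate.GroundTruth.from_constants({
        ("gamma", "AUT", "stimulus", "*"): 30.0,
        ("theta", "AUT", "stimulus", "*"): -20.0,
    })
    return cfg, truth


@pytest.fixture(scope="session")
def recovery_table(recovery_setup):
    cfg, truth = recovery_setup
    rec, events, channels = simulate.simulate_recording(cfg, truth)
    epochs, channels = preprocess.preprocess_recording(rec, channels, events)
    return power.build_long_power_table("S01", epochs, channels)


def structured_truth():
    """Task-specific theta trajectories (shared across subsystems) and
    subsystem-specific gamma trajectories (shared across tasks)."""
    ramp = np.linspace(0.0, 1.0, N_BINS)
    cells = {
        ("theta", "MW", "stimulus", "*"): 40.0 - 30.0 * ramp,
        ("theta", "MW", "response", "*"): -10.0 - 20.0 * ramp,
        ("theta", "AUT", "stimulus", "*"): -30.0 + 60.0 * ramp,
        ("theta", "AUT", "response", "*"): 25.0 - 25.0 * ramp,
        ("gamma", "*", "stimulus", "lateral-DMN"): 20.0 + 30.0 * ramp,
        ("gamma", "*", "response", "lateral-DMN"): 60.0 + 0.0 * ramp,
        ("gamma", "*", "stimulus", "dorsomedial-DMN"): 15.0 + 0.0 * ramp,
        ("gamma", "*", "response", "dorsomedial-DMN"): 35.0 - 30.0 * ramp,
    }
    return simulate.GroundTruth.from_constants(cells)


@pytest.fixture(scope="session")
def structure_table():
    """Ten subjects with electrodes in both DMN subsystems and the planted
    task/subsystem dynamics of :func:`structured_truth`."""
    cfg = simulate.SimConfig(
        n_subjects=10, n_probes_per_subject=2, contacts_per_probe=2,
        rate=500.0, n_blocks=1, mw_per_block=4, aut_per_block=4,
        att_per_block=0, stimulus_s=16.0, response_s=16.0, seed=23)
    truth = structured_truth()
    tables = []
    for subject, rec, events, channels in simulate.simulate_cohort(cfg, truth):
        epochs, channels = preprocess.preprocess_recording(rec, channels, events)
        tables.append(power.build_long_power_table(subject, epochs, channels))
    return pd.concat(tables, ignore_index=True)
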