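"""Shared fixtures: the default stimulus design and noise-free synthetic
subjects built from the published group-level pathway parameters."""
from __future__ import annotations

import numpy as np
import pytest

import trackloop as tl

DURATION_S = 75.0
SAMPLE_RATE_HZ = 80.0
DISCARD_S = 25.0


@pytest.fixture(scope="session")
def grid() -> tl.FrequencyGrid:
    return tl.build_frequency_grid()


@pytest.fixture(scope="session")
def signal_groups(grid):
    rng = np.random.default_rng(1234)
    ref = tl.make_signal_groups(grid, "reference", rng)
    dist = tl.make_signal_groups(grid, "disturbance", rng)
    return ref, dist


@pytest.fixture(scope="session")
def plan(grid) -> tl.SessionPlan:
    return tl.build_session_plan(grid, rng_seed=7)


def make_subject(subject_id: str, group: str,
                 preview_filter=None, remnant_sd=0.0) -> tl.SyntheticSubject:
    p = tl.GROUP_PARAMS[group]
    return tl.SyntheticSubject(
        subject_id=subject_id,
        feedforward=tl.PathwayModel(**p["feedforward"]),
        feedback=tl.PathwayModel(**p["feedback"]),
        preview_filter=preview_filter,
        remnant_sd=remnant_sd,
    )


@pytest.fixture(scope="session")
def control_subject() -> tl.SyntheticSubject:
    return make_subject("control_01", "control")


@pytest.fixture(scope="session")
def ataxia_subject() -> tl.SyntheticSubject:
    return make_subject("ataxia_01", "ataxia")


def run_session(subject, plan, signal_groups):
    ref, dist = signal_groups
    return tl.simulate_session(subject, plan, ref, dist,
                               DURATION_S, SAMPLE_RATE_HZ)


@pytest.fixture(scope="session")
def control_records(control_subject, plan, signal_groups):
    return run_session(control_subject, plan, signal_groups)


@pytest.fixture(scope="session")
def ataxia_records(ataxia_subject, plan, signal_groups):
    return run_session(ataxia_subject, plan, signal_groups)


@pytest.fixture(scope="session")
def control_analysis(control_records, grid):
    return tl.identify_subject(control_records, grid, preview_ms=None,
                               discard_s=DISCARD_S, subject_id="control_01")


@pytest.fixture(scope="session")
def ataxia_analysis(ataxia_records, grid):
    return tl.identify_subject(ataxia_records, grid, preview_ms=None,
                               discard_s=DISCARD_S, subject_id="ataxia_01")
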