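"""Shared fixtures: rendered suites and their pipeline runs (session-scoped)."""

from __future__ import annotations

import pytest

from confine_track.config import AnalysisConfig
from confine_track.pipeline import run_pipeline
from confine_track.synth import (
    registration_suite,
    render_scenario,
    rupture_suite,
    tracking_suite,
    transit_suite,
)


def _run(scenario):
    sequence, gt = render_scenario(scenario)
    bundle = run_pipeline(AnalysisConfig(), sequence=sequence)
    return scenario, gt, bundle


@pytest.fixture(scope="session")
def registration_scenes():
    return [render_scenario(sc) + (sc,) for sc in registration_suite()]


@pytest.fixture(scope="session")
def tracking_run():
    return _run(tracking_suite()[0])


@pytest.fixture(scope="session")
def transit_runs():
    return [_run(sc) for sc in transit_suite()]


@pytest.fixture(scope="session")
def rupture_runs():
    return [_run(sc) for sc in rupture_suite()]
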