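"""Shared fixtures: one toy protein, one planted study, one full analysis.

The expensive artefacts (toy-protein build, default fixture, end-to-end
pipeline run and its cavity-free negative control) are session-scoped so the
whole suite pays for each of them once.
"""

from __future__ import annotations

import pytest

from crypticpocket.pipeline import (
    FixtureSpec,
    PipelineConfig,
    default_cavity_center,
    generate_fixture,
    run_analysis,
)
from crypticpocket.synthetic import (
    CavitySpec,
    StateSchedule,
    ToyProteinSpec,
    build_toy_protein,
    make_state_library,
    plant_transient_cavity,
)


@pytest.fixture(scope="session")
def toy_protein():
    return build_toy_protein(ToyProteinSpec(seed=0))


@pytest.fixture(scope="session")
def library4(toy_protein):
    return make_state_library(toy_protein, K=4, displacement=4.0, seed=1, min_separation=4.0)


@pytest.fixture(scope="session")
def cavity_spec(toy_protein):
    spec = FixtureSpec()
    center = default_cavity_center(toy_protein, spec.gate_range, spec.target_volume)
    return CavitySpec(spec.gate_range, tuple(center), spec.open_states, spec.target_volume)


@pytest.fixture(scope="session")
def planted_library(library4, cavity_spec):
    return plant_transient_cavity(library4, cavity_spec)


@pytest.fixture(scope="session")
def default_schedule():
    return StateSchedule((("S1", 0, 100), ("S2", 100, 220), ("S3", 220, 300), ("S4", 300, 400)))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    manifest = generate_fixture(FixtureSpec(seed=0), out)
    return manifest


@pytest.fixture(scope="session")
def analysis_bundle(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("analysis")
    config = PipelineConfig(
        topology=fixture_dir["topology"],
        ensemble=fixture_dir["ensemble"],
        reference=fixture_dir["reference"],
        output_dir=str(out),
        loop_gap_ranges=((12, 19), (1, 8)),
        helicity_range=(1, 11),
    )
    return run_analysis(config)


@pytest.fixture(scope="session")
def negative_bundle(tmp_path_factory):
    fix = tmp_path_factory.mktemp("negfixture")
    manifest = generate_fixture(FixtureSpec(seed=0, cavity=False), fix)
    out = tmp_path_factory.mktemp("neganalysis")
    config = PipelineConfig(
        topology=manifest["topology"],
        ensemble=manifest["ensemble"],
        reference=manifest["reference"],
        output_dir=str(out),
    )
    return run_analysis(config)
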