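"""Shared fixtures: a generated default scenario and its pipeline objects."""

from __future__ import annotations

from pathlib import Path

import pytest

from spliceoff.pipeline import ComparisonInput, PipelineConfig
from spliceoff.simulate import default_scenario, simulate_scenario

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory) -> Path:
    """Default 3-targeting-AON scenario at replicate depth 200, n=6."""
    out = tmp_path_factory.mktemp("scenario")
    simulate_scenario(default_scenario(depth=200), SCENARIO_SEED, out)
    return out


@pytest.fixture(scope="session")
def scenario(scenario_dir):
    from spliceoff.simulate import read_manifest

    return read_manifest(scenario_dir / "manifest.json")


@pytest.fixture(scope="session")
def pipeline_config(scenario_dir, scenario) -> PipelineConfig:
    return PipelineConfig(
        genome=scenario_dir / "genome.fa",
        gtf=scenario_dir / "annotation.gtf",
        aon_table=scenario_dir / "aons.tsv",
        comparisons=[
            ComparisonInput(
                name=name,
                rmats_dir=scenario_dir / "comparisons" / name,
                whippet_diff=scenario_dir / "comparisons" / name / "whippet.diff",
                targeting=spec["targeting"],
                scrambled=spec["scrambled"],
            )
            for name, spec in sorted(scenario.comparisons.items())
        ],
    )


@pytest.fixture(scope="session")
def scan_result(pipeline_config):
    from spliceoff.pipeline import run_scan

    return run_scan(pipeline_config)


@pytest.fixture(scope="session")
def classification(pipeline_config, scan_result):
    from spliceoff.pipeline import run_classification

    return run_classification(pipeline_config, scan_result.sites)
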