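"""Shared fixtures: the default seeded synthetic library and its pipeline run.

The chimera screen dominates runtime (hundreds of ~940 bp global
alignments), so the default library and the full pipeline result are built
once per session and shared.
"""

from __future__ import annotations

import pytest

from ardra.fixtures import load_table1
from ardra.otu import AbundanceTable
from ardra.pipeline import PipelineConfig, run_pipeline
from ardra.simulate import CommunitySpec, generate

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_library():
    return generate(CommunitySpec(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_result(default_library):
    return run_pipeline(
        default_library.clones,
        default_library.references,
        PipelineConfig(seed=DEFAULT_SEED),
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_abundance(table1):
    return AbundanceTable(dict(zip(table1["otu"], table1["count"])))


def pytest_configure(config):
    from hypothesis import settings

    settings.register_profile("repro", derandomize=True, deadline=None)
    settings.load_profile("repro")
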