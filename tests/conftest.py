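from __future__ import annotations

import pytest

from dadascan.pipeline import run_pipeline, scenario_config
from dadascan.simulate import build_element, default_scenario, default_templates


@pytest.fixture(scope="session")
def scenario():
    """The packaged synthetic survey scenario at its fixed seed."""
    return default_scenario(1)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def element():
    """A small element reused by characterization tests."""
    return build_element(42, 1500, 420)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the fixed-seed scenario, shared by the
    end-to-end tests."""
    run_dir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = scenario_config(str(run_dir), seed=1)
    summary = run_pipeline(cfg)
    return cfg, summary
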