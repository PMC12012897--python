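"""Shared fixtures: one synthetic dataset and one pipeline run per session."""

from __future__ import annotations

import pytest

from allohybrid.pipeline import PipelineConfig, run_pipeline
from allohybrid.simulate import GroundTruth, SimConfig, simulate_all


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default-scale synthetic dataset with planted ground truth (seed 1)."""
    root = tmp_path_factory.mktemp("dataset")
    config = SimConfig(seed=1)
    truth = simulate_all(config, root)
    return {"dir": root, "config": config, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    """Full pipeline executed once on the session dataset."""
    outdir = tmp_path_factory.mktemp("results")
    config = PipelineConfig(indir=str(dataset["dir"]), outdir=str(outdir), seed=1)
    summary = run_pipeline(config)
    return {"outdir": outdir, "config": config, "summary": summary}


@pytest.fixture(scope="session")
def truth(dataset) -> GroundTruth:
    return dataset["truth"]
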