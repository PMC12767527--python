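"""Shared fixtures.

The expensive fixture is ``pipeline_run``: one full end-to-end run of the
synthetic pipeline (generation -> prep -> training -> transfer ->
evaluation -> attribution -> design) at desk scale, shared session-wide by
the end-to-end and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from enhancerkit.pipeline import Pipeline, PipelineConfig
from enhancerkit.synthetic import MotifGrammar, generate_genome, plant_regulatory_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A small planted genome + ground truth for geometry/label tests."""
    genome = generate_genome(3, 120_000, seed=5)
    grammar = MotifGrammar()
    planted, truth = plant_regulatory_landscape(genome, grammar, n_regions_per_tissue=12, seed=6)
    return planted, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full synthetic end-to-end run under the default study conditions
    (3 tissues, 300 regions per tissue, compact architecture)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(out_dir=str(out), seed=11)
    pipe = Pipeline(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.run()
    return pipe


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
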