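"""Shared fixtures: tiny hand-written files and the standard synthetic run."""

from __future__ import annotations

import io

import pytest

from pathnet import annotations as ann
from pathnet import pipeline, synthetic
from pathnet.ontology import load_obo

CHAIN_OBO = """format-version: 1.2
default-namespace: biological_process
ontology: test

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: a
namespace: biological_process
is_a: GO:0000002
"""

DIAMOND_OBO = """format-version: 1.2
default-namespace: biological_process
ontology: test

[Term]
id: D
name: apex
namespace: biological_process

[Term]
id: B
name: left
namespace: biological_process
is_a: D

[Term]
id: C
name: right
namespace: biological_process
is_a: D

[Term]
id: A
name: base
namespace: biological_process
is_a: B
is_a: C
"""


@pytest.fixture
def chain_dag():
    """ROOT <- B <- A pure is_a chain."""
    return load_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_dag():
    """A -> {B, C} -> D diamond."""
    return load_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture(scope="session")
def std_paths(tmp_path_factory):
    """Standard synthetic corpus (std-v1, seed 17) written once per session."""
    outdir = tmp_path_factory.mktemp("std_v1")
    return synthetic.generate_all(outdir, synthetic.STD_V1)


@pytest.fixture(scope="session")
def std_corpus():
    return synthetic.generate_corpus(synthetic.STD_V1)


@pytest.fixture(scope="session")
def std_result(std_paths):
    """Full pipeline run on the standard corpus (shared; treat as read-only)."""
    cfg = pipeline.PipelineConfig(
        obo=std_paths["obo"],
        gaf=std_paths["gaf"],
        gmt=std_paths["gmt"],
        diseases=std_paths["diseases"],
    )
    return pipeline.run_all(cfg)


@pytest.fixture(scope="session")
def std_table(std_paths):
    """Filtered + propagated annotation table of the standard corpus."""
    dag = load_obo(std_paths["obo"])
    table = ann.load_gaf(std_paths["gaf"])
    return ann.propagate(ann.filter_evidence(table), dag), dag
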