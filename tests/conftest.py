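"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

import hypermet as hm


@pytest.fixture(scope="session")
def small_world() -> hm.SynthWorld:
    """A reduced planted world for fast pipeline-level tests."""
    return hm.generate_world(hm.SynthConfig(
        n_diseases=15, n_metabolites=80, n_proteins=24, n_go=40, seed=11,
    ))


@pytest.fixture(scope="session")
def small_hypergraph(small_world) -> hm.Hypergraph:
    return hm.build_hypergraph(small_world.tables, small_world.catalog)


@pytest.fixture(scope="session")
def small_embeddings(small_world):
    """(hypergraph, vertex embeddings, disease embeddings, diagnostics)."""
    config = hm.PipelineConfig(embed_dim=16, hidden_dim=16, max_epochs=40,
                               ae_max_epochs=120, seed=11)
    return hm.embed_world(small_world, config)
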