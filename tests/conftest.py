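"""Shared fixtures: simulated experiments reused across the suite.

All heavy simulations are session-scoped so each configuration is built
once. Every fixture is fully deterministic (fixed seeds).
"""

from __future__ import annotations

import numpy as np
import pytest

import covarnet as cn
import covarnet.preprocess as pp
from covarnet import network, sim


def preprocess_pipeline(adata, layer="exon"):
    adata = pp.apply_cell_qc(adata)
    adata = pp.filter_genes(adata)
    return pp.rpm_normalize(adata, layer=layer)


def call_pipeline(cfg, layer="exon"):
    adata, truth = sim.simulate_counts(cfg)
    adata = preprocess_pipeline(adata, layer=layer)
    res = cn.replicate_correlations(adata)
    calls = cn.call_covariations(res)
    return adata, truth, res, calls


@pytest.fixture(scope="session")
def modular_run():
    """Default disjoint-module conditions (2,000 genes, 24 modules, seed 1)."""
    return call_pipeline(sim.modular_config(seed=1))


@pytest.fixture(scope="session")
def modular_ko_run():
    return call_pipeline(sim.modular_config(seed=1, knockout=True))


@pytest.fixture(scope="session")
def null_run():
    """No planted structure: 150 genes (>10,000 pairs), loading 0, seed 1."""
    cfg = cn.SimConfig(n_genes=150, n_factors=0, loading_scale=0.0, seed=1)
    adata, truth = sim.simulate_counts(cfg)
    adata = preprocess_pipeline(adata)
    res = cn.replicate_correlations(adata)
    return adata, truth, res, cn.call_covariations(res)


@pytest.fixture(scope="session")
def transcriptome_wt():
    """Dense transcriptome-wide covariation conditions, wild type, exon."""
    adata, truth, res, calls = call_pipeline(sim.transcriptome_config(seed=1))
    net = network.build_network(calls)
    return adata, truth, calls, net


@pytest.fixture(scope="session")
def transcriptome_annotations(transcriptome_wt):
    _, truth, _, _ = transcriptome_wt
    return sim.simulate_annotations(truth)


@pytest.fixture(scope="session")
def transcriptome_nets():
    """Networks for all four condition x layer combinations (shared seed)."""
    nets = {}
    for ko in (False, True):
        for layer in ("exon", "intron"):
            adata, _ = sim.simulate_counts(sim.transcriptome_config(seed=1, knockout=ko))
            adata = preprocess_pipeline(adata, layer=layer)
            calls = cn.call_covariations(cn.replicate_correlations(adata))
            nets[("ko" if ko else "wt", layer)] = network.build_network(calls)
    return nets


@pytest.fixture(scope="session")
def modular_network(modular_run):
    _, _, _, calls = modular_run
    return network.build_network(calls)
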