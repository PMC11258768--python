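"""Shared fixtures: small synthetic proteins and one full planted pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from spatialmtr import (
    SimulationConfig,
    aggregate_observed,
    enumerate_expected,
    make_cds,
    make_helix_model,
    map_counts_to_model,
    score_protein,
)
from spatialmtr.annotation import merge_counts
from spatialmtr.simulate import make_labeled_variants, simulate_observed
from spatialmtr.structure import ProteinModel, Residue3D


def collinear_model(spacing: float = 3.8, n: int = 5) -> ProteinModel:
    """Residues on the x axis at the given spacing."""
    residues = [
        Residue3D(
            index=i,
            aa="A",
            ca_coord=np.array([(i - 1) * spacing, 0.0, 0.0]),
            plddt=90.0,
        )
        for i in range(1, n + 1)
    ]
    return ProteinModel(protein_id="line", residues=residues)


@pytest.fixture
def chain5() -> ProteinModel:
    return collinear_model()


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    return SimulationConfig()  # defaults are the planted-signal condition


@pytest.fixture(scope="session")
def planted_pipeline(planted_config):
    """Transcript, model, counts and scores for the planted condition."""
    cfg = planted_config
    tx = make_cds(cfg.n_residues, cfg.seed)
    model = make_helix_model(cfg, sequence=tx.protein)
    observed = simulate_observed(tx, cfg)
    counts = merge_counts(
        enumerate_expected(tx), aggregate_observed(observed, tx)
    )
    counts = map_counts_to_model(counts, tx, model)
    score_set = score_protein(
        model, counts, transcript_id=tx.transcript_id
    )
    labels = make_labeled_variants(cfg)
    return {
        "config": cfg,
        "transcript": tx,
        "model": model,
        "observed": observed,
        "counts": counts,
        "scores": score_set,
        "labels": labels,
    }
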