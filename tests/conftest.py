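"""Shared fixtures: one decomposed synthetic corpus and one trained
pipeline, both session-scoped because decomposition and cross-validated
training dominate the suite's runtime."""

import numpy as np
import pytest

from submovekit.closed_loop import AnnPolicy, SimulationConfig, evaluate_closed_loop
from submovekit.decompose import DecompositionConfig, decompose_dataset
from submovekit.features import build_training_tables
from submovekit.io import preprocess_dataset
from submovekit.nets import TrainingConfig, crossval_evaluate, train_nets
from submovekit.synthetic import GeneratorConfig, generate_corpus

CORPUS_SEED = 0
N_REACHES = 50


@pytest.fixture(scope="session")
def decomposed_corpus():
    """50 well-separated synthetic reaches (sigma_v = 0.5 cm/s), preprocessed
    and decomposed over N = 1..10. Ground truth rides along for
    parameter-recovery checks."""
    gen = GeneratorConfig.well_separated(n_reaches=N_REACHES, seed=CORPUS_SEED)
    ds, truths = generate_corpus(gen)
    ds = preprocess_dataset(ds)
    dcfg = DecompositionConfig(n_range=tuple(range(1, 11)), n_restarts=3, seed=CORPUS_SEED)
    decomps = decompose_dataset(ds, dcfg)
    truths = {tr.trial_id: t for tr, t in zip(ds.trials, truths)}
    return ds, truths, decomps, (gen, dcfg)


@pytest.fixture(scope="session")
def trained_pipeline():
    """The full prediction study on a default-policy corpus: 400 reaches
    decomposed over N = 1..7, cross-validated networks and the closed-loop
    evaluation. Sized so the amplitude/duration networks have on the order
    of a thousand training rows."""
    gen = GeneratorConfig(n_reaches=400, seed=CORPUS_SEED)
    ds, truths = generate_corpus(gen)
    ds = preprocess_dataset(ds)
    dcfg = DecompositionConfig(n_range=tuple(range(1, 8)), n_restarts=2, seed=CORPUS_SEED)
    decomps = decompose_dataset(ds, dcfg)
    tables = build_training_tables(ds, decomps)
    tcfg = TrainingConfig(seed=CORPUS_SEED)
    cv = crossval_evaluate(*tables, tcfg)
    nets = train_nets(*tables, tcfg)
    closed = evaluate_closed_loop(AnnPolicy(nets), ds, SimulationConfig())
    return {
        "dataset": ds,
        "truths": {tr.trial_id: t for tr, t in zip(ds.trials, truths)},
        "decompositions": decomps,
        "tables": tables,
        "crossval": cv,
        "nets": nets,
        "closed_loop": closed,
    }
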