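"""Shared fixtures: reference matrices and a realistically deep simulated
matrix set (session-scoped, seeded) that several modules test against."""

import numpy as np
import pytest

import ctxcodon as cc
from ctxcodon.datasets import REFERENCE_CONTEXT_MATRICES, REFERENCE_EQUILIBRIA

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def reference_matrices():
    return REFERENCE_CONTEXT_MATRICES


@pytest.fixture(scope="session")
def reference_equilibria():
    return REFERENCE_EQUILIBRIA


@pytest.fixture(scope="session")
def table1_model():
    return cc.make_preset_model("table1_like", seed=1)


@pytest.fixture(scope="session")
def simulated_raw256(table1_model):
    """Raw per-context counts scored from simulated chloroplast-like triplets."""
    batches = [
        cc.extract_site_observations(
            cc.simulate_triplet(table1_model, 1_000_000, seed=500 + i)
        )
        for i in range(3)
    ]
    return cc.count_contexts(cc.SiteObservations.concatenate(batches))


@pytest.fixture(scope="session")
def simulated_pooled48(simulated_raw256):
    return cc.pool_matrices(simulated_raw256, scheme="AT")


@pytest.fixture(scope="session")
def synthetic_fitness(simulated_pooled48):
    """Fitness table built from a biased synthetic reference gene pair."""
    rng = np.random.default_rng(77)
    refs = []
    for seed in (11, 12):
        aa = "".join(rng.choice(list(AA_ALPHABET), 400))
        gene = cc.simulate_neutral_gene(aa, simulated_pooled48, seed=seed)
        refs.append(cc.CodonUsageTable.from_sequence(gene, gene_id=f"ref{seed}"))
    return cc.build_fitness_table(refs)


def random_aa(rng, length):
    return "".join(rng.choice(list(AA_ALPHABET), length))
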