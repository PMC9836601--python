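import numpy as np
import pytest

from mitoanchor.consensus import CallPolicy, build_pileup, reconstruct
from mitoanchor.kalign import align_reads
from mitoanchor.simlib import (
    DamageParams,
    LibraryParams,
    mutate_genome,
    random_genome,
    simulate_library,
)


@pytest.fixture(scope="session")
def truth_genome():
    return random_genome(4000, seed=11, gc=0.45)


@pytest.fixture(scope="session")
def diverged_query(truth_genome):
    q = mutate_genome(truth_genome, 0.05, seed=12)
    q.id = "query"
    return q


def make_library(truth, *, n_pairs=300, read_len=100, insert_mean=120,
                 insert_sd=25, endogenous_fraction=1.0, seq_error=0.0,
                 damage=None, seed=3):
    lib = LibraryParams(n_pairs=n_pairs, read_len=read_len,
                        insert_mean=insert_mean, insert_sd=insert_sd,
                        endogenous_fraction=endogenous_fraction,
                        seq_error=seq_error, seed=seed)
    r1, r2, truths = simulate_library(truth, None, lib,
                                      damage or DamageParams())
    return r1 + r2, truths


def quick_reconstruction(reads, query, preset="low", policy=None):
    alignments, _ = align_reads(reads, query, preset)
    pileup = build_pileup(alignments, dict(reads), query)
    return reconstruct(pileup, query, policy or CallPolicy()), pileup


@pytest.fixture(scope="session")
def clean_reads(truth_genome):
    reads, _ = make_library(truth_genome, seed=3)
    return reads


@pytest.fixture(scope="session")
def clean_reconstruction(clean_reads, diverged_query):
    return quick_reconstruction(clean_reads, diverged_query)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
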