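"""Shared fixtures: small pedigrees, simulated datasets, chain states."""

from __future__ import annotations

import io

import numpy as np
import pytest

import ssnnmm as sm
from ssnnmm.engine import Chain, RunConfig
from ssnnmm.simulate import assign_roles


def make_pedigree(text: str):
    """Pedigree from inline CSV text, topologically ordered."""
    return sm.topological_order(sm.read_pedigree(io.StringIO(text)))


@pytest.fixture
def trio():
    return make_pedigree("id,sire,dam\n1,0,0\n2,0,0\n3,1,2\n")


@pytest.fixture
def fullsib_mating():
    """Founders 1,2; full sibs 3,4; inbred offspring 5."""
    return make_pedigree("id,sire,dam\n1,0,0\n2,0,0\n3,1,2\n4,1,2\n5,3,4\n")


def random_pedigree(seed: int, n: int = 120):
    """Arbitrary acyclic pedigree with founders, unknown single parents and
    repeated matings — exercises every branch of Henderson's rules."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if i < 5:
            continue
        kind = rng.random()
        if kind < 0.15:
            continue  # founder
        if kind < 0.3:  # one known parent
            sire[i] = rng.integers(0, i)
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sire[i], dam[i] = s, d
    return sm.Pedigree(
        ids=tuple(f"I{k}" for k in range(n)), sire=sire, dam=dam, ordered=True
    )


@pytest.fixture(scope="session")
def small_dataset():
    """200 individuals, 40 markers, polygenic-ish trait, 30-animal test set."""
    ped = sm.simulate_pedigree(40, 4, 2, seed=101)
    geno = sm.gene_drop(ped, 40, seed=102)
    pheno, truth = sm.simulate_phenotypes(geno, qtl_prop=0.1, h2=0.7, seed=103)
    pheno = assign_roles(pheno, ped, 30)
    return ped, geno, pheno, truth


def make_chain(ped, geno, pheno, **cfg_kwargs) -> Chain:
    return Chain(ped, geno, pheno, RunConfig(**cfg_kwargs))
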