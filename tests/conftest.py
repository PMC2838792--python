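"""Shared fixtures: small pedigrees, trait matrices, and builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cladelink.io import (GeneticMap, GenotypeTable, Individual, Marker,
                          Pedigree, TraitMatrix)


@pytest.fixture
def toy():
    from cladelink.simulate import make_toy_fixture

    return make_toy_fixture()


@pytest.fixture
def random_matrix():
    """Factory for random binary trait matrices with optional missingness."""

    def build(n, n_traits, seed, missing=0.0):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 2, size=(n, n_traits)).astype(float)
        if missing:
            arr[rng.random((n, n_traits)) < missing] = np.nan
        return TraitMatrix(pd.DataFrame(
            arr, index=[f"I:{k}" for k in range(n)],
            columns=[f"t{j}" for j in range(n_traits)]))

    return build


@pytest.fixture
def nuclear_family():
    """Factory: two founders + n children, one marker, optional genotypes.

    Returns (pedigree, genotypes, map). Genotypes are Mendelian-consistent:
    parents (1,2) x (3,4), children drawn from parental alleles.
    """

    def build(n_children=2, seed=0, alleles=(1, 2, 3, 4),
              freqs=(0.25, 0.25, 0.25, 0.25), typed=True):
        rng = np.random.default_rng(seed)
        gmap = GeneticMap([Marker("M1", "1", 0.0, alleles, freqs)])
        inds = [Individual("F", "1", None, None, "male", 2),
                Individual("F", "2", None, None, "female", 1)]
        for k in range(n_children):
            inds.append(Individual("F", str(3 + k), "1", "2",
                                   "male" if k % 2 == 0 else "female",
                                   2 if k % 2 == 0 else 1))
        ped = Pedigree(inds)
        gt = GenotypeTable([i.uid for i in inds], gmap)
        if typed:
            pg = {"F:1": (alleles[0], alleles[1]),
                  "F:2": (alleles[2 % len(alleles)], alleles[3 % len(alleles)])}
            for u, g in pg.items():
                gt.set(u, "M1", g)
            for k in range(n_children):
                gt.set(f"F:{3 + k}", "M1", tuple(sorted(
                    (pg["F:1"][rng.integers(2)], pg["F:2"][rng.integers(2)]))))
        return ped, gt, gmap

    return build


@pytest.fixture
def phase_known_family():
    """Factory: three-generation family giving phase-known paternal meioses
    (see :func:`cladelink.reference.phase_known_family`)."""
    from cladelink.reference import phase_known_family as build

    return build
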