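"""Shared fixtures: small trees, clade maps, models and simulated data."""

from __future__ import annotations

import numpy as np
import pytest

from phylosupport.alignment import Alignment
from phylosupport.likelihood import simulate_alignment
from phylosupport.model import SubstitutionModel
from phylosupport.synthetic_data import (CladeTreeConfig, make_clade_tree,
                                         make_profile_library)
from phylosupport.treeops import CladeMap, parse_newick


@pytest.fixture
def worked_tree():
    """The 7-tip worked example: stems readable off the construction."""
    return parse_newick(
        "(((P1:1,P2:1):0.4,((C1:1,C2:1):0.1,(X1:1,X2:1):0.1):0.2):0.3,O1:2);")


@pytest.fixture
def worked_clademap():
    return CladeMap({"Outgroup": {"O1"},
                     "Lophotrochozoa": {"P1"}, "Ecdysozoa": {"P2"},
                     "Chordata": {"C1", "C2"},
                     "Xenambulacraria": {"X1", "X2"}})


@pytest.fixture(scope="session")
def lg_gamma():
    return SubstitutionModel.lg(gamma_alpha=0.7)


@pytest.fixture(scope="session")
def mixture_model():
    """Three sparse profiles + gamma, the small heterogeneous test model."""
    profiles = make_profile_library(3, concentration=0.3, seed=11)
    return SubstitutionModel.mixture(profiles, gamma_alpha=0.7)


@pytest.fixture(scope="session")
def five_tip_tree():
    return parse_newick("((A:0.11,B:0.23):0.08,(C:0.3,D:0.14):0.06,E:0.2);")


@pytest.fixture(scope="session")
def five_tip_alignment(five_tip_tree, mixture_model):
    return simulate_alignment(five_tip_tree, mixture_model, 60, seed=21)


@pytest.fixture(scope="session")
def default_clade_tree():
    """Default 20-taxon DM clan tree and its clade map (seed 0)."""
    return make_clade_tree(CladeTreeConfig(seed=0))


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary tree via sequential joining; lengths U(0.02, 0.6)."""
    frags = [f"t{i}" for i in range(n_tips)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a, b = frags[i], frags[j]
        la, lb = rng.uniform(0.02, 0.6, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(merged)
    return frags[0] + ";"
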