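"""Shared fixtures and the independent brute-force likelihood oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.linalg
from hypothesis import HealthCheck, settings

import chromlik as ck

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Independent oracle: literal sum-product enumeration
# ---------------------------------------------------------------------------

def enumeration_negloglik(tree: ck.Phylogeny, tip_vectors: dict,
                          Qd: np.ndarray, prior: np.ndarray) -> float:
    """Likelihood by explicit enumeration of internal-node states.

    Per-branch transition matrices come straight from ``scipy.linalg.expm``;
    the joint probability of every assignment of states to internal nodes
    is accumulated in plain Python loops with no rescaling, caching or
    vectorized recursion, making this a genuinely independent check of the
    pruning engine on small trees.
    """
    n = Qd.shape[0]
    P = {i: scipy.linalg.expm(Qd * tree.edge_length[i])
         for i in range(tree.n_nodes) if i != tree.root}
    # Marginalize each tip against its conditioning vector up front.
    tip_factor = {i: P[i] @ tip_vectors[tree.tip_label[i]]
                  if i != tree.root else None
                  for i in tree.tip_label}
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = prior[amap[tree.root]]
        for i in internals:
            if i == tree.root:
                continue
            prob *= P[i][amap[tree.parent[i]], amap[i]]
        for i in tree.tip_label:
            prob *= tip_factor[i][amap[tree.parent[i]]]
        total += prob
    return -np.log(total)


@pytest.fixture(scope="session")
def oracle():
    return enumeration_negloglik


# ---------------------------------------------------------------------------
# Spaces, parameters, trees
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def bichrom_space():
    """Full-size two-trait space (c_max = 25, 52 states)."""
    return ck.build_state_space(25, (0, 1))


@pytest.fixture(scope="session")
def small_space():
    """Small two-trait space (c_max = 5, 12 states) for enumeration tests."""
    return ck.build_state_space(5, (0, 1))


@pytest.fixture(scope="session")
def solanum_space():
    return ck.solanum_state_space()


@pytest.fixture(scope="session")
def nuisance_params():
    """The eight fixed rates of the simulation scenarios."""
    return dict(ck.NUISANCE_RATES)


@pytest.fixture(scope="session")
def s1_params(nuisance_params):
    return ck.BiChroMParams(**nuisance_params, rho0=0.01, rho1=0.01)


@pytest.fixture
def four_tip_tree():
    return ck.read_newick("((A:3.1,B:0.4):1.2,(C:2.0,D:0.7):2.5);")


@pytest.fixture
def four_tip_obs():
    return ck.TipObservations(
        {"A": (5, 0), "B": (12, 1), "C": (26, 0), "D": (3, 1)})


@pytest.fixture(scope="session")
def sim_tree_and_tips(bichrom_space, s1_params):
    """A 40-tip simulated data set under S1 for quick fitting tests."""
    Q = ck.build_q_bichrom(s1_params, bichrom_space)
    tree = ck.rescale_height(ck.simulate_yule_tree(40, 7), 50.0)
    tips = ck.simulate_tips(tree, Q, bichrom_space, seed=8)
    return tree, tips
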