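"""Metastability index, hub-set search and hierarchy selection."""

from itertools import combinations

import numpy as np
import pytest

from helpers import chain_from_flux, metastable_chain

from chromwalk.errors import InvalidSetError
from chromwalk.metastability import (
    HubSet,
    MetastabilityProfile,
    grow_hub_set,
    mc_optimize_hubs,
    metastability_index,
    rho_profile,
    seed_pair,
    select_hierarchy,
)
from chromwalk.msm import kinetic_matrices


def _rho_reference(gamma, members):
    """Loop-based re-implementation of the metastability index."""
    members = list(members)
    num = max(gamma[i, j] for i in members for j in members if i != j)
    den = min(
        max(gamma[k, j] for j in members)
        for k in range(gamma.shape[0])
        if k not in members
    )
    return num / den


def test_metastability_index_matches_reference():
    rng = np.random.default_rng(0)
    gamma = rng.uniform(0.01, 1.0, (9, 9))
    np.fill_diagonal(gamma, 0.0)
    for members in [(0, 5), (1, 4, 7), (0, 2, 3, 8)]:
        assert metastability_index(gamma, members) == pytest.approx(
            _rho_reference(gamma, members), rel=1e-12
        )


def test_metastability_index_low_for_true_blocks():
    # two well-separated blocks: a hub in each block scores far below
    # a hub pair inside one block
    rng = np.random.default_rng(1)
    model = metastable_chain(10, rng, n_blocks=2, eps=0.001)
    gamma = kinetic_matrices(model).gamma
    across = metastability_index(gamma, (0, 9))
    within = metastability_index(gamma, (0, 1))
    assert across < 0.1
    assert within > 10 * across


@pytest.mark.parametrize(
    "members", [(1,), (2, 2), (-1, 3), (0, 99), tuple(range(9))]
)
def test_metastability_index_validates_members(members):
    gamma = np.ones((9, 9))
    with pytest.raises(InvalidSetError):
        metastability_index(gamma, members)


def test_hubset_sorts_and_validates():
    h = HubSet(members=(5, 2, 9), rho=0.3)
    assert h.members == (2, 5, 9)
    assert h.size == 3
    with pytest.raises(InvalidSetError):
        HubSet(members=(1, 1), rho=0.0)
    with pytest.raises(InvalidSetError):
        HubSet(members=(1,), rho=0.0)


def test_seed_pair_matches_brute_force():
    rng = np.random.default_rng(2)
    model = metastable_chain(8, rng)
    gamma = kinetic_matrices(model).gamma
    pair = seed_pair(model, gamma)
    a = int(np.argmax(model.stationary))
    best = min(
        (metastability_index(gamma, (a, i)), i) for i in range(8) if i != a
    )
    assert pair.members == tuple(sorted((a, best[1])))
    assert pair.rho == pytest.approx(best[0], rel=1e-12)


def test_grow_hub_set_matches_brute_force():
    rng = np.random.default_rng(3)
    gamma = rng.uniform(0.01, 1.0, (11, 11))
    np.fill_diagonal(gamma, 0.0)
    base = HubSet(members=(2, 7), rho=metastability_index(gamma, (2, 7)))
    grown = grow_hub_set(gamma, base)
    candidates = [
        (metastability_index(gamma, (2, 7, i)), i)
        for i in range(11)
        if i not in (2, 7)
    ]
    best_rho, best_i = min(candidates)
    assert grown.members == tuple(sorted((2, 7, best_i)))
    assert grown.rho == pytest.approx(best_rho, rel=1e-12)


def test_mc_never_worse_than_init_and_is_deterministic():
    rng = np.random.default_rng(4)
    model = metastable_chain(10, rng, n_blocks=3)
    gamma = kinetic_matrices(model).gamma
    init = HubSet(members=(0, 1, 2), rho=metastability_index(gamma, (0, 1, 2)))
    out1 = mc_optimize_hubs(gamma, model.stationary, 3, init, iters=300, seed=11)
    out2 = mc_optimize_hubs(gamma, model.stationary, 3, init, iters=300, seed=11)
    assert out1.rho <= init.rho + 1e-12
    assert out1.members == out2.members
    assert out1.rho == out2.rho
    assert out1.rho == pytest.approx(
        metastability_index(gamma, out1.members), rel=1e-12
    )


def test_rho_profile_finds_planted_block_count():
    rng = np.random.default_rng(5)
    model = metastable_chain(12, rng, n_blocks=3, eps=0.001)
    gamma = kinetic_matrices(model).gamma
    profile = rho_profile(gamma, model, n_max=6, iters=300, seed=0)
    brute3 = min(
        metastability_index(gamma, c) for c in combinations(range(12), 3)
    )
    assert profile.by_size[3].rho == pytest.approx(brute3, rel=1e-9)
    assert profile.by_size[3].rho < 0.1


def _fake_profile(rhos):
    by_size = {
        n: HubSet(members=(0, 1), rho=float(r))
        for n, r in zip(range(2, 2 + len(rhos)), rhos)
    }
    # HubSet freezes members; sizes come from the dict keys only
    return MetastabilityProfile(by_size=by_size, n_max=1 + len(rhos))


def test_select_hierarchy_minima_threshold_and_doubling():
    #       n:   2    3    4    5    6    7    8    9    10
    profile = _fake_profile([0.1, 0.5, 0.2, 0.6, 0.3, 0.9, 0.75, 0.95, 0.9])
    levels = select_hierarchy(profile)
    assert levels.all_minima == [2, 4, 6, 8]
    # trivial n=2 dropped; 6 < 2*4 dropped by doubling; 8 kept
    assert levels.sizes == [4, 8]
    assert select_hierarchy(profile, keep_trivial=True).sizes == [2, 4, 8]
    assert select_hierarchy(profile, skip_first=True).sizes == [6]


def test_select_hierarchy_plateaus_and_edges():
    # plateau 0.3,0.3 is one minimum at its smallest n; the first point
    # counts when below its right neighbour; the last point never counts
    profile = _fake_profile([0.2, 0.7, 0.3, 0.3, 0.8, 0.1])
    levels = select_hierarchy(profile, keep_trivial=True)
    assert levels.all_minima == [2, 4]
    assert levels.sizes == [2, 4]


def test_select_hierarchy_empty_is_valid():
    profile = _fake_profile([0.9, 0.95, 0.99])
    assert select_hierarchy(profile).sizes == []
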