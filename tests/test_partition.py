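"""Committors, hard partitions, NMI/RMI and the random baseline."""

import numpy as np
import pytest

from helpers import chain_from_flux

from chromwalk.errors import InvalidSpecError, UndefinedEntropyError
from chromwalk.metastability import HubSet
from chromwalk.partition import (
    PartitionSet,
    assign_hierarchical_labels,
    committor_probabilities,
    hard_assign,
    normalized_mutual_information,
    random_boundary_baseline,
    rescaled_mi,
)


def test_committor_partition_of_unity_and_boundaries():
    rng = np.random.default_rng(0)
    model = chain_from_flux(np.exp(rng.normal(0, 1, (12, 12))))
    hubs = HubSet(members=(1, 5, 9), rho=0.0)
    soft = committor_probabilities(model, hubs)
    assert soft.q.shape == (12, 3)
    assert np.allclose(soft.q.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(soft.q[[1, 5, 9], :], np.eye(3))
    assert (soft.q >= -1e-12).all()


def test_committor_three_state_uniform():
    model = chain_from_flux(np.ones((3, 3)))
    soft = committor_probabilities(model, HubSet(members=(0, 2), rho=0.0))
    # from the middle state both hubs are one uniform step away
    assert soft.q[1, 0] == pytest.approx(0.5)
    assert soft.q[1, 1] == pytest.approx(0.5)


def test_committor_matches_independent_absorbing_solve():
    rng = np.random.default_rng(1)
    model = chain_from_flux(np.exp(rng.normal(0, 1, (8, 8))))
    members = (0, 4)
    soft = committor_probabilities(model, HubSet(members=members, rho=0.0))
    # independent oracle: absorbing-chain fundamental matrix N = (I-Q)^-1
    p = model.transition
    interior = [i for i in range(8) if i not in members]
    q_mat = p[np.ix_(interior, interior)]
    r_mat = p[np.ix_(interior, list(members))]
    absorb = np.linalg.inv(np.eye(len(interior)) - q_mat) @ r_mat
    assert np.allclose(soft.q[interior, :], absorb, atol=1e-10)


def test_hard_assign_argmax_and_tie_break():
    from chromwalk.partition import SoftPartition

    soft_q = np.array([[1.0, 0.0], [0.2, 0.8], [0.5, 0.5], [0.0, 1.0]])
    sp = SoftPartition(q=soft_q, hubs=HubSet(members=(0, 3), rho=0.0))
    parts = hard_assign(sp, resolution=10)
    assert list(parts.assignment) == [0, 1, 0, 1]  # tie -> first (lowest) hub
    assert parts.resolution == 10
    assert parts.n_partitions == 2


def test_nmi_identical_schemes():
    a = PartitionSet.from_assignment([0, 0, 1, 1, 2, 2])
    b = PartitionSet.from_assignment([2, 2, 0, 0, 1, 1])  # relabelled copy
    assert normalized_mutual_information(a, a) == pytest.approx(1.0)
    assert normalized_mutual_information(a, b) == pytest.approx(1.0)
    assert normalized_mutual_information(a, a, variant="literal") == pytest.approx(0.5)


def test_nmi_independent_schemes_is_zero():
    a = PartitionSet.from_assignment([0, 0, 1, 1])
    b = PartitionSet.from_assignment([0, 1, 0, 1])
    assert normalized_mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)


def test_nmi_errors():
    a = PartitionSet.from_assignment([0, 0, 1, 1])
    with pytest.raises(InvalidSpecError):
        normalized_mutual_information(a, PartitionSet.from_assignment([0, 1]))
    with pytest.raises(UndefinedEntropyError):
        normalized_mutual_information(a, PartitionSet.from_assignment([0, 0, 0, 0]))
    with pytest.raises(InvalidSpecError):
        normalized_mutual_information(a, a, variant="bogus")


def test_rescaled_mi_anchor_points():
    assert rescaled_mi(0.77) == 0.0
    assert rescaled_mi(1.0) == 1.0
    assert rescaled_mi(0.885) == pytest.approx(0.5)


def test_baseline_singleton_scheme_is_exactly_one():
    # k = n leaves a unique boundary placement: both random schemes are the
    # identity partition, so NMI = 1 for every sample
    scheme = PartitionSet.from_assignment(np.arange(6))
    assert random_boundary_baseline(scheme, samples=10, seed=0) == pytest.approx(1.0)


def test_baseline_matches_exhaustive_enumeration():
    # n=5 loci, k=2: 4 possible cut positions; enumerate all 16 ordered
    # scheme pairs exactly and compare with the sampled mean
    n, cuts = 5, range(1, 5)

    def scheme_for(c):
        return PartitionSet.from_assignment([0] * c + [1] * (n - c))

    exact = np.mean(
        [
            normalized_mutual_information(scheme_for(c1), scheme_for(c2))
            for c1 in cuts
            for c2 in cuts
        ]
    )
    est = random_boundary_baseline(scheme_for(2), samples=4000, seed=1)
    assert est == pytest.approx(exact, abs=0.02)


def test_baseline_averages_per_chromosome():
    # two chromosomes; chromosome 2 has a single partition and must be
    # skipped (it carries no boundary), leaving the chr1-only baseline
    scheme = PartitionSet(
        assignment=np.array([0, 0, 1, 1, 2, 2, 2, 2]),
        chroms=np.array(["chr1"] * 4 + ["chr2"] * 4),
        bin_starts=np.arange(8, dtype=np.int64) * 50_000,
        resolution=50_000,
    )
    only_chr1 = PartitionSet.from_assignment([0, 0, 1, 1])
    a = random_boundary_baseline(scheme, samples=500, seed=2)
    b = random_boundary_baseline(only_chr1, samples=500, seed=2)
    assert a == pytest.approx(b)
    with pytest.raises(UndefinedEntropyError):
        random_boundary_baseline(PartitionSet.from_assignment([0, 0, 0]))


def test_assign_hierarchical_labels_nesting():
    coarse = PartitionSet.from_assignment([0, 0, 0, 1, 1, 1])
    fine = PartitionSet.from_assignment([0, 0, 1, 2, 2, 3])
    assign_hierarchical_labels([coarse, fine])
    assert coarse.labels == ["1", "2"]
    assert fine.labels == ["1.1", "1.2", "2.1", "2.2"]


def test_partition_set_bookkeeping():
    parts = PartitionSet.from_assignment([0, 0, 1, 0], resolution=10)
    assert parts.n_partitions == 2
    assert list(parts.partition_sizes()) == [3, 1]
    assert list(parts.lengths_bp()) == [30, 10]
    # non-contiguous partition 0 reports two intervals
    assert parts.intervals(0) == [("chr?", 0, 20), ("chr?", 30, 40)]
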