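"""Soft (committor) and hard partitions, and partition-scheme comparison.

Given a hub set M, the committor q_a(i) is the probability that a probe
departing from locus i reaches hub a before any other hub: it solves the
harmonic system sum_j (p_ij - delta_ij) q_a(j) = 0 on non-hub loci with
boundary values q_a(a) = 1 and q_a(b) = 0 for the other hubs, so the
committors form a partition of unity.  Hard partitions assign each locus to
the hub with maximal committor.  Agreement between two partitioning schemes
is quantified by (rescaled) normalized mutual information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    InvalidSpecError,
    SingularityError,
    UndefinedEntropyError,
)
from .metastability import HubSet
from .msm import MarkovModel

logger = logging.getLogger(__name__)

#: linear rescale of NMI against the random-boundary baseline mean
RMI_BASELINE = 0.77

__all__ = [
    "SoftPartition",
    "PartitionSet",
    "committor_probabilities",
    "hard_assign",
    "normalized_mutual_information",
    "rescaled_mi",
    "random_boundary_baseline",
    "assign_hierarchical_labels",
    "RMI_BASELINE",
]


@dataclass
class SoftPartition:
    """Committor probabilities q (rows = loci, columns = hubs in genomic order)."""

    q: np.ndarray
    hubs: HubSet

    @property
    def n_loci(self) -> int:
        return self.q.shape[0]

    @property
    def n_partitions(self) -> int:
        return self.q.shape[1]


@dataclass
class PartitionSet:
    """Hard assignment of loci to partitions, with genomic bookkeeping.

    ``assignment[i]`` is the partition index (column of the committor matrix,
    i.e. hubs in genomic order) of active locus i.  ``chroms``/``bin_starts``
    carry the genomic coordinates of the active loci; partitions need not be
    genomically contiguous, so extents are reported as interval lists.
    """

    assignment: np.ndarray
    chroms: np.ndarray
    bin_starts: np.ndarray
    resolution: int
    labels: list[str] = field(default_factory=list)
    hubs: HubSet | None = None

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.chroms = np.asarray(self.chroms)
        self.bin_starts = np.asarray(self.bin_starts, dtype=np.int64)
        if not self.labels:
            self.labels = [str(k + 1) for k in range(self.n_partitions)]

    @classmethod
    def from_assignment(
        cls, assignment, chrom: str = "chr?", resolution: int = 50_000
    ) -> "PartitionSet":
        """Wrap a bare label vector with synthetic consecutive coordinates."""
        assignment = np.asarray(assignment, dtype=int)
        n = assignment.size
        return cls(
            assignment=assignment,
            chroms=np.full(n, chrom),
            bin_starts=np.arange(n, dtype=np.int64) * resolution,
            resolution=resolution,
        )

    @property
    def n_loci(self) -> int:
        return self.assignment.size

    @property
    def n_partitions(self) -> int:
        return int(self.assignment.max()) + 1

    def partition_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_partitions)

    def lengths_bp(self) -> np.ndarray:
        return self.partition_sizes() * self.resolution

    def intervals(self, k: int) -> list[tuple[str, int, int]]:
        """Genomic extents of partition k as (chrom, start, end) intervals."""
        out = []
        sel = np.flatnonzero(self.assignment == k)
        for i in sel:
            c, s = self.chroms[i], int(self.bin_starts[i])
            if out and out[-1][0] == c and out[-1][2] == s:
                out[-1] = (c, out[-1][1], s + self.resolution)
            else:
                out.append((c, s, s + self.resolution))
        return out

    def to_bed(self, path, level: str = ".") -> None:
        rows = []
        for k in range(self.n_partitions):
            for c, s, e in self.intervals(k):
                rows.append((c, s, e, self.labels[k], level))
        import pandas as pd

        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def committor_probabilities(model: MarkovModel, hubs: HubSet) -> SoftPartition:
    """Solve the committor system for every hub, sharing one factorization.

    Interior (non-hub) loci satisfy (I - P_II) q_a = P_I,a with boundary
    values q_a(a) = 1, q_a(b) = 0 for other hubs b.  The interior matrix is
    LU-factored once and reused across hubs.
    """
    p = model.transition
    n = model.n_states
    m = np.asarray(hubs.members, dtype=int)  # genomically sorted
    interior = np.setdiff1d(np.arange(n), m)
    a_mat = np.eye(interior.size) - p[np.ix_(interior, interior)]
    rhs = p[np.ix_(interior, m)]
    try:
        lu, piv = scipy.linalg.lu_factor(a_mat)
        q_int = scipy.linalg.lu_solve((lu, piv), rhs)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise SingularityError(f"committor system singular: {exc}", model.beta)
    if not np.all(np.isfinite(q_int)):
        raise SingularityError("non-finite committor values", model.beta)
    q = np.zeros((n, m.size))
    q[interior, :] = q_int
    q[m, np.arange(m.size)] = 1.0
    return SoftPartition(q=q, hubs=hubs)


def hard_assign(
    soft: SoftPartition,
    chroms=None,
    bin_starts=None,
    resolution: int = 50_000,
    chrom: str = "chr?",
) -> PartitionSet:
    """Assign each locus to the hub with maximal committor.

    Ties go to the hub with the lowest genomic index (the committor columns
    are in genomic hub order, and argmax returns the first maximum).
    """
    assignment = np.argmax(soft.q, axis=1)
    n = soft.n_loci
    if chroms is None:
        chroms = np.full(n, chrom)
    if bin_starts is None:
        bin_starts = np.arange(n, dtype=np.int64) * resolution
    return PartitionSet(
        assignment=assignment,
        chroms=np.asarray(chroms),
        bin_starts=np.asarray(bin_starts),
        resolution=resolution,
        hubs=soft.hubs,
    )


def _entropy(freq: np.ndarray) -> float:
    nz = freq[freq > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_mutual_information(
    p1: PartitionSet, p2: PartitionSet, variant: str = "sym"
) -> float:
    """NMI between two partitioning schemes over the same loci.

    ``variant="sym"`` (default) normalizes by (H1 + H2)/2 so that identical
    schemes score 1; ``variant="literal"`` uses 1/(H1 + H2), under which
    identical schemes score 0.5.  Invariant under partition relabeling.
    """
    if p1.n_loci != p2.n_loci:
        raise InvalidSpecError("schemes cover different numbers of loci")
    if variant not in ("sym", "literal"):
        raise InvalidSpecError(f"unknown NMI variant {variant!r}")
    n = p1.n_loci
    k1, k2 = p1.n_partitions, p2.n_partitions
    joint = np.zeros((k1, k2))
    np.add.at(joint, (p1.assignment, p2.assignment), 1.0)
    joint /= n
    nu1, nu2 = joint.sum(axis=1), joint.sum(axis=0)
    h1, h2 = _entropy(nu1), _entropy(nu2)
    if h1 == 0 or h2 == 0:
        raise UndefinedEntropyError("a scheme has a single partition (zero entropy)")
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(nu1, nu2)[nz])).sum())
    factor = 2.0 if variant == "sym" else 1.0
    return factor * mi / (h1 + h2)


def rescaled_mi(nmi: float, baseline: float = RMI_BASELINE) -> float:
    """RMI = (NMI - baseline) / (1 - baseline); not clipped."""
    return (nmi - baseline) / (1.0 - baseline)


def _random_contiguous(n_loci: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Labels of a scheme with k contiguous blocks and uniform random boundaries."""
    cuts = rng.choice(np.arange(1, n_loci), size=k - 1, replace=False) if k > 1 else []
    bounds = np.sort(np.asarray(cuts, dtype=int))
    labels = np.zeros(n_loci, dtype=int)
    labels[bounds] = 1
    return np.cumsum(labels)


def random_boundary_baseline(
    scheme: PartitionSet, samples: int = 2000, seed: int = 0
) -> float:
    """Mean NMI between pairs of random-boundary schemes shaped like ``scheme``.

    For each sample and each chromosome, two schemes are drawn with the same
    number of partitions as ``scheme`` has on that chromosome but uniformly
    random distinct internal boundaries (contiguous blocks); the NMI (default
    variant) is a per-chromosome quantity, so per-chromosome values are
    averaged over chromosomes and samples.  This is the chance-agreement
    level used to rescale NMI.
    """
    if samples < 1:
        raise InvalidSpecError("samples must be >= 1")
    if scheme.n_partitions < 2:
        raise UndefinedEntropyError("scheme has fewer than 2 partitions")
    rng = np.random.default_rng(seed)
    uniq = pd_unique_stable(scheme.chroms)
    per_chrom = []
    for c in uniq:
        sel = scheme.chroms == c
        k_c = np.unique(scheme.assignment[sel]).size
        if k_c >= 2:  # single-partition chromosomes carry no boundary to draw
            per_chrom.append((int(sel.sum()), k_c))
    if not per_chrom:
        raise UndefinedEntropyError("no chromosome with at least 2 partitions")
    total = 0.0
    for _ in range(samples):
        chrom_nmis = []
        for n_c, k_c in per_chrom:
            a = PartitionSet.from_assignment(
                _random_contiguous(n_c, k_c, rng), resolution=scheme.resolution
            )
            b = PartitionSet.from_assignment(
                _random_contiguous(n_c, k_c, rng), resolution=scheme.resolution
            )
            chrom_nmis.append(normalized_mutual_information(a, b))
        total += float(np.mean(chrom_nmis))
    return total / samples


def pd_unique_stable(values) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return np.asarray(values)[np.sort(idx)]


def assign_hierarchical_labels(levels: list[PartitionSet]) -> None:
    """Label nested partitions as "1", "1.2", "1.2.4", ... in place.

    ``levels`` is ordered coarse to fine.  At the top level, partitions are
    numbered in genomic hub order.  Each finer partition inherits the label
    of the parent it overlaps most (majority of loci) and appends its rank
    among siblings, again in genomic order.
    """
    if not levels:
        return
    top = levels[0]
    top.labels = [str(k + 1) for k in range(top.n_partitions)]
    for parent, child in zip(levels, levels[1:]):
        labels = []
        sibling_count: dict[str, int] = {}
        for k in range(child.n_partitions):
            sel = child.assignment == k
            parents = parent.assignment[sel]
            maj = int(np.bincount(parents).argmax())
            base = parent.labels[maj]
            sibling_count[base] = sibling_count.get(base, 0) + 1
            labels.append(f"{base}.{sibling_count[base]}")
        child.labels = labels
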