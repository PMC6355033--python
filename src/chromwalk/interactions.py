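"""Effective interactions between partitions and observed/expected affinity.

Two coarse-graining routes are provided.  On a single chromosome the exact
committor-weighted flux between soft partitions a, b is

    F_ab = sum_i q_a(i) pi_ib,

the portion of probe flux into hub b that drains through partition a.  At
genome scale, where committors are impractical, a mean-field block sum over
hard partitions is used instead:

    F_AB = sum_i theta_A(i) sum_j pi_ij theta_B(j).

Ranked effective interactions are classified into discrete strength layers
(scaffold, then percentile bands).  Independently of flux, the affinity
C_AB = P(A and B) / (P(A) P(B)) — the observed-over-expected contact ratio —
measures the degree of association between partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .msm import MarkovModel
from .partition import PartitionSet, SoftPartition

logger = logging.getLogger(__name__)

#: percentile breaks (percent of ranked pairs) bounding layers 1..3
DEFAULT_LAYER_PERCENTILES = (1.35, 1.5, 1.7, 2.0)

LAYER_NAMES = ("scaffold", "1", "2", "3", "below")

__all__ = [
    "EffectiveInteractionMatrix",
    "AffinityMatrix",
    "effective_flux_soft",
    "effective_flux_hard",
    "classify_layers",
    "affinity_matrix",
    "major_cluster",
    "DEFAULT_LAYER_PERCENTILES",
]


@dataclass
class EffectiveInteractionMatrix:
    """Symmetric effective-interaction matrix over partitions.

    ``raw`` keeps the unsymmetrized committor-weighted values in soft mode
    (the reported ``F`` is (raw + raw.T)/2); in hard mode raw equals F.
    """

    F: np.ndarray
    mode: str  # "soft_intra" | "hard_genome"
    raw: np.ndarray | None = None
    layer: np.ndarray | None = None
    labels: list[str] | None = None

    @property
    def n_partitions(self) -> int:
        return self.F.shape[0]


@dataclass
class AffinityMatrix:
    """Observed/expected affinity C over partitions (diagonal undefined)."""

    C: np.ndarray
    p_joint: np.ndarray
    p_marginal: np.ndarray
    labels: list[str] | None = None


def effective_flux_soft(
    soft: SoftPartition, model: MarkovModel
) -> EffectiveInteractionMatrix:
    """Committor-weighted flux between soft partitions (single chromosome).

    Column sums of the raw matrix reproduce the stationary weights of the
    hubs (partition of unity of the committors); the raw matrix is not
    exactly symmetric and is reported symmetrized.
    """
    if soft.n_loci != model.n_states:
        raise InvalidSpecError("soft partition and model state spaces differ")
    hubs = np.asarray(soft.hubs.members, dtype=int)
    raw = soft.q.T @ model.flux[:, hubs]
    asym = np.abs(raw - raw.T).max()
    logger.debug("soft effective flux: max raw asymmetry %.3e", asym)
    return EffectiveInteractionMatrix(F=(raw + raw.T) / 2.0, mode="soft_intra", raw=raw)


def effective_flux_hard(
    parts: PartitionSet, flux: np.ndarray
) -> EffectiveInteractionMatrix:
    """Mean-field block sums of the genome flux by hard partition pair.

    ``flux`` must be the symmetric probe flux normalized over ordered
    off-diagonal locus pairs of the whole state space; the result sums to the
    total flux (1) over all partition pairs including A = B.
    """
    if parts.n_loci != flux.shape[0]:
        raise InvalidSpecError("partition set and flux matrix sizes differ")
    if np.any(parts.assignment < 0):
        raise InvalidSpecError("unassigned loci present")
    k = parts.n_partitions
    theta = np.zeros((parts.n_loci, k))
    theta[np.arange(parts.n_loci), parts.assignment] = 1.0
    f = theta.T @ flux @ theta
    return EffectiveInteractionMatrix(
        F=f, mode="hard_genome", raw=f, labels=list(parts.labels)
    )


def classify_layers(
    eim: EffectiveInteractionMatrix,
    n_scaffold: int = 2000,
    layer_percentiles=DEFAULT_LAYER_PERCENTILES,
) -> np.ndarray:
    """Label unordered partition pairs by interaction-strength layer.

    Pairs are ranked by F descending (ties broken by pair index, and pairs
    tied with the last scaffold pair are all included in the scaffold).  The
    strongest ``n_scaffold`` pairs form the scaffold layer; subsequent
    percentile bands of the ranked list form layers 1..3; everything weaker
    is "below".  Stores and returns a (k, k) array of layer labels with
    "self" on the diagonal.
    """
    f = eim.F
    k = f.shape[0]
    iu, ju = np.triu_indices(k, 1)
    n_pairs = iu.size
    if n_scaffold > n_pairs:
        raise InvalidSpecError("n_scaffold exceeds the number of pairs")
    vals = f[iu, ju]
    order = np.lexsort((iu * k + ju, -vals))  # value desc, then pair index asc
    ranks = np.empty(n_pairs, dtype=int)
    ranks[order] = np.arange(n_pairs)
    cutoff_val = vals[order[n_scaffold - 1]] if n_scaffold > 0 else np.inf
    labels = np.full(n_pairs, "below", dtype=object)
    bounds = [int(np.floor(p / 100.0 * n_pairs)) for p in layer_percentiles]
    for name, lo, hi in zip(("3", "2", "1"), bounds[:-1][::-1], bounds[1:][::-1]):
        labels[(ranks >= lo) & (ranks < hi)] = name
    labels[ranks < max(n_scaffold, bounds[0])] = "scaffold"
    labels[vals >= cutoff_val] = "scaffold"  # ties at the scaffold cutoff
    layer = np.full((k, k), "self", dtype=object)
    layer[iu, ju] = labels
    layer[ju, iu] = labels
    eim.layer = layer
    return layer


def affinity_matrix(counts_cm, parts: PartitionSet) -> AffinityMatrix:
    """Observed/expected affinity between hard partitions from raw counts.

    P(A and B) is the fraction of inter-partition counts falling on the
    (ordered) pair; P(A) sums P(A and Y) over Y != A and adds to 1 over A;
    C_AB = P(A and B)/(P(A) P(B)).  Partitions with zero inter-partition
    counts get flagged (NaN) rows/columns.  Scale-invariant in the counts.
    """
    counts = np.asarray(counts_cm.counts if hasattr(counts_cm, "counts") else counts_cm)
    if parts.n_loci != counts.shape[0]:
        raise InvalidSpecError("partition set and count matrix sizes differ")
    k = parts.n_partitions
    theta = np.zeros((parts.n_loci, k))
    theta[np.arange(parts.n_loci), parts.assignment] = 1.0
    block = theta.T @ counts @ theta
    np.fill_diagonal(block, 0.0)  # A != B only
    denom = block.sum()  # ordered distinct partition pairs
    if denom <= 0:
        raise InvalidSpecError("no inter-partition counts")
    p_joint = block / denom
    p_marg = p_joint.sum(axis=1)
    flagged = p_marg <= 0
    if flagged.any():
        logger.warning("%d partitions with zero inter-partition counts", flagged.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        c = p_joint / np.outer(p_marg, p_marg)
    c[flagged, :] = np.nan
    c[:, flagged] = np.nan
    np.fill_diagonal(c, np.nan)
    return AffinityMatrix(
        C=c, p_joint=p_joint, p_marginal=p_marg, labels=list(parts.labels)
    )


def major_cluster(eim: EffectiveInteractionMatrix, layers=("scaffold", "1")) -> list[set[int]]:
    """Connected components of the graph of scaffold/layer-1 interactions.

    Returns components sorted by size descending; the first is the major
    cluster.  Requires :func:`classify_layers` to have been run.
    """
    if eim.layer is None:
        raise InvalidSpecError("run classify_layers first")
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = np.isin(eim.layer, layers)
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, set[int]] = {}
    for node, c in enumerate(comp):
        groups.setdefault(c, set()).add(node)
    return sorted(groups.values(), key=len, reverse=True)
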