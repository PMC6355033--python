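"""Metastability index, Monte-Carlo hub-set search, hierarchy detection.

A hub set M is a small set of loci acting as attractors of the random walk.
Its quality is measured by the metastability index

    rho_M = max_{i in M} max_{j in M\\{i}} Gamma_ij
            ---------------------------------------
            min_{i not in M} max_{j in M} Gamma_ij

the ratio of the largest hub-to-hub connection probability (small when hubs
sit in different basins) to the worst-case probability of hitting any hub
from outside (large when every locus drains quickly into some hub).  Low
rho_M means the hub set captures a metastable modular structure.

Optimal hub sets of every size n are found by a three-step scheme: seed the
size-2 set from the stationary distribution, refine each set by Metropolis
Monte Carlo over two move types, and grow the set one locus at a time.  Local
minima of the resulting rho(n) profile below an operational threshold mark
the levels of structural hierarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSetError, InvalidSpecError
from .msm import MarkovModel

#: Metropolis acceptance temperature for uphill Delta-rho moves (rho is O(1))
DEFAULT_MC_TEMPERATURE = 0.05

__all__ = [
    "HubSet",
    "MetastabilityProfile",
    "HierarchyLevels",
    "metastability_index",
    "seed_pair",
    "mc_optimize_hubs",
    "grow_hub_set",
    "rho_profile",
    "select_hierarchy",
    "DEFAULT_MC_TEMPERATURE",
]


@dataclass(frozen=True)
class HubSet:
    """A set of hub loci with its metastability index."""

    members: tuple[int, ...]
    rho: float
    beta: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(sorted(int(m) for m in self.members)))
        if len(set(self.members)) != len(self.members):
            raise InvalidSetError("hub set contains duplicate loci")
        if len(self.members) < 2:
            raise InvalidSetError("hub set needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MetastabilityProfile:
    """Optimal hub set found for every size n = 2..n_max."""

    by_size: dict[int, HubSet]
    beta: float | None = None
    n_max: int = 50

    @property
    def sizes(self) -> np.ndarray:
        return np.array(sorted(self.by_size), dtype=int)

    @property
    def rhos(self) -> np.ndarray:
        return np.array([self.by_size[n].rho for n in sorted(self.by_size)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.sizes,
                "rho": self.rhos,
                "hubs": [
                    ",".join(map(str, self.by_size[n].members)) for n in self.sizes
                ],
            }
        )


@dataclass
class HierarchyLevels:
    """Hub-set sizes selected as hierarchy levels, smallest first."""

    sizes: list[int]
    rho_threshold: float = 0.8
    all_minima: list[int] = field(default_factory=list)


def _validate_members(gamma: np.ndarray, members) -> np.ndarray:
    m = np.asarray(members, dtype=int)
    n_states = gamma.shape[0]
    if m.size < 2:
        raise InvalidSetError("hub set needs at least 2 members")
    if m.size >= n_states:
        raise InvalidSetError("hub set must leave at least one non-hub locus")
    if np.unique(m).size != m.size:
        raise InvalidSetError("duplicate loci in hub set")
    if m.min() < 0 or m.max() >= n_states:
        raise InvalidSetError("hub index out of range")
    return m


def metastability_index(gamma: np.ndarray, members) -> float:
    """rho_M for hub set ``members`` given the pairwise committor matrix."""
    m = _validate_members(gamma, members)
    sub = gamma[np.ix_(m, m)]
    numerator = np.where(~np.eye(m.size, dtype=bool), sub, -np.inf).max()
    outside = np.ones(gamma.shape[0], dtype=bool)
    outside[m] = False
    denominator = gamma[outside][:, m].max(axis=1).min()
    return float(numerator / denominator)


def seed_pair(model: MarkovModel, gamma: np.ndarray) -> HubSet:
    """Initial hub pair: a = argmax_i mu_i, b = argmin_i rho_{a,i}.

    Ties broken by lowest locus index (argmax/argmin return the first hit).
    """
    n = gamma.shape[0]
    if n < 3:
        raise InvalidSetError("seed pair needs at least 3 states")
    a = int(np.argmax(model.stationary))
    # rho_{a,i} for every candidate i, vectorized over i
    num = np.maximum(gamma[a, :], gamma[:, a])  # hub-to-hub term per candidate
    pair_hit = np.maximum(gamma[:, a][:, None], gamma)  # [k, i] = max(G_ka, G_ki)
    pair_hit[a, :] = np.inf  # k must lie outside {a, i}
    np.fill_diagonal(pair_hit, np.inf)
    den = pair_hit.min(axis=0)
    rho = num / den
    rho[a] = np.inf
    b = int(np.argmin(rho))
    return HubSet(members=(a, b), rho=float(rho[b]))


def mc_optimize_hubs(
    gamma: np.ndarray,
    mu: np.ndarray,
    n: int,
    init: HubSet,
    iters: int = 500,
    seed: int | np.random.SeedSequence = 0,
    t_mc: float = DEFAULT_MC_TEMPERATURE,
) -> HubSet:
    """Metropolis Monte-Carlo refinement of a size-n hub set.

    Each iteration draws one of two move types with equal probability:
    (a) replace a random hub ``a`` by its strongest committor partner
    ``argmax_i Gamma_ai``; (b) replace a random hub by a uniformly random
    non-hub locus.  Moves that would duplicate a locus are rejected and
    redrawn.  A trial set is accepted if Delta-rho <= 0, otherwise with
    probability exp(-Delta-rho / t_mc).  The best (lowest-rho) set ever
    visited — including the initial one — is returned.
    """
    if init.size != n:
        raise InvalidSetError(f"init has size {init.size}, expected {n}")
    if iters < 1:
        raise InvalidSpecError("iters must be >= 1")
    n_states = gamma.shape[0]
    if not 2 <= n < n_states:
        raise InvalidSetError("hub-set size out of range")
    rng = np.random.default_rng(seed)
    members = list(init.members)
    member_set = set(members)
    cur_rho = metastability_index(gamma, members)
    best_rho, best_members = cur_rho, tuple(members)

    for _ in range(iters):
        trial_locus = -1
        for _attempt in range(20):  # redraw on duplicate-producing moves
            pos = int(rng.integers(n))
            if rng.random() < 0.5:
                cand = int(np.argmax(gamma[members[pos]]))
            else:
                cand = int(rng.integers(n_states))
            if cand not in member_set:
                trial_locus = cand
                break
        if trial_locus < 0:
            continue
        old = members[pos]
        members[pos] = trial_locus
        trial_rho = metastability_index(gamma, members)
        delta = trial_rho - cur_rho
        if delta <= 0 or rng.random() < math.exp(-delta / t_mc):
            member_set.discard(old)
            member_set.add(trial_locus)
            cur_rho = trial_rho
            if cur_rho < best_rho:
                best_rho, best_members = cur_rho, tuple(members)
        else:
            members[pos] = old
    return HubSet(members=best_members, rho=best_rho)


def grow_hub_set(gamma: np.ndarray, hubs: HubSet) -> HubSet:
    """Extend a hub set by the non-hub locus that minimizes rho of the union.

    Evaluates rho_{M + {i}} for every non-hub i in one vectorized pass;
    ties go to the lowest locus index.
    """
    m = _validate_members(gamma, hubs.members)
    n_states = gamma.shape[0]
    if m.size + 1 >= n_states:
        raise InvalidSetError("cannot grow: no non-hub locus would remain")
    outside = np.setdiff1d(np.arange(n_states), m)
    sub = gamma[np.ix_(m, m)]
    cur_num = np.where(~np.eye(m.size, dtype=bool), sub, -np.inf).max()
    # numerator with candidate i added as a hub
    to_hubs = gamma[outside][:, m].max(axis=1)  # max_j G_ij
    from_hubs = gamma[m][:, outside].max(axis=0)  # max_a G_ai
    num = np.maximum(cur_num, np.maximum(to_hubs, from_hubs))
    # denominator: min over k outside M+{i} of max(hit_k, G_ki)
    hit = gamma[outside][:, m].max(axis=1)  # max_j in M of G_kj, k outside
    h = np.maximum(hit[:, None], gamma[np.ix_(outside, outside)])
    np.fill_diagonal(h, np.inf)  # k == i is no longer outside
    den = h.min(axis=0)
    rho = num / den
    k = int(np.argmin(rho))
    return HubSet(members=tuple(m) + (int(outside[k]),), rho=float(rho[k]))


def rho_profile(
    gamma: np.ndarray,
    model: MarkovModel,
    n_max: int = 50,
    iters: int = 500,
    seed: int = 0,
    t_mc: float = DEFAULT_MC_TEMPERATURE,
) -> MetastabilityProfile:
    """Optimized metastability profile rho(n) for n = 2..n_max.

    Size 2 starts from :func:`seed_pair`; each subsequent size starts from
    the greedy one-locus extension of the previous optimum and is refined by
    :func:`mc_optimize_hubs`.  Per-size random streams are spawned
    deterministically from ``seed``.
    """
    if n_max >= gamma.shape[0]:
        raise InvalidSpecError("n_max must be below the number of states")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_max + 1)
    mu = model.stationary
    current = seed_pair(model, gamma)
    by_size: dict[int, HubSet] = {}
    for n in range(2, n_max + 1):
        init = current if n == 2 else grow_hub_set(gamma, by_size[n - 1])
        by_size[n] = mc_optimize_hubs(
            gamma, mu, n, init, iters=iters, seed=streams[n], t_mc=t_mc
        )
    return MetastabilityProfile(by_size=by_size, beta=model.beta, n_max=n_max)


def _local_minima(sizes: np.ndarray, rhos: np.ndarray) -> list[int]:
    """Indices of strict local minima; plateaus contribute their smallest n.

    The first point counts as a minimum when it lies below the first
    differing value to its right (relevant for the trivial n = 2 level); the
    last point is never a minimum since the profile beyond it is unknown.
    """
    k = len(rhos)
    minima = []
    for i in range(k - 1):
        # previous differing value
        left = next((rhos[j] for j in range(i - 1, -1, -1) if rhos[j] != rhos[i]), None)
        right = next((rhos[j] for j in range(i + 1, k) if rhos[j] != rhos[i]), None)
        if right is None or right <= rhos[i]:
            continue
        if left is not None and left <= rhos[i]:
            continue
        if i > 0 and rhos[i - 1] == rhos[i]:
            continue  # not the first point of its plateau
        minima.append(i)
    return minima


def select_hierarchy(
    profile: MetastabilityProfile,
    rho_threshold: float = 0.8,
    min_growth: float = 2.0,
    keep_trivial: bool = False,
    skip_first: bool = False,
) -> HierarchyLevels:
    """Pick hierarchy levels from the rho(n) profile.

    Strict local minima with rho below ``rho_threshold`` qualify; the trivial
    size-2 level is dropped unless ``keep_trivial``; a greedy ascending pass
    enforces n_i >= min_growth * n_{i-1}.  ``skip_first`` drops the smallest
    qualifying size before the growth filter (the rule used for the largest
    chromosomes, where the first minimum gives partitions that are too
    coarse).  An empty result is valid, not an error.
    """
    sizes, rhos = profile.sizes, profile.rhos
    idx = _local_minima(sizes, rhos)
    qualifying = [int(sizes[i]) for i in idx if rhos[i] < rho_threshold]
    all_minima = list(qualifying)
    if not keep_trivial:
        qualifying = [s for s in qualifying if s != 2]
    if skip_first and qualifying:
        qualifying = qualifying[1:]
    levels: list[int] = []
    for s in qualifying:
        if not levels or s >= min_growth * levels[-1]:
            levels.append(s)
    return HierarchyLevels(sizes=levels, rho_threshold=rho_threshold, all_minima=all_minima)
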