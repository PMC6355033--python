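"""Hierarchical toy chromosome: a 1D energy profile with nested basins.

The toy system is a linear chain of ``n_loci`` loci carrying an intrinsic
energy ``E_i`` shaped as nested wells: the top level splits the chain into a
few basins separated by the tallest barriers, each basin is recursively
subdivided by lower barriers.  Well floors are staggered by seeded random
offsets (up to the smallest barrier height), as in a hand-drawn hierarchical
landscape: a perfectly symmetric profile with all wells equally deep would
make hub sets of intermediate size artificially competitive (many covers of
the degenerate wells score the same low metastability index), an artifact
the depth disorder removes.  Contacts between loci follow a power law in
genomic distance, so the pairwise contact energy is

    E_ij = (E_i + E_j)/2 - alpha * ln(d0 / d_ij),      d_ij = |i - j| * d0,

and the associated Markov State Model has flux pi_ij ~ exp(-beta * E_ij).
Because the basin structure is known by construction, the toy landscape is
the ground-truth fixture for the metastability and partitioning machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import numpy as np

from .errors import InvalidSpecError
from .msm import EnergyLandscape, MarkovModel, build_msm

__all__ = [
    "ToyLandscapeSpec",
    "EnergyProfile1D",
    "generate_hierarchical_profile",
    "toy_pair_energy",
    "toy_msm",
    "write_profile_tsv",
]


@dataclass(frozen=True)
class ToyLandscapeSpec:
    """Parameters of the hierarchical toy chromosome.

    Defaults reproduce the three-level reference landscape: 500 loci,
    branching 2/3/3 (18 leaf wells), barrier heights 2.0/1.25/0.5 in
    dimensionless energy units, contact exponent alpha = 1.5.
    """

    n_loci: int = 500
    branching: tuple[int, ...] = (2, 3, 3)
    barrier_heights: tuple[float, ...] = (2.0, 1.25, 0.5)
    well_shape: str = "cosine"
    alpha: float = 1.5
    d0: float = 1.0
    seed: int = 0  # seeds the random stagger of the well-floor energies

    def __post_init__(self):
        object.__setattr__(self, "branching", tuple(int(b) for b in self.branching))
        object.__setattr__(
            self, "barrier_heights", tuple(float(h) for h in self.barrier_heights)
        )
        if len(self.branching) != len(self.barrier_heights):
            raise InvalidSpecError("branching and barrier_heights must have equal length")
        if any(b < 2 for b in self.branching):
            raise InvalidSpecError("every branching factor must be >= 2")
        if any(
            h1 <= h2 for h1, h2 in zip(self.barrier_heights, self.barrier_heights[1:])
        ):
            raise InvalidSpecError("barrier heights must strictly decrease with level")
        if self.n_loci < self.n_leaf_wells:
            raise InvalidSpecError("n_loci too small to host all leaf wells")
        if self.alpha < 0:
            raise InvalidSpecError("contact exponent alpha must be non-negative")
        if self.well_shape not in ("cosine", "parabolic"):
            raise InvalidSpecError(f"unknown well shape {self.well_shape!r}")

    @property
    def n_leaf_wells(self) -> int:
        return prod(self.branching)

    @property
    def n_levels(self) -> int:
        return len(self.branching)


@dataclass
class EnergyProfile1D:
    """Locus energies plus per-level ground-truth basin labels."""

    energies: np.ndarray  # (n_loci,)
    basin_labels: np.ndarray  # (n_levels, n_loci), int
    spec: ToyLandscapeSpec = field(repr=False, default=None)

    @property
    def n_loci(self) -> int:
        return self.energies.size

    def labels_at_level(self, level: int) -> np.ndarray:
        """Ground-truth basin index per locus at ``level`` (1-based)."""
        return self.basin_labels[level - 1]


def _leaf_barrier_heights(spec: ToyLandscapeSpec) -> np.ndarray:
    """Barrier height between consecutive leaf wells w and w+1.

    The height is set by the highest hierarchy level at which the two wells
    belong to different basins.
    """
    n_leaves = spec.n_leaf_wells
    # leaves per basin at each level, e.g. branching (2,3,3) -> (9, 3, 1)
    group = np.cumprod((1,) + spec.branching[::-1][:-1])[::-1]
    heights = np.empty(n_leaves - 1)
    for w in range(n_leaves - 1):
        for level in range(spec.n_levels):
            per = n_leaves // prod(spec.branching[: level + 1])
            if w // per != (w + 1) // per:
                heights[w] = spec.barrier_heights[level]
                break
    del group
    return heights


def generate_hierarchical_profile(spec: ToyLandscapeSpec) -> EnergyProfile1D:
    """Build the 1D hierarchical energy profile and its ground-truth labels.

    Loci are assigned to leaf wells in contiguous, equal-length blocks
    (remainder loci go to the last well).  Well floors phi_w are staggered by
    seeded uniform offsets in [0, h_min), with h_min the smallest barrier
    height, so that wells are unequally deep without ever overriding the
    level structure.  The barrier top between wells w and w+1 sits at

        max(phi_w, phi_{w+1}) + h_boundary,

    i.e. the barrier measured from the shallower adjacent well is exactly the
    height of the hierarchy level separating the wells.  Within a well the
    energy interpolates from the wall top down to the floor,

        E(t) = phi + (top_wall(t) - phi) * (1 + cos(2*pi*t)) / 2,  t in [0, 1),

    using the left wall for t < 1/2 and the right one otherwise ("cosine"
    shape; "parabolic" uses (2t - 1)^2 in place of the cosine factor).  The
    first locus of every well sits exactly on the barrier top and the central
    locus is pinned exactly to the floor, so the profile has one strict local
    maximum per internal barrier (n_leaf_wells - 1), each with prominence at
    least the height of its hierarchy level.  The outermost walls use the
    tallest barrier height (confining ends).
    """
    n_leaves = spec.n_leaf_wells
    internal = _leaf_barrier_heights(spec)
    rng = np.random.default_rng(spec.seed)
    floors = rng.uniform(0.0, spec.barrier_heights[-1], n_leaves)
    # absolute barrier-top energy on each side of every leaf well
    tops = np.maximum(floors[:-1], floors[1:]) + internal
    top_left = np.concatenate([[floors[0] + spec.barrier_heights[0]], tops])
    top_right = np.concatenate([tops, [floors[-1] + spec.barrier_heights[0]]])

    base = spec.n_loci // n_leaves
    sizes = np.full(n_leaves, base, dtype=int)
    sizes[-1] += spec.n_loci - base * n_leaves
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    energies = np.empty(spec.n_loci)
    leaf_labels = np.empty(spec.n_loci, dtype=int)
    for w in range(n_leaves):
        s, n = starts[w], sizes[w]
        t = np.arange(n) / n
        amp = np.where(t < 0.5, top_left[w], top_right[w]) - floors[w]
        if spec.well_shape == "cosine":
            shape = (1.0 + np.cos(2.0 * np.pi * t)) / 2.0
        else:  # parabolic
            shape = (2.0 * t - 1.0) ** 2
        well = floors[w] + amp * shape
        well[np.argmin(well)] = floors[w]  # floor attained exactly on the grid
        energies[s : s + n] = well
        leaf_labels[s : s + n] = w

    labels = np.empty((spec.n_levels, spec.n_loci), dtype=int)
    for level in range(spec.n_levels):
        per = n_leaves // prod(spec.branching[: level + 1])
        labels[level] = leaf_labels // per
    return EnergyProfile1D(energies=energies, basin_labels=labels, spec=spec)


def toy_pair_energy(
    profile: EnergyProfile1D, alpha: float | None = None, d0: float | None = None
) -> np.ndarray:
    """Pairwise contact energy E_ij = (E_i+E_j)/2 - alpha*ln(d0/d_ij).

    The diagonal is left at 0 but is excluded from any downstream MSM.
    """
    if alpha is None:
        alpha = profile.spec.alpha if profile.spec else 1.5
    if d0 is None:
        d0 = profile.spec.d0 if profile.spec else 1.0
    if alpha < 0:
        raise InvalidSpecError("alpha must be non-negative")
    e = profile.energies
    n = e.size
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float) * d0
    with np.errstate(divide="ignore"):
        dist_term = -alpha * np.log(np.where(d > 0, d0 / d, 1.0))
    e_pair = (e[:, None] + e[None, :]) / 2.0 + dist_term
    np.fill_diagonal(e_pair, 0.0)
    return e_pair


def toy_msm(
    profile: EnergyProfile1D,
    beta: float,
    alpha: float | None = None,
    d0: float | None = None,
) -> MarkovModel:
    """MSM of a probe on the toy contact-energy landscape at inverse temperature beta.

    Flux pi_ij ~ exp(-beta * E_ij) over ordered off-diagonal pairs; the
    transition matrix is row-stochastic with zero diagonal and satisfies
    detailed balance by construction.
    """
    if profile.n_loci < 2:
        raise InvalidSpecError("toy MSM needs at least 2 loci")
    e_pair = toy_pair_energy(profile, alpha=alpha, d0=d0)
    infinite = np.eye(profile.n_loci, dtype=bool)
    landscape = EnergyLandscape(
        e_pair=e_pair, e_locus=profile.energies.copy(), infinite_pairs=infinite
    )
    return build_msm(landscape, beta)


def write_profile_tsv(profile: EnergyProfile1D, path) -> None:
    """Export (locus_index, E_i, level labels...) as TSV."""
    import pandas as pd

    cols = {"locus_index": np.arange(profile.n_loci), "E": profile.energies}
    for lvl in range(profile.basin_labels.shape[0]):
        cols[f"level{lvl + 1}_label"] = profile.basin_labels[lvl]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
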