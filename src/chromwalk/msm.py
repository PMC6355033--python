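"""Boltzmann-flux Markov State Model on a contact-energy landscape.

Contacts between genomic loci define a pairwise pseudo-energy
``E_ij = -ln f_ij``; a random walk ("probe") on the loci is modelled by the
Maxwell-Boltzmann flux

    pi_ij(beta) = exp(-beta * E_ij) / Z(beta),

with Z summed over ordered off-diagonal pairs, stationary weights
``mu_i = sum_j pi_ij`` and transition matrix ``p_ij = pi_ij / mu_i``.  The
chain is reversible by construction (``mu_i p_ij = mu_j p_ji``).  Kinetic
quantities derived here:

* mean first-passage time (MFPT) tau_ij: expected number of steps from i to j,
* mean recurrence time (MRT) tau_i = 1/mu_i (Kac's formula),
* pairwise committor Gamma_ij = tau_i / (tau_ij + tau_ji): probability that a
  probe leaving i hits j before returning to i.

Raising beta (annealing) exponentially amplifies energy differences so that
only the strongest contacts carry flux, exposing the separation of kinetic
time scales used by the metastability analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    ConnectivityError,
    InvalidSpecError,
    SelectionError,
    SingularityError,
)

logger = logging.getLogger(__name__)

#: relative residual above which an MFPT solve is declared singular
MFPT_RESIDUAL_TOL = 1e-6

__all__ = [
    "EnergyLandscape",
    "MarkovModel",
    "KineticMatrices",
    "pair_energies",
    "build_msm",
    "mean_first_passage",
    "mean_recurrence",
    "pair_committor_matrix",
    "kinetic_matrices",
    "select_beta",
]


@dataclass
class EnergyLandscape:
    """Pairwise and per-locus contact energies in dimensionless (beta=1) units.

    ``infinite_pairs`` marks pairs with zero observed counts (flux exactly 0);
    the diagonal is always treated as infinite (self-contacts are excluded
    from the MSM).
    """

    e_pair: np.ndarray
    e_locus: np.ndarray
    infinite_pairs: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.e_locus.size


@dataclass
class MarkovModel:
    """Reversible MSM at inverse temperature ``beta``.

    flux: symmetric pi_ij, summing to 1 over ordered off-diagonal pairs;
    stationary: mu_i = sum_j pi_ij (sums to 1);
    transition: row-stochastic p_ij = pi_ij / mu_i with zero diagonal.
    """

    beta: float
    flux: np.ndarray
    stationary: np.ndarray
    transition: np.ndarray

    @property
    def n_states(self) -> int:
        return self.stationary.size


@dataclass
class KineticMatrices:
    """MFPT matrix (steps, diagonal 0), MRT vector and committor Gamma."""

    mfpt: np.ndarray
    mrt: np.ndarray
    gamma: np.ndarray


def pair_energies(cm) -> EnergyLandscape:
    """Contact energies E_ij = -ln f_ij and E_i = -ln f_i from a contact matrix.

    ``cm`` is a :class:`~chromwalk.hic.ContactMatrix` whose inactive loci have
    been removed (every row sum positive).  Zero-count pairs are marked
    infinite and carry no flux downstream.
    """
    counts = np.asarray(cm.counts, dtype=float)
    row_tot = counts.sum(axis=1)
    if np.any(row_tot <= 0):
        raise InvalidSpecError("contact matrix has zero-coverage loci; mask them first")
    infinite = counts <= 0
    np.fill_diagonal(infinite, True)
    with np.errstate(divide="ignore"):
        e_pair = -np.log(np.where(infinite, 1.0, counts))
    e_pair[infinite] = np.inf
    np.fill_diagonal(e_pair, np.inf)
    e_locus = -np.log(row_tot)
    return EnergyLandscape(e_pair=e_pair, e_locus=e_locus, infinite_pairs=infinite)


def build_msm(landscape: EnergyLandscape, beta: float) -> MarkovModel:
    """Construct the Boltzmann-flux MSM at inverse temperature ``beta``.

    Weights are computed in log-space with a max shift so that high beta does
    not underflow the dominant contacts.  Raises
    :class:`~chromwalk.errors.ConnectivityError` if the positive-flux graph is
    disconnected (MFPTs would diverge).
    """
    if beta <= 0:
        raise InvalidSpecError("beta must be positive")
    n = landscape.n_loci
    if n < 2:
        raise InvalidSpecError("MSM needs at least 2 loci")
    logw = -beta * landscape.e_pair
    logw[landscape.infinite_pairs] = -np.inf
    np.fill_diagonal(logw, -np.inf)
    shift = logw.max()
    if not np.isfinite(shift):
        raise ConnectivityError("no finite pair energies")
    w = np.exp(logw - shift)
    z = w.sum()
    flux = w / z
    mu = flux.sum(axis=1)
    if np.any(mu <= 0):
        raise ConnectivityError("locus with zero total flux at this beta")
    n_comp, _ = connected_components(csr_matrix(flux > 0), directed=False)
    if n_comp > 1:
        raise ConnectivityError(f"flux graph splits into {n_comp} components")
    p = flux / mu[:, None]
    return MarkovModel(beta=beta, flux=flux, stationary=mu, transition=p)


def mean_first_passage(model: MarkovModel) -> np.ndarray:
    """All-pairs MFPT of the chain, in discrete steps (diagonal set to 0).

    For each target j the first-step system
    ``tau_ij = 1 + sum_{k != j} p_ik tau_kj`` (i != j) is solved by a dense
    LU factorization of I - P with row and column j removed.  The LU solve
    is backward stable, so the residual of the first-step equations stays at
    machine level even for stiff (high-beta) chains; a column whose relative
    residual exceeds ``MFPT_RESIDUAL_TOL``, or that yields non-finite or
    non-positive times, raises
    :class:`~chromwalk.errors.SingularityError` carrying beta.
    """
    p = model.transition
    n = model.n_states
    a_full = np.eye(n) - p
    tau = np.zeros((n, n))
    keep = np.ones(n, dtype=bool)
    ones = np.ones(n - 1)
    for j in range(n):
        keep[j] = False
        a_sub = a_full[np.ix_(keep, keep)]
        try:
            col = np.linalg.solve(a_sub, ones)
        except np.linalg.LinAlgError as exc:
            raise SingularityError(f"MFPT solve failed for target {j}: {exc}", model.beta)
        if not np.all(np.isfinite(col)) or np.any(col <= 0):
            raise SingularityError("non-finite or non-positive MFPT", model.beta)
        rel = np.abs(ones - a_sub @ col).max() / max(col.max(), 1.0)
        if rel > MFPT_RESIDUAL_TOL:
            raise SingularityError(
                f"MFPT residual {rel:.2e} above {MFPT_RESIDUAL_TOL:.0e} "
                f"for target {j}",
                model.beta,
            )
        tau[keep, j] = col
        keep[j] = True
    return tau


def mean_recurrence(model: MarkovModel, mfpt: np.ndarray) -> np.ndarray:
    """MRT tau_i = 1 + sum_{k != i} p_ik tau_ki (equals 1/mu_i by Kac)."""
    return 1.0 + np.einsum("ik,ki->i", model.transition, mfpt)


def pair_committor_matrix(mfpt: np.ndarray, mrt: np.ndarray) -> np.ndarray:
    """Pairwise committor Gamma_ij = tau_i / (tau_ij + tau_ji), in (0, 1].

    Gamma_ij is the probability that a probe departing from i hits j before
    returning to i.  Not symmetric in general.  Diagonal set to 0.
    """
    denom = mfpt + mfpt.T
    np.fill_diagonal(denom, 1.0)  # guard; diagonal zeroed below
    gamma = mrt[:, None] / denom
    np.fill_diagonal(gamma, 0.0)
    return gamma


def kinetic_matrices(model: MarkovModel) -> KineticMatrices:
    """Convenience: MFPT, MRT and committor of a model in one call."""
    mfpt = mean_first_passage(model)
    mrt = mean_recurrence(model, mfpt)
    return KineticMatrices(mfpt=mfpt, mrt=mrt, gamma=pair_committor_matrix(mfpt, mrt))


def select_beta(landscape: EnergyLandscape, candidates) -> int:
    """Largest annealing parameter for which the MFPT computation is stable.

    Scans ``candidates`` from the largest down; the first value for which the
    MSM builds, the flux graph is connected and the MFPT solve passes the
    residual/positivity screen is returned.  Rejected values are logged.
    """
    cands = sorted(candidates)
    if not cands:
        raise SelectionError("empty candidate list")
    rejected = []
    for beta in reversed(cands):
        try:
            model = build_msm(landscape, beta)
            mean_first_passage(model)
        except (ConnectivityError, SingularityError) as exc:
            rejected.append((beta, str(exc)))
            logger.info("beta=%s rejected: %s", beta, exc)
            continue
        if rejected:
            logger.info("selected beta=%s (rejected: %s)", beta, rejected)
        return beta
    raise SelectionError(f"no candidate beta passed the stability screen: {rejected}")
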