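"""Shared test utilities: small chains, synthetic genome schemes, fidelity."""

from __future__ import annotations

import numpy as np

from chromwalk.msm import MarkovModel
from chromwalk.partition import PartitionSet

#: hg19 chromosome lengths (bp), chr1..chr22 + chrX
HG19_LENGTHS = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
}


def chain_from_flux(w: np.ndarray) -> MarkovModel:
    """Reversible MSM from an arbitrary positive symmetric weight matrix."""
    w = (np.asarray(w, dtype=float) + np.asarray(w, dtype=float).T) / 2.0
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    flux = w / w.sum()
    mu = flux.sum(axis=1)
    return MarkovModel(
        beta=1.0, flux=flux, stationary=mu, transition=flux / mu[:, None]
    )


def metastable_chain(
    n_states: int, rng: np.random.Generator, n_blocks: int = 2, eps: float = 0.01
) -> MarkovModel:
    """Block-structured chain: strong intra-block flux, weak inter-block flux."""
    labels = np.sort(rng.integers(0, n_blocks, n_states))
    w = np.where(labels[:, None] == labels[None, :], 1.0, eps)
    return chain_from_flux(w * rng.uniform(0.5, 1.5, (n_states, n_states)))


def genome_scheme_539(resolution: int = 50_000) -> PartitionSet:
    """Synthetic genome-wide scheme: 539 partitions over hg19 at 50 kbp.

    Partitions are allocated to chromosomes proportionally to length
    (largest-remainder rounding) and laid out as equal contiguous blocks,
    mimicking a genome-wide structural-unit annotation with a ~5.7 Mbp mean
    partition size.
    """
    chroms = list(HG19_LENGTHS)
    lengths = np.array([HG19_LENGTHS[c] for c in chroms], dtype=float)
    quota = 539 * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    remainder = 539 - alloc.sum()
    alloc[np.argsort(quota - np.floor(quota))[::-1][:remainder]] += 1

    chrom_arr, start_arr, assign_arr = [], [], []
    offset = 0
    for c, k_c in zip(chroms, alloc):
        n_c = HG19_LENGTHS[c] // resolution
        chrom_arr.append(np.full(n_c, c))
        start_arr.append(np.arange(n_c, dtype=np.int64) * resolution)
        assign_arr.append((np.arange(n_c) * k_c) // n_c + offset)
        offset += k_c
    return PartitionSet(
        assignment=np.concatenate(assign_arr),
        chroms=np.concatenate(chrom_arr),
        bin_starts=np.concatenate(start_arr),
        resolution=resolution,
    )


def majority_fidelity(assignment: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of loci whose partition's majority ground-truth basin matches.

    Each partition is mapped to the ground-truth basin holding the majority
    of its loci; fidelity is the fraction of loci whose own basin equals
    their partition's majority basin.
    """
    assignment = np.asarray(assignment)
    truth = np.asarray(truth)
    correct = 0
    for k in np.unique(assignment):
        basins = truth[assignment == k]
        correct += int(np.bincount(basins).max())
    return correct / truth.size


def simulate_mfpt(
    model: MarkovModel,
    src: int,
    dst: int,
    n_walkers: int,
    rng: np.random.Generator,
    max_steps: int = 100_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the MFPT src -> dst."""
    cum = np.cumsum(model.transition, axis=1)
    pos = np.full(n_walkers, src)
    steps = np.zeros(n_walkers)
    alive = np.ones(n_walkers, dtype=bool)
    for _ in range(max_steps):
        if not alive.any():
            break
        u = rng.random(int(alive.sum()))
        pos[alive] = (u[:, None] < cum[pos[alive]]).argmax(axis=1)
        steps[alive] += 1
        alive[alive] = pos[alive] != dst
    assert not alive.any(), "simulation budget exhausted"
    return float(steps.mean()), float(steps.std(ddof=1) / np.sqrt(n_walkers))
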