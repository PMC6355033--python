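"""Binned Hi-C contact matrices: triplet-text I/O, smoothing, locus masks.

Input is the sparse triplet dialect used by GEO GSE63525 raw-observed dumps:
one chromosome per file, lines ``start_i<TAB>start_j<TAB>count`` with bin
start coordinates in bp (0-based, half-open bins of width ``resolution``).
Raw counts are the expected input; preprocessing is a single isotropic 2D
Gaussian convolution (default sigma = 200 kbp truncated at 4 sigma) that
damps sampling noise before the pseudo-energies are taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import EmptyInputError, FormatError, InvalidSpecError

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "LocusMask",
    "read_contacts",
    "write_contacts",
    "gaussian_smooth",
    "mask_inactive_loci",
    "from_dense",
]


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact counts for one chromosome.

    ``bin_starts`` maps matrix index -> genomic bin start (bp).  After
    smoothing the counts are real-valued.
    """

    counts: np.ndarray
    chrom: str
    resolution: int
    bin_starts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_starts = np.asarray(self.bin_starts, dtype=np.int64)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise InvalidSpecError("counts must be square")
        if self.bin_starts.size != n:
            raise InvalidSpecError("bin_starts length must match matrix size")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_end(self, i: int) -> int:
        return int(self.bin_starts[i]) + self.resolution


@dataclass
class LocusMask:
    """Which genomic bins survive masking, and how to map back.

    ``active`` is indexed by original bin; ``index_map[k]`` is the original
    bin index of reduced-state k.
    """

    active: np.ndarray
    index_map: np.ndarray = field(init=False)

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        self.index_map = np.flatnonzero(self.active)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def expand(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a reduced-space vector back onto all original bins."""
        out = np.full(self.active.size, fill, dtype=float)
        out[self.index_map] = values
        return out


def read_contacts(path, resolution: int, chrom: str = "chr?") -> ContactMatrix:
    """Parse a triplet-text contact dump into a dense symmetric matrix.

    Bin index = start // resolution; coordinates must be exact multiples of
    the resolution and counts non-negative.  Duplicate pairs within a file
    are summed.  Diagonal entries are stored (they are excluded from the MSM
    later, not at parse time).
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["i", "j", "count"], comment="#"
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no contact records in {path}")
    if df.empty:
        raise EmptyInputError(f"no contact records in {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise FormatError(f"malformed triplet line in {path}")
    starts = df[["i", "j"]].to_numpy()
    if np.any(starts % resolution != 0) or np.any(starts < 0):
        raise FormatError(f"coordinate not a non-negative multiple of {resolution} bp")
    counts = df["count"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise FormatError("negative contact count")
    bi = starts[:, 0] // resolution
    bj = starts[:, 1] // resolution
    n = int(max(bi.max(), bj.max())) + 1
    mat = np.zeros((n, n))
    np.add.at(mat, (bi, bj), counts)
    np.add.at(mat, (bj, bi), counts)
    # both additions hit the diagonal; halve it back
    diag = np.einsum("ii->i", mat)
    diag /= 2.0
    if not np.allclose(mat[~np.isnan(mat)], mat.T[~np.isnan(mat)]):
        raise FormatError("contact matrix failed symmetry check")
    bin_starts = np.arange(n, dtype=np.int64) * resolution
    return ContactMatrix(counts=mat, chrom=chrom, resolution=resolution, bin_starts=bin_starts)


def write_contacts(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (including diagonal) back as triplet text."""
    iu, ju = np.nonzero(np.triu(cm.counts) != 0)
    df = pd.DataFrame(
        {
            "i": cm.bin_starts[iu],
            "j": cm.bin_starts[ju],
            "count": cm.counts[iu, ju],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def from_dense(
    counts: np.ndarray, chrom: str = "chr?", resolution: int = 50_000
) -> ContactMatrix:
    """Wrap a dense symmetric array as a ContactMatrix with synthetic coordinates."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    return ContactMatrix(
        counts=counts,
        chrom=chrom,
        resolution=resolution,
        bin_starts=np.arange(n, dtype=np.int64) * resolution,
    )


def gaussian_smooth(
    cm: ContactMatrix, sigma_bp: float = 200_000, truncate_sigmas: float = 4.0
) -> ContactMatrix:
    """Isotropic 2D Gaussian convolution of the counts.

    sigma in bins = sigma_bp / resolution; the kernel is truncated at
    ``truncate_sigmas`` and applied with zero padding (plain truncation, no
    boundary renormalization).  ``sigma_bp = 0`` returns the input unchanged.
    """
    if sigma_bp < 0:
        raise InvalidSpecError("sigma must be non-negative")
    if sigma_bp == 0:
        smoothed = cm.counts.copy()
    else:
        sigma_bins = sigma_bp / cm.resolution
        smoothed = gaussian_filter(
            cm.counts, sigma=sigma_bins, truncate=truncate_sigmas, mode="constant"
        )
        smoothed = (smoothed + smoothed.T) / 2.0  # enforce exact symmetry
    return ContactMatrix(
        counts=smoothed,
        chrom=cm.chrom,
        resolution=cm.resolution,
        bin_starts=cm.bin_starts.copy(),
    )


def mask_inactive_loci(cm: ContactMatrix) -> tuple[ContactMatrix, LocusMask]:
    """Drop loci with zero total contacts (centromeres, unmappable bins).

    Such rows make the pseudo-energies and the MSM singular.  Returns the
    reduced matrix plus the mask for mapping results back to genomic bins.
    """
    active = cm.counts.sum(axis=1) > 0
    if not active.any():
        raise EmptyInputError("all loci are inactive")
    n_dropped = int((~active).sum())
    if n_dropped:
        logger.info("masking %d inactive loci of %d", n_dropped, cm.n_bins)
    mask = LocusMask(active=active)
    reduced = ContactMatrix(
        counts=cm.counts[np.ix_(active, active)],
        chrom=cm.chrom,
        resolution=cm.resolution,
        bin_starts=cm.bin_starts[active],
    )
    return reduced, mask
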