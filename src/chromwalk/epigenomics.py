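"""Epigenomic overlays on partitions: densities, Z-scores, chromatin classes.

Signal tracks (bedGraph) are aggregated to a length-weighted mean density
per partition; densities are Z-scored across partitions with weights given
by partition length, so that structural units of different sizes are
comparable.  Giemsa cytoband annotations classify partitions as euchromatic
(EC: mostly gneg/gpos25), heterochromatic (HC: mostly gpos50/75/100) or
mixed.  Finally, the enrichment of a factor on a pair of partitions
(product of densities) is regressed on the effective interaction strength
in log-log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoordinateError, InsufficientDataError, InvalidSpecError
from .interactions import EffectiveInteractionMatrix
from .partition import PartitionSet

logger = logging.getLogger(__name__)

EC_STAINS = ("gneg", "gpos25")
HC_STAINS = ("gpos50", "gpos75", "gpos100")

__all__ = [
    "FactorDensityTable",
    "ChromatinClassTable",
    "read_bedgraph",
    "read_cytoband",
    "partition_signal_density",
    "zscore_densities",
    "classify_ec_hc",
    "enrichment_correlation",
]


@dataclass
class FactorDensityTable:
    """Per-partition signal densities and their length-weighted Z-scores."""

    density: pd.DataFrame  # rows = partitions, columns = factors
    weights: np.ndarray  # partition lengths in bp
    zscore: pd.DataFrame | None = None


@dataclass
class ChromatinClassTable:
    """Stain-class composition and EC/HC/mixed label per partition."""

    fractions: pd.DataFrame  # columns = stain classes (+ "other")
    classes: pd.Series  # "EC" | "HC" | "mixed"


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def read_cytoband(path) -> pd.DataFrame:
    """Read a UCSC cytoBand.txt file (chrom, start, end, name, gieStain)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "gieStain"],
    )


def _interval_overlap_sum(
    track: pd.DataFrame, chrom: str, start: int, end: int, weight_col: str | None
) -> tuple[float, float]:
    """(sum of value*overlap_bp, overlapped bp) of a track with [start, end)."""
    sub = track[track["chrom"] == chrom]
    if sub.empty:
        return 0.0, 0.0
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    ov = np.clip(e - s, 0, None).astype(float)
    if weight_col is None:
        return float(ov.sum()), float(ov.sum())
    return float((ov * sub[weight_col].to_numpy()).sum()), float(ov.sum())


def partition_signal_density(track: pd.DataFrame, parts: PartitionSet) -> np.ndarray:
    """Length-weighted mean signal per partition; uncovered bases count 0.

    The track must share the assembly/chromosome naming of the partitions;
    a non-empty track with no chromosome in common raises CoordinateError.
    """
    part_chroms = set(np.unique(parts.chroms))
    if len(track) and not part_chroms & set(track["chrom"].unique()):
        raise CoordinateError(
            "track chromosomes do not match partition chromosomes"
        )
    dens = np.zeros(parts.n_partitions)
    for k in range(parts.n_partitions):
        total_bp = 0.0
        weighted = 0.0
        for chrom, start, end in parts.intervals(k):
            wsum, _ = _interval_overlap_sum(track, chrom, start, end, "value")
            weighted += wsum
            total_bp += end - start
        dens[k] = weighted / total_bp if total_bp > 0 else 0.0
    return dens


def zscore_densities(table: FactorDensityTable) -> pd.DataFrame:
    """Weighted Z-scores per factor: Z = (x - mu_w) / sigma_w.

    mu_w and sigma_w are the partition-length-weighted mean and standard
    deviation of the factor density across partitions.  A factor with zero
    weighted variance gets a flagged (all-NaN) column.
    """
    if len(table.density) < 2:
        raise InvalidSpecError("Z-scores need at least 2 partitions")
    w = np.asarray(table.weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise InvalidSpecError("partition weights must be non-negative, not all zero")
    z = {}
    for col in table.density.columns:
        x = table.density[col].to_numpy(dtype=float)
        mu = np.average(x, weights=w)
        sigma = np.sqrt(np.average((x - mu) ** 2, weights=w))
        if sigma == 0:
            logger.warning("factor %s has zero weighted variance; Z undefined", col)
            z[col] = np.full(x.size, np.nan)
        else:
            z[col] = (x - mu) / sigma
    table.zscore = pd.DataFrame(z, index=table.density.index)
    return table.zscore


def classify_ec_hc(
    bands: pd.DataFrame, parts: PartitionSet, threshold: float = 0.8
) -> ChromatinClassTable:
    """EC/HC/mixed labels from Giemsa stain composition.

    A partition is EC when more than ``threshold`` of its length overlaps
    gneg/gpos25 bands, HC when more than ``threshold`` overlaps
    gpos50/75/100; acen/gvar/stalk and uncovered bases count toward neither
    (grouped as "other").  A partition with no band overlap is "mixed" with
    a warning.
    """
    stains = list(EC_STAINS) + list(HC_STAINS)
    rows = []
    labels = []
    for k in range(parts.n_partitions):
        length = 0.0
        per_stain = dict.fromkeys(stains, 0.0)
        for chrom, start, end in parts.intervals(k):
            length += end - start
            for stain in stains:
                sub = bands[bands["gieStain"] == stain]
                wsum, _ = _interval_overlap_sum(sub, chrom, start, end, None)
                per_stain[stain] += wsum
        fracs = {s: per_stain[s] / length for s in stains}
        covered = sum(fracs.values())
        fracs["other"] = 1.0 - covered
        rows.append(fracs)
        if covered == 0:
            logger.warning("partition %s has zero cytoband overlap", parts.labels[k])
            labels.append("mixed")
        elif sum(fracs[s] for s in EC_STAINS) > threshold:
            labels.append("EC")
        elif sum(fracs[s] for s in HC_STAINS) > threshold:
            labels.append("HC")
        else:
            labels.append("mixed")
    return ChromatinClassTable(
        fractions=pd.DataFrame(rows, index=parts.labels),
        classes=pd.Series(labels, index=parts.labels),
    )


def enrichment_correlation(
    eim: EffectiveInteractionMatrix,
    table: FactorDensityTable,
    classes: ChromatinClassTable,
    pair_class: str,
    factor: str | None = None,
):
    """Log-log regression of factor-density products on effective interaction.

    Over unordered partition pairs whose chromatin classes match
    ``pair_class`` ("EC-EC", "HC-HC" or "EC-HC") and whose effective
    interaction and density product are both positive, regress
    ln(density_A * density_B) on ln(F_AB).  Pairs with zero density product
    are dropped (and counted in the log).  Returns a DataFrame with slope,
    Pearson r and two-sided p per factor.
    """
    want = tuple(sorted(pair_class.split("-")))
    if len(want) != 2 or any(c not in ("EC", "HC") for c in want):
        raise InvalidSpecError(f"unknown pair class {pair_class!r}")
    cls = classes.classes.to_numpy()
    k = eim.n_partitions
    iu, ju = np.triu_indices(k, 1)
    match = np.array(
        [tuple(sorted((cls[i], cls[j]))) == want for i, j in zip(iu, ju)]
    )
    factors = [factor] if factor else list(table.density.columns)
    out = []
    for f in factors:
        d = table.density[f].to_numpy(dtype=float)
        prod = d[iu] * d[ju]
        fvals = eim.F[iu, ju]
        keep = match & (fvals > 0) & (prod > 0)
        dropped = int((match & (fvals > 0) & (prod <= 0)).sum())
        if dropped:
            logger.info("factor %s: dropped %d zero-product pairs", f, dropped)
        if keep.sum() < 3:
            raise InsufficientDataError(
                f"only {int(keep.sum())} qualifying pairs for factor {f}"
            )
        x, y = np.log(fvals[keep]), np.log(prod[keep])
        if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
            # constant response (or predictor): no association by definition
            slope, rvalue, pvalue = 0.0, 0.0, 1.0
        else:
            res = stats.linregress(x, y)
            slope, rvalue, pvalue = res.slope, res.rvalue, res.pvalue
        out.append(
            {
                "factor": f,
                "slope": slope,
                "r": rvalue,
                "p": pvalue,
                "n_pairs": int(keep.sum()),
            }
        )
    return pd.DataFrame(out).set_index("factor")
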