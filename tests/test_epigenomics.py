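"""Epigenomic overlays: densities, Z-scores, EC/HC classes, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromwalk.epigenomics import (
    FactorDensityTable,
    classify_ec_hc,
    enrichment_correlation,
    partition_signal_density,
    read_bedgraph,
    read_cytoband,
    zscore_densities,
)
from chromwalk.errors import (
    CoordinateError,
    InsufficientDataError,
    InvalidSpecError,
)
from chromwalk.interactions import EffectiveInteractionMatrix
from chromwalk.partition import PartitionSet


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _bands(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "gieStain"])


def test_read_bedgraph_and_cytoband(tmp_path):
    bg = tmp_path / "t.bedGraph"
    bg.write_text("# comment\nchr1\t0\t100\t2.5\nchr1 100 200 1.0\n")
    df = read_bedgraph(bg)
    assert list(df.columns) == ["chrom", "start", "end", "value"]
    assert len(df) == 2
    assert df["value"].tolist() == [2.5, 1.0]

    cb = tmp_path / "cytoBand.txt"
    cb.write_text("chr1\t0\t500\tp36\tgneg\nchr1\t500\t900\tp35\tgpos50\n")
    bands = read_cytoband(cb)
    assert bands["gieStain"].tolist() == ["gneg", "gpos50"]


def test_partition_signal_density_weighted_mean():
    # partition 0 = [0, 20), partition 1 = [20, 40) at 10 bp resolution
    parts = PartitionSet.from_assignment([0, 0, 1, 1], chrom="chr1", resolution=10)
    track = _track([("chr1", 0, 10, 4.0), ("chr1", 10, 30, 1.0)])
    dens = partition_signal_density(track, parts)
    # partition 0: 10bp*4 + 10bp*1 over 20bp; partition 1: 10bp*1 + 10bp*0
    assert dens[0] == pytest.approx(2.5)
    assert dens[1] == pytest.approx(0.5)


def test_partition_signal_density_chrom_mismatch():
    parts = PartitionSet.from_assignment([0, 1], chrom="chr1", resolution=10)
    with pytest.raises(CoordinateError):
        partition_signal_density(_track([("chr9", 0, 10, 1.0)]), parts)


def test_zscore_densities_weighted():
    density = pd.DataFrame({"K9me3": [1.0, 3.0], "flat": [2.0, 2.0]})
    table = FactorDensityTable(density=density, weights=np.array([3.0, 1.0]))
    z = zscore_densities(table)
    mu = (3 * 1.0 + 1 * 3.0) / 4.0
    sigma = np.sqrt((3 * (1.0 - mu) ** 2 + 1 * (3.0 - mu) ** 2) / 4.0)
    assert z["K9me3"].tolist() == pytest.approx([(1.0 - mu) / sigma, (3.0 - mu) / sigma])
    assert z["flat"].isna().all()  # zero-variance factor is flagged
    # weighted mean of the Z-scores vanishes
    assert np.average(z["K9me3"], weights=[3, 1]) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(InvalidSpecError):
        zscore_densities(FactorDensityTable(density=density.iloc[:1], weights=np.ones(1)))


def test_classify_ec_hc_labels():
    parts = PartitionSet.from_assignment([0, 1, 2], chrom="chr1", resolution=100)
    bands = _bands(
        [
            ("chr1", 0, 100, "a", "gneg"),        # partition 0: pure EC
            ("chr1", 100, 190, "b", "gpos75"),    # partition 1: 90% HC
            ("chr1", 200, 250, "c", "gneg"),      # partition 2: 50/50 split
            ("chr1", 250, 300, "d", "gpos100"),
        ]
    )
    table = classify_ec_hc(bands, parts, threshold=0.8)
    assert table.classes.tolist() == ["EC", "HC", "mixed"]
    assert table.fractions.loc[:, "gneg"].iloc[0] == pytest.approx(1.0)
    # uncovered bases count toward "other"
    assert table.fractions["other"].iloc[1] == pytest.approx(0.1)


def test_classify_ec_hc_no_overlap_is_mixed():
    parts = PartitionSet.from_assignment([0, 1], chrom="chr1", resolution=100)
    bands = _bands([("chr1", 0, 100, "a", "gneg")])
    table = classify_ec_hc(bands, parts)
    assert table.classes.tolist() == ["EC", "mixed"]


def _enrichment_setup(densities):
    """EIM with F_AB exactly the density product, all partitions EC."""
    k = len(densities)
    d = np.asarray(densities, dtype=float)
    f = np.outer(d, d)
    eim = EffectiveInteractionMatrix(F=f, mode="hard_genome")
    table = FactorDensityTable(
        density=pd.DataFrame({"X": d}), weights=np.ones(k)
    )
    classes = classify_ec_hc(
        _bands([("chr1", i * 100, (i + 1) * 100, str(i), "gneg") for i in range(k)]),
        PartitionSet.from_assignment(np.arange(k), chrom="chr1", resolution=100),
    )
    return eim, table, classes


def test_enrichment_identity_gives_slope_one():
    eim, table, classes = _enrichment_setup([1.0, 2.0, 4.0, 0.5, 3.0])
    res = enrichment_correlation(eim, table, classes, "EC-EC")
    assert res.loc["X", "slope"] == pytest.approx(1.0)
    assert res.loc["X", "r"] == pytest.approx(1.0)
    assert res.loc["X", "n_pairs"] == 10


def test_enrichment_constant_densities():
    eim, table, classes = _enrichment_setup([2.0, 2.0, 2.0, 2.0])
    res = enrichment_correlation(eim, table, classes, "EC-EC")
    assert res.loc["X", "slope"] == 0.0
    assert res.loc["X", "r"] == 0.0
    assert res.loc["X", "p"] == 1.0


def test_enrichment_p_value_matches_permutation_oracle():
    # independent x and noisy y: the analytic two-sided p of Pearson r must
    # agree with a 10^4-draw permutation estimate
    rng = np.random.default_rng(0)
    k = 12
    d = rng.uniform(0.5, 2.0, k)
    eim, table, classes = _enrichment_setup(d)
    eim.F = np.exp(rng.normal(0.0, 1.0, (k, k)))  # decouple F from densities
    eim.F = (eim.F + eim.F.T) / 2.0
    res = enrichment_correlation(eim, table, classes, "EC-EC")
    iu, ju = np.triu_indices(k, 1)
    x = np.log(eim.F[iu, ju])
    y = np.log(d[iu] * d[ju])
    r_obs = abs(stats.pearsonr(x, y)[0])
    perm = np.array(
        [abs(stats.pearsonr(rng.permutation(x), y)[0]) for _ in range(10_000)]
    )
    p_perm = (1 + (perm >= r_obs).sum()) / (1 + perm.size)
    assert res.loc["X", "p"] == pytest.approx(p_perm, abs=0.02)


def test_enrichment_errors():
    eim, table, classes = _enrichment_setup([1.0, 2.0, 3.0])
    with pytest.raises(InvalidSpecError):
        enrichment_correlation(eim, table, classes, "EC-XX")
    # force all classes to HC so no EC-EC pair qualifies
    classes.classes[:] = "HC"
    with pytest.raises(InsufficientDataError):
        enrichment_correlation(eim, table, classes, "EC-EC")
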