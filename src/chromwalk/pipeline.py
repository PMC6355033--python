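"""End-to-end workflow: smooth -> mask -> MSM -> profile -> partitions -> fluxes.

``run_chromosome`` executes the whole single-chromosome analysis; ``run_genome``
merges per-chromosome partitions at representative hierarchy levels and
computes mean-field effective interactions, strength layers and affinities
over the genome-wide contact matrix.  Every run writes its artifacts as TSV
with a manifest of content hashes so that reruns under a fixed seed are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hic, interactions, metastability, msm, partition
from .errors import ChromwalkError, InvalidSpecError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ChromosomeResult", "run_chromosome", "run_genome"]


@dataclass
class RunConfig:
    """Tunable parameters of the pipeline, with field-standard defaults.

    resolution: Hi-C bin width (bp); sigma_bp: Gaussian smoothing width;
    beta: per-chromosome inverse temperature, integer or "auto" (largest
    stable integer in beta_candidates); n_max/mc_iters: metastability scan
    depth and Monte-Carlo budget; rho_threshold: hierarchy cutoff;
    representative_levels: which hierarchy level represents each chromosome
    in the genome-wide merge (1-based index into the selected levels).
    """

    resolution: int = 50_000
    sigma_bp: float = 200_000
    truncate_sigmas: float = 4.0
    beta: int | str = "auto"
    beta_candidates: tuple[int, ...] = tuple(range(1, 13))
    n_max: int = 50
    mc_iters: int = 500
    rho_threshold: float = 0.8
    min_growth: float = 2.0
    keep_trivial: bool = False
    skip_first_chroms: tuple[str, ...] = ("chr1", "chr2")
    representative_levels: dict = field(default_factory=dict)
    n_scaffold: int = 2000
    seed: int = 0

    def __post_init__(self):
        for name in ("resolution", "n_max", "mc_iters"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.sigma_bp < 0 or self.rho_threshold <= 0:
            raise InvalidSpecError("sigma_bp must be >= 0 and rho_threshold > 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key=value config file (comments with #)."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise InvalidSpecError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            if key == "beta" and value != "auto":
                value = int(value)
            elif key in ("beta_candidates", "skip_first_chroms"):
                parts = [v for v in value.split(",") if v]
                value = tuple(int(v) for v in parts) if key == "beta_candidates" else tuple(parts)
            elif key == "representative_levels":
                value = json.loads(value)
            elif isinstance(default, bool):
                value = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                value = int(value)
            elif isinstance(default, float):
                value = float(value)
            kwargs[key] = value
        return cls(**kwargs)

    def dump(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(map(str, v))
            elif isinstance(v, dict):
                v = json.dumps(v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"


@dataclass
class ChromosomeResult:
    """All single-chromosome artifacts, keyed by hierarchy level size."""

    chrom: str
    beta: int
    mask: hic.LocusMask
    profile: metastability.MetastabilityProfile
    levels: metastability.HierarchyLevels
    partitions: dict[int, partition.PartitionSet]
    soft: dict[int, partition.SoftPartition]
    effective: dict[int, interactions.EffectiveInteractionMatrix]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, files: list[Path]) -> None:
    manifest = {p.name: _sha256(p) for p in files}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def run_chromosome(
    config: RunConfig,
    cm: hic.ContactMatrix | None = None,
    contact_path=None,
    chrom: str = "chr?",
    out_dir=None,
) -> ChromosomeResult:
    """Full single-chromosome analysis.

    Accepts either an in-memory contact matrix or a triplet-text path.
    Stages: Gaussian smoothing, inactive-locus masking, pseudo-energies,
    annealing-parameter selection, MSM and kinetics, metastability profile,
    hierarchy detection, committors, hard partitions and soft effective
    interactions per level.  Raises the failing stage's error annotated with
    the stage name.
    """
    if cm is None:
        if contact_path is None:
            raise InvalidSpecError("provide a contact matrix or a contact file path")
        if not Path(contact_path).exists():
            raise FileNotFoundError(f"contact file not found: {contact_path}")
        cm = hic.read_contacts(contact_path, config.resolution, chrom)
    chrom = cm.chrom
    stage = "smooth"
    try:
        smoothed = hic.gaussian_smooth(cm, config.sigma_bp, config.truncate_sigmas)
        stage = "mask"
        reduced, mask = hic.mask_inactive_loci(smoothed)
        stage = "energies"
        landscape = msm.pair_energies(reduced)
        stage = "select_beta"
        if config.beta == "auto":
            beta = msm.select_beta(landscape, config.beta_candidates)
        else:
            beta = int(config.beta)
        stage = "msm"
        model = msm.build_msm(landscape, beta)
        stage = "kinetics"
        kin = msm.kinetic_matrices(model)
        stage = "profile"
        profile = metastability.rho_profile(
            kin.gamma,
            model,
            n_max=min(config.n_max, model.n_states - 1),
            iters=config.mc_iters,
            seed=config.seed,
        )
        stage = "hierarchy"
        levels = metastability.select_hierarchy(
            profile,
            rho_threshold=config.rho_threshold,
            min_growth=config.min_growth,
            keep_trivial=config.keep_trivial,
            skip_first=chrom in config.skip_first_chroms,
        )
        stage = "partitions"
        partitions, softs, effs = {}, {}, {}
        for size in levels.sizes:
            hubs = profile.by_size[size]
            soft = partition.committor_probabilities(model, hubs)
            softs[size] = soft
            partitions[size] = partition.hard_assign(
                soft,
                chroms=np.full(model.n_states, chrom),
                bin_starts=reduced.bin_starts,
                resolution=reduced.resolution,
            )
            effs[size] = interactions.effective_flux_soft(soft, model)
        partition.assign_hierarchical_labels(
            [partitions[s] for s in levels.sizes]
        )
    except ChromwalkError as exc:
        logger.error("chromosome %s failed at stage %s: %s", chrom, stage, exc)
        raise
    result = ChromosomeResult(
        chrom=chrom,
        beta=beta,
        mask=mask,
        profile=profile,
        levels=levels,
        partitions=partitions,
        soft=softs,
        effective=effs,
    )
    if out_dir is not None:
        _export_chromosome(result, Path(out_dir))
    return result


def _export_chromosome(res: ChromosomeResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    p = out_dir / f"{res.chrom}_rho_profile.tsv"
    res.profile.to_frame().to_csv(p, sep="\t", index=False)
    files.append(p)
    for size, parts in res.partitions.items():
        p = out_dir / f"{res.chrom}_partitions_n{size}.bed"
        parts.to_bed(p, level=str(size))
        files.append(p)
        p = out_dir / f"{res.chrom}_effective_n{size}.tsv"
        pd.DataFrame(
            res.effective[size].F, index=parts.labels, columns=parts.labels
        ).to_csv(p, sep="\t")
        files.append(p)
    meta = out_dir / f"{res.chrom}_run.json"
    meta.write_text(
        json.dumps(
            {"chrom": res.chrom, "beta": res.beta, "levels": list(map(int, res.levels.sizes))},
            indent=1,
        )
    )
    files.append(meta)
    _write_manifest(out_dir, files)


def merge_partitions(
    per_chrom: dict[str, ChromosomeResult], config: RunConfig
) -> partition.PartitionSet:
    """Concatenate representative-level partitions into one genome scheme.

    The representative level per chromosome comes from
    ``config.representative_levels`` (1-based index into the chromosome's
    selected hierarchy levels; default: deepest level available).  Labels
    become "<chrom>-<label>".
    """
    chroms_arr, starts_arr, assign_arr, labels = [], [], [], []
    offset = 0
    for chrom, res in per_chrom.items():
        if not len(res.levels.sizes):
            raise InvalidSpecError(f"{chrom} has no hierarchy levels")
        idx = config.representative_levels.get(chrom)
        size = res.levels.sizes[idx - 1] if idx else res.levels.sizes[-1]
        parts = res.partitions[size]
        chroms_arr.append(parts.chroms)
        starts_arr.append(parts.bin_starts)
        assign_arr.append(parts.assignment + offset)
        labels.extend(f"{chrom}-{lab}" for lab in parts.labels)
        offset += parts.n_partitions
    return partition.PartitionSet(
        assignment=np.concatenate(assign_arr),
        chroms=np.concatenate(chroms_arr),
        bin_starts=np.concatenate(starts_arr),
        resolution=config.resolution,
        labels=labels,
    )


def run_genome(
    config: RunConfig,
    per_chrom: dict[str, ChromosomeResult],
    genome_counts: np.ndarray,
    out_dir=None,
):
    """Genome-wide mean-field analysis over merged partitions.

    ``genome_counts`` is the raw (unsmoothed) genome contact matrix over the
    concatenated active loci of the per-chromosome runs, in the same order as
    the merge.  Computes the genome flux (beta = 1 Boltzmann normalization of
    counts over ordered off-diagonal pairs), hard effective interactions,
    strength layers, the major cluster and the affinity matrix.
    """
    missing = [c for c, r in per_chrom.items() if r is None]
    if missing:
        raise InvalidSpecError(f"missing per-chromosome results: {missing}")
    merged = merge_partitions(per_chrom, config)
    counts = np.asarray(genome_counts, dtype=float)
    if counts.shape[0] != merged.n_loci:
        raise InvalidSpecError("genome counts do not match merged partitions")
    flux = counts.copy()
    np.fill_diagonal(flux, 0.0)
    flux /= flux.sum()
    eim = interactions.effective_flux_hard(merged, flux)
    n_pairs = merged.n_partitions * (merged.n_partitions - 1) // 2
    interactions.classify_layers(eim, n_scaffold=min(config.n_scaffold, n_pairs))
    clusters = interactions.major_cluster(eim)
    aff = interactions.affinity_matrix(counts, merged)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        for name, mat in (("effective", eim.F), ("affinity", aff.C)):
            p = out_dir / f"genome_{name}.tsv"
            pd.DataFrame(mat, index=merged.labels, columns=merged.labels).to_csv(
                p, sep="\t"
            )
            files.append(p)
        _write_manifest(out_dir, files)
    return {
        "partitions": merged,
        "effective": eim,
        "affinity": aff,
        "clusters": clusters,
    }
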