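"""Configuration-driven orchestration of the full analysis.

One declarative config names the per-group inputs (newick tree +
occurrence CSV), the grid, the randomization settings and the
comparison options; :func:`run_all` then produces, per group, the six
observed surfaces, PD/RPD significance maps, the CANAPE map and the
beta-diversity regionalization, and across groups the standardized
surfaces, mean-all/mean-concordant summaries, leave-one-out variants
and fuzzy group dendrograms.  A manifest records config, seeds,
checksums and timings; the whole run is a pure function of the input
files and the config (one global seed deterministically derives every
per-stage, per-group seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._errors import InvalidParameterError, StageError
from .beta import average_linkage_cluster, cut_clusters, pairwise_phylo_jaccard
from .canape import build_null_ensemble, canape_classify, significance_ranks
from .compare import leave_group_out, mean_concordant_cells, standardize_surfaces
from .experiments import derive_seed
from .fuzzy import NeighborhoodSpec, cluster_groups, pairwise_group_dissimilarity
from .grid import GridSpec, aggregate_to_grid, align_matrix_to_tree, read_occurrences
from .io import read_surfaces_csv, write_surfaces_csv
from .metrics import (
    phylogenetic_diversity,
    phylogenetic_endemism,
    relative_metric,
    taxon_richness,
    weighted_endemism,
)
from .randomize import RandomizationConfig
from .tree import branch_incidence, equalize_branch_lengths, read_tree

logger = logging.getLogger(__name__)

__all__ = ["GroupInputs", "AnalysisConfig", "run_group_analysis",
           "run_cross_group_analysis", "run_all"]

COMPARE_METRICS = ("TR", "WE", "PD", "PE")


@dataclass
class GroupInputs:
    tree: str
    occurrences: str


@dataclass
class AnalysisConfig:
    groups: dict[str, GroupInputs]
    outdir: str
    seed: int = 0
    cell_size: float = 25_000.0
    origin_x: float | None = None
    origin_y: float | None = None
    n_reps: int = 999
    alpha_two_tailed: float = 0.05
    alpha_super: float = 0.01
    burn_in_swaps_factor: float = 1.0
    either_tree: bool = False
    convention: str = "root"
    standardization_mode: str = "per-group"
    fuzzy_radius: float = 100_000.0
    n_clusters: int = 4

    def __post_init__(self):
        if not self.groups:
            raise InvalidParameterError("config needs at least one group")
        for name, g in list(self.groups.items()):
            if isinstance(g, dict):
                g = GroupInputs(**g)
                self.groups[name] = g
            for role, p in (("tree", g.tree), ("occurrences", g.occurrences)):
                if not p:
                    raise InvalidParameterError(
                        f"group '{name}' is missing its {role} path"
                    )
                if not Path(p).exists():
                    raise InvalidParameterError(
                        f"group '{name}' {role} path does not exist: {p}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def randomization(self, seed: int) -> RandomizationConfig:
        return RandomizationConfig(
            n_reps=self.n_reps,
            alpha_two_tailed=self.alpha_two_tailed,
            alpha_super=self.alpha_super,
            seed=seed,
            burn_in_swaps_factor=self.burn_in_swaps_factor,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_group_analysis(config: AnalysisConfig, group: str) -> dict[str, Path]:
    """Observed surfaces, significance maps, CANAPE and beta for one group."""
    if group not in config.groups:
        raise InvalidParameterError(f"unknown group '{group}'")
    gdir = Path(config.outdir) / group
    gdir.mkdir(parents=True, exist_ok=True)
    inputs = config.groups[group]
    out: dict[str, Path] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, group, exc) from exc
        logger.info("[%s] %s: %.2fs", group, name, time.perf_counter() - t0)
        return result

    tree = stage("read_tree", lambda: read_tree(inputs.tree))
    occ = stage("read_occurrences", lambda: read_occurrences(inputs.occurrences))
    grid = GridSpec(config.cell_size, config.origin_x, config.origin_y)
    matrix = stage("aggregate", lambda: aggregate_to_grid(occ, grid))
    matrix, tree = stage(
        "align", lambda: align_matrix_to_tree(matrix, tree, "prune-both")
    )

    def observed():
        inc = branch_incidence(tree, matrix, config.convention)
        inc_eq = branch_incidence(
            equalize_branch_lengths(tree), matrix, config.convention
        )
        surfaces = [
            taxon_richness(matrix, group),
            weighted_endemism(matrix, group),
            phylogenetic_diversity(inc, group),
            phylogenetic_endemism(inc, group),
            relative_metric(
                phylogenetic_diversity(inc, group),
                phylogenetic_diversity(inc_eq, group),
            ),
            relative_metric(
                phylogenetic_endemism(inc, group),
                phylogenetic_endemism(inc_eq, group),
            ),
        ]
        return inc, surfaces

    inc, surfaces = stage("metrics", observed)
    out["surfaces"] = gdir / "surfaces.csv"
    write_surfaces_csv(surfaces, out["surfaces"])

    cfg = config.randomization(derive_seed(config.seed, "ensemble", group))
    ens = stage(
        "randomization",
        lambda: build_null_ensemble(matrix, tree, cfg, config.convention),
    )
    pd_sig = significance_ranks(ens, "PD", "two", cfg.alpha_two_tailed)
    rpd_sig = significance_ranks(ens, "RPD", "two", cfg.alpha_two_tailed)
    out["significance_pd"] = gdir / "significance_pd.csv"
    out["significance_rpd"] = gdir / "significance_rpd.csv"
    pd_sig.to_frame().to_csv(out["significance_pd"])
    rpd_sig.to_frame().to_csv(out["significance_rpd"])

    def canape():
        pe_act = significance_ranks(ens, "PE_actual", "high", cfg.alpha_two_tailed)
        pe_eq = significance_ranks(ens, "PE_equalized", "high", cfg.alpha_two_tailed)
        rpe = significance_ranks(ens, "RPE", "two", cfg.alpha_two_tailed)
        return canape_classify(pe_act, pe_eq, rpe, cfg, config.either_tree)

    cmap = stage("canape", canape)
    out["canape"] = gdir / "canape.csv"
    cmap.to_frame().to_csv(out["canape"])

    def beta():
        dissim = pairwise_phylo_jaccard(inc)
        dend = average_linkage_cluster(dissim)
        k = min(config.n_clusters, dend.n_leaves)
        return dissim, dend, cut_clusters(dend, k)

    dissim, dend, clusters = stage("beta", beta)
    out["beta_dissimilarity"] = gdir / "beta_dissimilarity.csv"
    out["beta_dendrogram"] = gdir / "beta_dendrogram.nwk"
    out["beta_clusters"] = gdir / "beta_clusters.csv"
    dissim.to_frame().to_csv(out["beta_dissimilarity"], index_label="cell_id")
    out["beta_dendrogram"].write_text(dend.to_newick() + "\n")
    clusters.rename_axis("cell_id").to_csv(out["beta_clusters"])
    return out


def run_cross_group_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Standardized summaries, leave-one-out and fuzzy dendrograms."""
    if len(config.groups) < 2:
        raise InvalidParameterError("cross-group analysis needs >= 2 groups")
    outdir = Path(config.outdir) / "cross"
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    spec = NeighborhoodSpec(radius=config.fuzzy_radius)
    summary_info = {}
    for metric in COMPARE_METRICS:
        per_group = []
        for group in config.groups:
            path = Path(config.outdir) / group / "surfaces.csv"
            if not path.exists():
                raise StageError("cross", group,
                                 f"missing group surfaces {path}")
            for s in read_surfaces_csv(path):
                if s.metric == metric:
                    per_group.append(s)
        try:
            std = standardize_surfaces(per_group, config.standardization_mode)
            out[f"standardized_{metric}"] = outdir / f"standardized_{metric}.csv"
            write_surfaces_csv(std, out[f"standardized_{metric}"])
            summary = mean_concordant_cells(std)
            out[f"summary_{metric}"] = outdir / f"summary_{metric}.csv"
            write_surfaces_csv(
                [summary.mean_all, summary.mean_concordant],
                out[f"summary_{metric}"],
            )
            loo = {}
            for group in config.groups:
                if len(config.groups) < 3:
                    break
                sub = leave_group_out(std, group)
                loo[group] = {
                    "n_concordant": sub.n_concordant,
                    "concordant_change": sub.concordant_change,
                }
                out[f"leaveout_{group}_{metric}"] = (
                    outdir / f"leaveout_{group}_{metric}.csv"
                )
                write_surfaces_csv(
                    [sub.mean_all, sub.mean_concordant],
                    out[f"leaveout_{group}_{metric}"],
                )
            dissim = pairwise_group_dissimilarity(
                {s.group: s for s in std}, spec
            )
            out[f"fuzzy_{metric}"] = outdir / f"fuzzy_{metric}.csv"
            dissim.to_frame().to_csv(out[f"fuzzy_{metric}"], index_label="group")
            dend = cluster_groups(dissim)
            out[f"fuzzy_dendrogram_{metric}"] = (
                outdir / f"fuzzy_dendrogram_{metric}.nwk"
            )
            out[f"fuzzy_dendrogram_{metric}"].write_text(dend.to_newick() + "\n")
            summary_info[metric] = {
                "n_concordant": summary.n_concordant,
                "leave_one_out": loo,
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"cross:{metric}", None, exc) from exc
    (outdir / "concordance.json").write_text(
        json.dumps(summary_info, indent=2, sort_keys=True)
    )
    out["concordance"] = outdir / "concordance.json"
    return out


def run_all(config: AnalysisConfig) -> Path:
    """Full per-group and cross-group run; writes the manifest once."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    t0 = time.perf_counter()
    for group in config.groups:
        g0 = time.perf_counter()
        files = run_group_analysis(config, group)
        manifest["stages"][group] = {
            "outputs": {k: str(p) for k, p in files.items()},
            "checksums": {k: _sha256(p) for k, p in files.items()},
            "seconds": round(time.perf_counter() - g0, 3),
        }
    if len(config.groups) >= 2:
        c0 = time.perf_counter()
        files = run_cross_group_analysis(config)
        manifest["stages"]["cross"] = {
            "outputs": {k: str(p) for k, p in files.items()},
            "checksums": {k: _sha256(p) for k, p in files.items()},
            "seconds": round(time.perf_counter() - c0, 3),
        }
    manifest["total_seconds"] = round(time.perf_counter() - t0, 3)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
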