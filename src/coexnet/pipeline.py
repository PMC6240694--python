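"""End-to-end orchestration of the per-condition and consensus analyses.

``run_condition`` chains the full single-network recipe: subset the
samples of one condition (optionally below a dose cutoff), keep the
top-N genes by rank-mean expression, build the signed Spearman network
(beta = 10), take the topological overlap, cluster 1 - TOM by average
linkage, cut the tree dynamically, summarize modules by eigengenes,
merge close modules (cut height 0.25), reassign poorly placed genes
(threshold 0.2), correlate eigengenes with dose, select significant
modules (p < 0.01), and — when a gene-set library or edge list is
supplied — run TF-target enrichment and hub detection.

``run_consensus`` runs the same front end per condition on the shared
gene universe (intersection of the per-condition top-N lists),
calibrates the per-condition TOMs, takes their entrywise minimum, and
detects consensus modules (minimum size 100) with per-condition trait
tables and the conservative consensus module-trait summary (p < 0.05).

Every run emits a machine-readable report of all effective parameters,
input digests and stage timings; with fixed inputs and configuration the
analysis tables are byte-identical across reruns (timings are isolated
in the report's ``timings`` key).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    EdgeList,
    EigengeneSet,
    ExpressionMatrix,
    GeneSetLibrary,
    ModulePartition,
    SampleMetadata,
    TOMMatrix,
)
from .enrichment import fisher_enrichment
from .errors import ComputationError, ValidationError
from .hubs import hub_candidates, module_degree
from .modules import (
    average_linkage,
    dynamic_tree_cut,
    kme,
    merge_close_modules,
    module_eigengene,
    partition_from_labels,
    reassign_genes,
    trim_low_kme_genes,
)
from .network import (
    calibrate_toms,
    consensus_tom,
    signed_adjacency,
    spearman_correlation,
    topological_overlap,
)
from .preprocess import rank_mean_filter, subset_condition
from .traits import (
    consensus_trait_relationship,
    dose_trait,
    eigengene_trait_correlation,
    select_significant,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of a network run, with the study defaults."""

    condition: str = ""
    max_dose_exclusive: float | None = None
    top_n: int = 10_000
    beta: float = 10.0
    deep_split: int = 2
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    reassign_threshold: float = 0.2
    min_kme_to_stay: float = 0.3
    trait_alpha: float = 0.01
    trait_transform: str = "ordinal"
    trait_method: str = "pearson"
    include_grey_in_traits: bool = False
    calibration_quantile: float = 0.95
    calibrate: bool = True
    consensus_min_module_size: int = 100
    consensus_trait_alpha: float = 0.05
    hub_top_fraction: float = 0.1
    max_block_size: int = 10_000

    def for_consensus(self) -> "PipelineConfig":
        return replace(
            self,
            min_module_size=self.consensus_min_module_size,
            trait_alpha=self.consensus_trait_alpha,
        )


@dataclass
class ConditionResult:
    """Everything a single-network run produces."""

    config: PipelineConfig
    expression: ExpressionMatrix
    partition: ModulePartition
    eigengenes: EigengeneSet
    kme: pd.DataFrame
    trait_table: pd.DataFrame
    significant: pd.DataFrame
    enrichment: pd.DataFrame | None
    hubs: pd.DataFrame | None
    report: dict[str, Any]

    @property
    def significant_module_genes(self) -> dict[str, list[str]]:
        modules = self.partition.modules
        return {m: modules[m] for m in self.significant["module"] if m in modules}


@dataclass
class ConsensusResult:
    """Everything a consensus run produces."""

    config: PipelineConfig
    conditions: tuple[str, ...]
    universe: tuple[str, ...]
    partition: ModulePartition
    eigengenes: dict[str, EigengeneSet]
    trait_tables: dict[str, pd.DataFrame]
    consensus_table: pd.DataFrame
    significant: pd.DataFrame
    report: dict[str, Any]


def _digest(expr: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update(("\t".join(expr.gene_ids) + "|" + "\t".join(expr.sample_ids)).encode())
    h.update(np.ascontiguousarray(expr.values).tobytes())
    return h.hexdigest()[:16]


class _StageClock:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def run(self, stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except (ValidationError, ComputationError):
            raise
        except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
            raise ComputationError(f"stage {stage!r} failed: {exc}") from exc
        self.timings[stage] = round(time.perf_counter() - t0, 4)
        return out


def _detect_modules(
    expr: ExpressionMatrix,
    tom: TOMMatrix,
    config: PipelineConfig,
    min_module_size: int,
    clock: _StageClock,
) -> tuple[ModulePartition, EigengeneSet]:
    link = clock.run("cluster", average_linkage, tom.dissimilarity())
    labels = clock.run(
        "tree_cut",
        dynamic_tree_cut,
        link,
        deep_split=config.deep_split,
        min_module_size=min_module_size,
    )
    partition = partition_from_labels(expr.gene_ids, labels)
    eigengenes = clock.run("eigengenes", module_eigengene, expr, partition)
    if partition.modules:
        partition = clock.run(
            "kme_trim", trim_low_kme_genes, expr, partition, eigengenes,
            config.min_kme_to_stay, min_module_size,
        )
        eigengenes = module_eigengene(expr, partition)
    if not partition.modules:
        return partition, eigengenes
    partition, eigengenes = clock.run(
        "merge", merge_close_modules, expr, partition, eigengenes,
        config.merge_cut_height,
    )
    if partition.modules:
        partition = clock.run(
            "reassign", reassign_genes, expr, partition, eigengenes,
            config.reassign_threshold,
        )
        partition = partition.relabel_by_size()
        eigengenes = module_eigengene(expr, partition)
    return partition, eigengenes


def _base_report(config: PipelineConfig, expr: ExpressionMatrix) -> dict[str, Any]:
    return {
        "coexnet_version": __version__,
        "numpy_version": np.__version__,
        "parameters": asdict(config),
        "input": {
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "digest": _digest(expr),
        },
    }


def run_condition(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    config: PipelineConfig,
    gene_sets: GeneSetLibrary | None = None,
    edges: EdgeList | None = None,
) -> ConditionResult:
    """Run the full single-condition network analysis."""
    clock = _StageClock()
    subset = clock.run(
        "subset", subset_condition, expr, meta, config.condition,
        config.max_dose_exclusive,
    )
    filtered = clock.run("filter", rank_mean_filter, subset, config.top_n)
    filtered.require_network_ready()
    cor = clock.run("correlation", spearman_correlation, filtered)
    adj = clock.run("adjacency", signed_adjacency, cor, config.beta)
    tom = clock.run(
        "tom", topological_overlap, adj, max_block_size=config.max_block_size
    )
    partition, eigengenes = _detect_modules(
        filtered, tom, config, config.min_module_size, clock
    )
    kme_table = clock.run("kme", kme, filtered, eigengenes)
    trait = clock.run(
        "trait", dose_trait, meta, filtered.sample_ids, config.trait_transform
    )
    trait_table = clock.run(
        "trait_correlation", eigengene_trait_correlation, eigengenes, trait,
        config.condition, config.trait_method,
    )
    significant = select_significant(trait_table, config.trait_alpha)

    enrich_table = None
    if gene_sets is not None and len(significant):
        universe = set(filtered.gene_ids) & gene_sets.gene_space
        tables = []
        modules = partition.modules
        for label in significant["module"]:
            genes = set(modules.get(label, ())) & universe
            if not genes or not universe:
                continue
            tables.append(
                fisher_enrichment(genes, gene_sets, universe, module_label=label)
            )
        enrich_table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=[
                "module", "set_name", "overlap", "module_size", "set_size",
                "universe", "p", "adj_p",
            ])
        )
        clock.timings["enrichment"] = clock.timings.get("enrichment", 0.0)

    hub_table = None
    if edges is not None and partition.modules:
        degrees: dict[str, int] = {}
        for genes in partition.modules.values():
            deg, _avg = module_degree(genes, edges)
            degrees.update(deg)
        hub_table = clock.run(
            "hubs", hub_candidates, kme_table, partition, degrees,
            config.hub_top_fraction,
        )

    report = _base_report(config, expr)
    report.update(
        {
            "analysis": "condition",
            "analyzed": {
                "n_samples": filtered.n_samples,
                "n_genes": filtered.n_genes,
                "n_modules": len(partition.modules),
                "n_grey": filtered.n_genes - partition.n_assigned,
                "n_significant_modules": int(len(significant)),
            },
            "timings": clock.timings,
        }
    )
    return ConditionResult(
        config, filtered, partition, eigengenes, kme_table, trait_table,
        significant, enrich_table, hub_table, report,
    )


def run_consensus(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    conditions: tuple[str, str] | list[str],
    config: PipelineConfig,
) -> ConsensusResult:
    """Run the consensus-network analysis across two or more conditions."""
    if len(conditions) < 2:
        raise ValidationError("consensus needs >= 2 conditions")
    clock = _StageClock()
    cconf = config.for_consensus()

    per_cond: dict[str, ExpressionMatrix] = {}
    universes: list[list[str]] = []
    for cond in conditions:
        subset = clock.run(
            f"subset[{cond}]", subset_condition, expr, meta, cond,
            config.max_dose_exclusive,
        )
        filtered = clock.run(
            f"filter[{cond}]", rank_mean_filter, subset, config.top_n
        )
        per_cond[cond] = filtered
        universes.append(filtered.gene_ids)

    universe = [g for g in universes[0] if all(g in set(u) for u in universes[1:])]
    if len(universe) < cconf.min_module_size:
        raise ValidationError(
            f"shared gene universe has {len(universe)} genes, fewer than the "
            f"consensus minimum module size {cconf.min_module_size}"
        )
    logger.info(
        "consensus universe: %d genes shared across %s", len(universe), conditions
    )
    per_cond = {c: e.select_genes(universe) for c, e in per_cond.items()}

    toms = []
    for cond in conditions:
        cor = spearman_correlation(per_cond[cond])
        adj = signed_adjacency(cor, config.beta)
        toms.append(
            topological_overlap(adj, max_block_size=config.max_block_size)
        )
    clock.timings["networks"] = sum(
        v for k, v in clock.timings.items() if k.startswith(("subset", "filter"))
    )
    if config.calibrate:
        toms = clock.run(
            "calibrate", calibrate_toms, toms, config.calibration_quantile
        )
    cons = clock.run("consensus_tom", consensus_tom, toms)

    ref_expr = per_cond[conditions[0]]
    partition, _ = _detect_modules(
        ref_expr, cons, cconf, cconf.min_module_size, clock
    )

    eigengenes: dict[str, EigengeneSet] = {}
    trait_tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        eig = module_eigengene(per_cond[cond], partition)
        eigengenes[cond] = eig
        trait = dose_trait(meta, per_cond[cond].sample_ids, config.trait_transform)
        trait_tables[cond] = eigengene_trait_correlation(
            eig, trait, cond, config.trait_method
        )
    consensus_table = clock.run(
        "consensus_traits", consensus_trait_relationship, list(trait_tables.values())
    )
    sig = consensus_table.dropna(subset=["consensus_p"])
    sig = sig.loc[sig["consensus_p"] < cconf.trait_alpha]
    sig = sig.sort_values(["consensus_r", "module"], ascending=[False, True])
    significant = sig.reset_index(drop=True)

    report = _base_report(config, expr)
    report.update(
        {
            "analysis": "consensus",
            "conditions": list(conditions),
            "analyzed": {
                "universe_genes": len(universe),
                "n_modules": len(partition.modules),
                "n_significant_modules": int(len(significant)),
                "calibration_scale_factors": (
                    list(cons.calibration.scale_factors) if cons.calibration else None
                ),
            },
            "timings": clock.timings,
        }
    )
    return ConsensusResult(
        cconf, tuple(conditions), tuple(universe), partition, eigengenes,
        trait_tables, consensus_table, significant, report,
    )
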