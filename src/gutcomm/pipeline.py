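"""End-to-end orchestration: preprocess -> network -> communities ->
per-community stratification -> association tests -> butyrate ratio.

`run_pipeline` works on in-memory objects; `run_pipeline_files` wires it
to the plain-text artifacts. Every stochastic stage derives its stream
from the single config seed, so reruns with the same config are
byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import associations, butyrate, network, preprocess, stability, stratify
from .io import (
    CountTable,
    KOTable,
    SubjectRecord,
    read_count_table,
    read_ko_table,
    read_metadata,
    read_newick,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    min_reads: int = 50
    min_samples: int = 10
    rare_frac: float = 1e-4
    rho_min: float = 0.4
    alpha: float = 0.05
    window_days: tuple[float, float] = (91.0, 275.0)
    target_days: float = 183.0
    k_min: int = 2
    k_max: int = 6
    n_perm: int = 1000
    n_boot: int = 1000
    null_variance: str = "perm"
    t_min: float = 0.01
    t_max: float = 100.0
    t_points: int = 60
    n_restarts: int = 20
    min_k_exclusive: int = 2
    unifrac_mode: str = "weighted_normalized"
    otu_level: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_days"] = list(self.window_days)
        return d

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data)
        if "window_days" in data:
            data["window_days"] = tuple(data["window_days"])
        return PipelineConfig(**data)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("preprocess")
def preprocess_stage(counts: CountTable, records: Sequence[SubjectRecord],
                     config: PipelineConfig):
    table = counts
    if config.otu_level:
        table = preprocess.filter_otus(table, config.min_reads, config.min_samples)
        table = preprocess.aggregate_to_genus(table)
    table = preprocess.filter_rare_genera(table, config.rare_frac)
    selection = preprocess.select_window_samples(
        records, config.window_days, config.target_days)
    selection = {c: s for c, s in selection.items() if s in table.sample_ids}
    if not selection:
        raise ValueError("no child has an in-window sample present in the counts")
    children = sorted(selection)
    abundance = preprocess.relative_abundance(table)
    abundance = abundance.select_samples([selection[c] for c in children])
    return table, abundance, selection


@_stage("network")
def network_stage(abundance, config: PipelineConfig):
    results = network.all_pairs(abundance, n_perm=config.n_perm,
                                n_boot=config.n_boot, seed=config.seed,
                                null_variance=config.null_variance)
    full = network.build_network(results, rho_min=config.rho_min,
                                 alpha=config.alpha, nodes=abundance.genus_ids)
    component = network.largest_component(full)
    return full, component


@_stage("communities")
def communities_stage(full, component, config: PipelineConfig):
    curve = stability.stability_sweep(
        component, t_min=config.t_min, t_max=config.t_max,
        n_points=config.t_points, seed=config.seed,
        n_restarts=config.n_restarts)
    partition = stability.select_partition(curve, config.min_k_exclusive)
    assignment = stability.assign_communities(full, partition)
    return curve, partition, assignment


@_stage("stratify")
def stratify_stage(abundance, assignment, tree, lineages_by_genus,
                   config: PipelineConfig):
    if tree is None:
        tree = stratify.taxonomy_cladogram(lineages_by_genus)
    communities = sorted({c for c in assignment.values() if c != stability.UNASSIGNED})
    clusterings = {}
    for comm in communities:
        sub = stratify.community_subtable(abundance, assignment, comm)
        nonzero = sub.values.sum(axis=0) > 0
        if not nonzero.all():
            dropped = [s for s, ok in zip(sub.sample_ids, nonzero) if not ok]
            logger.warning("community %s: dropping %d zero-abundance sample(s): %s",
                           comm, len(dropped), dropped)
            sub = sub.select_samples(
                [s for s, ok in zip(sub.sample_ids, nonzero) if ok])
        dist = stratify.unifrac_matrix(tree, sub, mode=config.unifrac_mode)
        clustering = stratify.choose_k(dist, range(config.k_min, config.k_max + 1))
        coords = stratify.pcoa_coordinates(dist)
        clusterings[comm] = (clustering, dist, coords)
    return tree, clusterings


def _survival_input(records: Sequence[SubjectRecord], children: Sequence[str],
                    groups: dict[str, str]) -> associations.SurvivalInput:
    outcome = {}
    for r in records:
        outcome.setdefault(r.child_id, (r.outcome_age_days, r.event))
    keep = [c for c in children if c in outcome]
    return associations.SurvivalInput(
        child_ids=list(keep),
        times=np.array([outcome[c][0] for c in keep]),
        events=np.array([outcome[c][1] for c in keep]),
        groups=[groups[c] for c in keep])


@_stage("associations")
def associations_stage(records, selection, clusterings, lineages_by_genus,
                       assignment, config: PipelineConfig):
    primary = {}
    for r in records:
        if selection.get(r.child_id) == r.sample_id:
            primary[r.child_id] = r
    results = {"communities": {}, "enrichment": {}}
    best = None  # (p_logrank, community, cluster, hr_dict)
    for comm, (clustering, _, _) in clusterings.items():
        child_of_sample = {s: c for c, s in selection.items()}
        comm_res = {"k": clustering.k, "clusters": {}}
        for label in range(clustering.k):
            member_samples = clustering.members(label)
            member_children = sorted(child_of_sample[s] for s in member_samples)
            groups = {child_of_sample[s]:
                      ("in" if s in member_samples else "out")
                      for s in clustering.sample_ids}
            children = sorted(groups)
            cluster_res = {"children": member_children, "n": len(member_children)}
            statuses = [associations.food_complexity(primary[c])
                        for c in children if c in primary]
            status_children = [c for c in children if c in primary]
            bf_table = associations.breastfeeding_table(
                statuses, [groups[c] for c in status_children], ("in", "out"))
            fc_table = associations.complexity_table(
                statuses, [groups[c] for c in status_children], ("in", "out"))
            cluster_res["breastfeeding_table"] = bf_table.tolist()
            cluster_res["p_breastfeeding"] = associations.fisher_exact(bf_table)
            cluster_res["complexity_table"] = fc_table.tolist()
            cluster_res["p_complexity"] = associations.fisher_exact(fc_table)
            surv = _survival_input(records, children, groups)
            try:
                hr = associations.hazard_ratio(surv, reference_group="out")
                cluster_res["survival"] = hr
                # risk-subgroup flag: smallest log-rank p among clusters of
                # elevated hazard that are large enough to be a subgroup
                if (np.isfinite(hr["p_logrank"]) and hr["hr"] > 1
                        and len(member_children) >= 5):
                    key = (hr["p_logrank"], comm, label)
                    if best is None or key < best[0]:
                        best = (key, comm, label, hr)
            except ValueError as exc:
                cluster_res["survival"] = {"error": str(exc)}
            comm_res["clusters"][str(label)] = cluster_res
        results["communities"][str(comm)] = comm_res
    for rank in ("order", "phylum"):
        enr = associations.taxon_enrichment(assignment, lineages_by_genus, rank)
        results["enrichment"][rank] = enr.to_dict(orient="records")
    if best is not None:
        _, comm, label, hr = best
        results["risk_subgroup"] = {
            "community": comm, "cluster": label,
            "hr": hr["hr"], "p_logrank": hr["p_logrank"],
        }
    else:
        results["risk_subgroup"] = None
    return results


@_stage("butyrate")
def butyrate_stage(ko: KOTable, selection, clusterings, risk: dict):
    comm = risk["community"]
    clustering, _, _ = clusterings[comm]
    child_of_sample = {s: c for c, s in selection.items()}
    risk_children = {child_of_sample[s]
                     for s in clustering.members(risk["cluster"])}
    clustered_children = {child_of_sample[s] for s in clustering.sample_ids}
    ratios = butyrate.but_buk_ratio(ko)
    sample_child = {}
    for c, s in selection.items():
        sample_child[s] = c
    keep = ratios["sample_id"].map(
        lambda s: sample_child.get(s) in clustered_children)
    ratios = ratios[keep].reset_index(drop=True)
    labels = ["risk" if sample_child[s] in risk_children else "other"
              for s in ratios["sample_id"]]
    if len(set(labels)) < 2:
        raise ValueError("butyrate comparison needs both groups present")
    comparison = butyrate.compare_ratio(ratios, labels)
    return {"comparison": comparison,
            "n_risk": labels.count("risk"), "n_other": labels.count("other")}


def run_pipeline(counts: CountTable, records: Sequence[SubjectRecord],
                 tree=None, ko: Optional[KOTable] = None,
                 config: Optional[PipelineConfig] = None) -> dict:
    """Run the full analysis and return the (JSON-serializable) report."""
    config = config or PipelineConfig()
    genus_table, abundance, selection = preprocess_stage(counts, records, config)
    full, component = network_stage(abundance, config)
    curve, partition, assignment = communities_stage(full, component, config)
    lineages_by_genus = {}
    if genus_table.lineages is not None:
        lineages_by_genus = dict(zip(genus_table.feature_ids, genus_table.lineages))
    tree, clusterings = stratify_stage(abundance, assignment, tree,
                                       lineages_by_genus, config)
    assoc = associations_stage(records, selection, clusterings,
                               lineages_by_genus, assignment, config)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "n_children_selected": len(selection),
        "n_genera": len(abundance.genus_ids),
        "network": {
            "n_nodes": full.number_of_nodes(),
            "n_edges": full.number_of_edges(),
            "largest_component_size": component.number_of_nodes(),
        },
        "communities": {
            "k": partition.k,
            "assignment": {g: (None if c == stability.UNASSIGNED else c)
                           for g, c in sorted(assignment.items())},
            "curve": [{"t": float(t), "k": int(p.k), "stability": float(v)}
                      for t, p, v in zip(curve.t_grid, curve.partitions,
                                         curve.values)],
        },
        "stratification": {
            str(comm): {
                "k": clustering.k,
                "clusters": {str(l): clustering.members(l)
                             for l in range(clustering.k)},
                "pcoa": {s: [float(x) for x in coords[i]]
                         for i, s in enumerate(clustering.sample_ids)},
            }
            for comm, (clustering, _, coords) in clusterings.items()
        },
        "associations": assoc,
    }
    if ko is not None and assoc["risk_subgroup"] is not None:
        try:
            report["butyrate"] = butyrate_stage(ko, selection, clusterings,
                                                assoc["risk_subgroup"])
        except (StageError, ValueError) as exc:
            logger.warning("butyrate stage skipped: %s", exc)
            report["butyrate"] = {"skipped": str(exc)}
    else:
        logger.info("butyrate stage skipped (no KO table or no risk subgroup)")
        report["butyrate"] = {"skipped": "no KO table or no risk subgroup"}
    return report


def run_pipeline_files(counts_path, metadata_path, tree_path=None, ko_path=None,
                       config: Optional[PipelineConfig] = None,
                       outdir=None) -> dict:
    """File-based front end; writes report.json and the resolved config."""
    config = config or PipelineConfig()
    counts = read_count_table(counts_path)
    records = read_metadata(metadata_path)
    tree = read_newick(tree_path) if tree_path else None
    ko = read_ko_table(ko_path) if ko_path else None
    report = run_pipeline(counts, records, tree=tree, ko=ko, config=config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=_json_default))
        config.to_yaml(outdir / "config.resolved.yaml")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
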