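"""Synthetic cohort generator with planted ground truth.

Produces every pipeline input: a genus- or OTU-level count table with
lineages, per-sample subject metadata with diet histories and a
seroconversion outcome, a genus tree, and a KO table. Genera inside a
planted community share a per-child latent factor on the log-abundance
scale (inducing block correlation after compositional closure); one
subgroup of children carries an elevated seroconversion hazard, a shifted
composition inside the last community, and a depressed but/buk ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import skbio

from .io import (
    CountTable,
    KOTable,
    Lineage,
    SubjectRecord,
    write_count_table,
    write_ko_table,
    write_metadata,
)

KO_SIGMA = 0.5


@dataclass
class SimTruth:
    """Ground-truth labels and parameters of one simulated cohort."""

    seed: int
    children: list[str]
    primary_samples: dict[str, str]  # child -> 6-month sample id
    genus_community: dict[str, int]  # planted community per genus (members only)
    risk_children: list[str]
    factors: np.ndarray  # (n_communities, n_children) latent factors
    true_hr: float = np.nan
    diet_coupling: float = np.nan
    ko_shift: float = np.nan

    def to_json(self, path) -> None:
        data = {
            "seed": self.seed,
            "children": self.children,
            "primary_samples": self.primary_samples,
            "genus_community": self.genus_community,
            "risk_children": self.risk_children,
            "factors": np.asarray(self.factors).tolist(),
            "true_hr": None if np.isnan(self.true_hr) else self.true_hr,
            "diet_coupling": None if np.isnan(self.diet_coupling) else self.diet_coupling,
            "ko_shift": None if np.isnan(self.ko_shift) else self.ko_shift,
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @staticmethod
    def from_json(path) -> "SimTruth":
        data = json.loads(Path(path).read_text())
        return SimTruth(
            seed=data["seed"], children=data["children"],
            primary_samples=data["primary_samples"],
            genus_community={g: int(c) for g, c in data["genus_community"].items()},
            risk_children=data["risk_children"],
            factors=np.asarray(data["factors"]),
            true_hr=data["true_hr"] if data["true_hr"] is not None else np.nan,
            diet_coupling=(data["diet_coupling"]
                           if data["diet_coupling"] is not None else np.nan),
            ko_shift=data["ko_shift"] if data["ko_shift"] is not None else np.nan,
        )


def _community_lineage(genus: str, community: Optional[int], idx: int) -> Lineage:
    if community is not None:
        return Lineage(kingdom="Bacteria", phylum=f"Phylum{community}",
                       class_=f"Class{community}", order=f"Order{community}",
                       family=f"Family{community}", genus=genus)
    return Lineage(kingdom="Bacteria", phylum=f"PhylumBg{idx % 2}",
                   class_=f"ClassBg{idx % 2}", order=f"OrderBg{idx % 3}",
                   family=f"FamilyBg{idx % 3}", genus=genus)


def simulate_counts(n_children: int = 40, n_genera: int = 60,
                    n_communities: int = 3, genera_per_community: int = 12,
                    depth: int = 50000, lam: float = 1.4, sigma: float = 0.2,
                    bridge_strength: float = 0.75,
                    background_sigma: float = 1.0, n_risk: Optional[int] = None,
                    subgroup_delta: float = 2.5, otu_level: bool = False,
                    max_otus_per_genus: int = 5, seed: Optional[int] = None
                    ) -> tuple[CountTable, SimTruth]:
    """Genus (or OTU) count table with planted co-varying communities.

    Per community c and child s a latent factor f_cs ~ N(0,1) is drawn;
    genus i of community c has log-expected abundance
    mu_i + lam*f_cs + N(0, sigma) with mu_i ~ N(-0.7, 0.4). Background
    genera are more abundant (mu_i ~ N(1, 1)) with independent
    N(0, background_sigma) noise, so the compositional denominator is
    dominated by stable background mass and closure does not glue the
    background together. Two "bridge" genera between each pair of adjacent
    communities load on both factors, which keeps the planted blocks in
    one connected component of the co-occurrence network. Within the last
    community, the first genus is boosted by ``subgroup_delta`` (log
    scale) in the planted risk subgroup and the second genus in the
    remaining children, so subject stratification has a recoverable
    signal. Expected proportions are the softmax over genera; counts are
    one multinomial draw of ``depth`` per child. With ``otu_level`` each
    genus is split into 2..max_otus_per_genus OTUs with Dirichlet weights
    and a handful of genus-unclassified OTUs is appended, so the
    preprocess stage is exercised.
    """
    n_bridges = 2 * max(n_communities - 1, 0)
    if genera_per_community * n_communities + n_bridges > n_genera:
        raise ValueError("communities plus bridges exceed n_genera")
    if seed is None:
        seed = 0
    rng = np.random.default_rng(seed)
    children = [f"child{i:02d}" for i in range(n_children)]
    samples = [f"{c}_s0" for c in children]

    genus_names: list[str] = []
    community_of: dict[str, int] = {}
    lineages: list[Lineage] = []
    for c in range(n_communities):
        for i in range(genera_per_community):
            g = f"C{c + 1}g{i:02d}"
            genus_names.append(g)
            community_of[g] = c
            lineages.append(_community_lineage(g, c, i))
    bridges = []
    for c in range(max(n_communities - 1, 0)):
        for rep in range(2):  # two bridges per adjacent pair for redundancy
            g = f"Br{c:02d}{'ab'[rep]}"
            genus_names.append(g)
            bridges.append((g, c, c + 1))
            lineages.append(_community_lineage(g, None, c))
    n_background = n_genera - len(genus_names)
    for i in range(n_background):
        g = f"Bg{i:02d}"
        genus_names.append(g)
        lineages.append(_community_lineage(g, None, i))

    if n_risk is None:
        n_risk = 13 if n_children >= 30 else max(2, n_children // 3)
    if n_risk > n_children:
        raise ValueError("n_risk cannot exceed n_children")
    factors = rng.normal(0.0, 1.0, size=(n_communities, n_children))
    risk_children = sorted(rng.choice(children, size=n_risk, replace=False).tolist())
    risk_mask = np.array([c in risk_children for c in children])

    bridge_of = {g: (a, b) for g, a, b in bridges}
    log_abund = np.empty((n_genera, n_children))
    for gi, g in enumerate(genus_names):
        if g in community_of:
            c = community_of[g]
            mu = rng.normal(-0.7, 0.4)
            log_abund[gi] = mu + lam * factors[c] + rng.normal(0.0, sigma, n_children)
        elif g in bridge_of:
            a, b = bridge_of[g]
            mu = rng.normal(-0.7, 0.4)
            load = bridge_strength * lam / np.sqrt(2.0)
            log_abund[gi] = mu + load * (factors[a] + factors[b]) + \
                rng.normal(0.0, sigma, n_children)
        else:
            mu = rng.normal(1.0, 1.0)
            log_abund[gi] = mu + rng.normal(0.0, background_sigma, n_children)
    # subgroup-specific composition shift inside the last community
    last = n_communities - 1
    g_risk = f"C{last + 1}g00"
    g_other = f"C{last + 1}g01"
    log_abund[genus_names.index(g_risk), risk_mask] += subgroup_delta
    log_abund[genus_names.index(g_other), ~risk_mask] += subgroup_delta

    expected = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    expected /= expected.sum(axis=0, keepdims=True)

    truth = SimTruth(seed=seed, children=children,
                     primary_samples=dict(zip(children, samples)),
                     genus_community=dict(community_of),
                     risk_children=risk_children, factors=factors)

    if not otu_level:
        counts = np.column_stack([
            rng.multinomial(depth, expected[:, s]) for s in range(n_children)])
        table = CountTable(genus_names, samples, counts, lineages)
        return table, truth

    # split genera into OTUs with Dirichlet weights; append unclassified OTUs
    otu_ids: list[str] = []
    otu_lineages: list[Lineage] = []
    otu_expected_rows: list[np.ndarray] = []
    counter = 0
    for gi, g in enumerate(genus_names):
        m = int(rng.integers(2, max_otus_per_genus + 1))
        w = rng.dirichlet(np.full(m, 2.0))
        for k in range(m):
            otu_ids.append(f"OTU{counter:05d}")
            counter += 1
            otu_lineages.append(lineages[gi])
            otu_expected_rows.append(expected[gi] * w[k])
    for k in range(5):  # genus-unclassified OTUs, dropped by aggregation
        otu_ids.append(f"OTU{counter:05d}")
        counter += 1
        otu_lineages.append(Lineage(kingdom="Bacteria", phylum="PhylumBg0",
                                    class_="ClassBg0", order="OrderBg0",
                                    family="FamilyBg0", genus=""))
        otu_expected_rows.append(np.full(n_children, 1e-4))
    otu_expected = np.vstack(otu_expected_rows)
    otu_expected /= otu_expected.sum(axis=0, keepdims=True)
    counts = np.column_stack([
        rng.multinomial(depth, otu_expected[:, s]) for s in range(n_children)])
    table = CountTable(otu_ids, samples, counts, otu_lineages)
    return table, truth


def simulate_metadata(truth: SimTruth, baseline_hazard: float = 6.5e-4,
                      hr: float = 2.8, censor_age_days: float = 1100,
                      diet_coupling: float = 1.0, n_followups: int = 3,
                      unknown_bf_fraction: float = 0.05,
                      seed: Optional[int] = None) -> list[SubjectRecord]:
    """Subject records consistent with the planted cohort structure.

    Seroconversion times are exponential with hazard
    baseline_hazard * hr^{I(risk subgroup)}, censored at
    ``censor_age_days``. Breast-feeding probability increases with the
    community-1 factor; solid-food introduction ages decrease with the
    community-2 factor. The primary sample age is Uniform(91, 275);
    follow-ups are spaced 200 days apart (outside the selection window).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = np.random.default_rng(seed)
    records = []
    n_comm = truth.factors.shape[0]
    for ci, child in enumerate(truth.children):
        risk = child in truth.risk_children
        hazard = baseline_hazard * (hr if risk else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        event = t_event <= censor_age_days
        outcome = float(min(t_event, censor_age_days))

        f_bf = truth.factors[0, ci]
        f_food = truth.factors[1 % n_comm, ci]
        p_bf = 1.0 / (1.0 + np.exp(-diet_coupling * f_bf))
        if rng.uniform() < unknown_bf_fraction:
            bf = "unknown"
        else:
            bf = "yes" if rng.uniform() < p_bf else "no"
        intro = {}
        for j, item in enumerate(("potato", "meat", "vegetables", "fruit", "formula")):
            age = 160.0 + 15.0 * j + rng.normal(0.0, 20.0) \
                - 60.0 * diet_coupling * f_food
            intro[item] = float(max(age, 30.0))

        primary_age = float(rng.uniform(91, 275))
        ages = [primary_age] + [primary_age + 200.0 * (k + 1)
                                for k in range(n_followups)]
        for s, age in enumerate(ages):
            records.append(SubjectRecord(
                child_id=child,
                sample_id=f"{child}_s{s}",
                sample_age_days=age,
                breastfeeding_at_sample=bf if s == 0 else "no",
                intro_age_days=dict(intro),
                outcome_age_days=max(outcome, 1.0),
                event=bool(event),
            ))
    truth.true_hr = hr
    truth.diet_coupling = diet_coupling
    return records


def simulate_ko(truth: SimTruth, shift: float = 0.5,
                seed: Optional[int] = None) -> KOTable:
    """KO table with the but components scaled by ``shift`` in the risk group."""
    if shift <= 0:
        raise ValueError("shift must be positive")
    rng = np.random.default_rng(seed)
    samples = [truth.primary_samples[c] for c in truth.children]
    ko_ids = ["K00634", "K00929", "K01034", "K01035"]
    values = np.exp(rng.normal(0.0, KO_SIGMA, size=(4, len(samples))))
    risk = np.array([c in truth.risk_children for c in truth.children])
    values[2:, risk] *= shift  # K01034/K01035 are the but components
    truth.ko_shift = shift
    return KOTable(ko_ids, samples, values)


def simulate_tree(genus_names: Sequence[str], seed: Optional[int] = None
                  ) -> skbio.TreeNode:
    """Random binary genus tree via sequential joins, exponential lengths."""
    names = list(genus_names)
    if len(names) < 2:
        raise ValueError("need at least two genus names")
    if len(set(names)) != len(names):
        raise ValueError("duplicate genus names")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=n, length=float(rng.exponential(1.0)) + 1e-6)
             for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.exponential(1.0)) + 1e-6)
        parent.extend([left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def evaluate_recovery(report: dict, truth: SimTruth, ko: Optional[KOTable] = None
                      ) -> dict:
    """Score a pipeline report against the generator's ground truth.

    Returns: selected community count, adjusted Rand index of the detected
    community labels vs the planted blocks (over planted genera that were
    assigned), ARI of the subject clustering on the truth-matched last
    community vs the risk subgroup, the hazard ratio estimated for the
    cluster best overlapping the true risk set, and (if ``ko`` is given)
    the but/buk comparison p-value for that estimated grouping.
    """
    from collections import Counter

    from sklearn.metrics import adjusted_rand_score

    out = {"k": report["communities"]["k"], "community_ari": 0.0,
           "strat_ari": None, "hr": None, "butyrate_p": None}
    assignment = report["communities"]["assignment"]
    detected = {g: c for g, c in assignment.items() if c is not None}
    planted = [g for g in detected if g in truth.genus_community]
    if planted:
        out["community_ari"] = float(adjusted_rand_score(
            [truth.genus_community[g] for g in planted],
            [detected[g] for g in planted]))
    last = max(truth.genus_community.values())
    overlap = Counter(detected[g] for g in planted
                      if truth.genus_community[g] == last)
    if not overlap:
        return out
    comm = str(overlap.most_common(1)[0][0])
    strat = report["stratification"].get(comm)
    if strat is None:
        return out
    sample_child = {s: c for c, s in truth.primary_samples.items()}
    cluster_of: dict[str, str] = {}
    for label, samples in strat["clusters"].items():
        for s in samples:
            cluster_of[sample_child[s]] = label
    children = sorted(cluster_of)
    risk = set(truth.risk_children)
    out["strat_ari"] = float(adjusted_rand_score(
        [int(c in risk) for c in children],
        [cluster_of[c] for c in children]))
    best_label = max(strat["clusters"], key=lambda l: len(
        {sample_child[s] for s in strat["clusters"][l]} & risk))
    surv = report["associations"]["communities"][comm]["clusters"][
        best_label].get("survival", {})
    if isinstance(surv, dict) and "hr" in surv:
        out["hr"] = surv["hr"]
    if ko is not None:
        from .butyrate import but_buk_ratio, compare_ratio

        est_risk = {sample_child[s] for s in strat["clusters"][best_label]}
        labels = ["risk" if c in est_risk else "other" for c in truth.children]
        if len(set(labels)) == 2:
            out["butyrate_p"] = compare_ratio(but_buk_ratio(ko), labels)["p"]
    return out


def write_bundle(outdir, seed: int = 0, otu_level: bool = True,
                 counts_kwargs: Optional[dict] = None,
                 metadata_kwargs: Optional[dict] = None,
                 ko_kwargs: Optional[dict] = None) -> SimTruth:
    """Write counts.tsv, metadata.csv, tree.nwk, ko.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_counts(otu_level=otu_level, seed=seed,
                                   **(counts_kwargs or {}))
    records = simulate_metadata(truth, seed=seed + 1, **(metadata_kwargs or {}))
    ko = simulate_ko(truth, seed=seed + 2, **(ko_kwargs or {}))
    genus_names = sorted({lin.genus for lin in table.lineages if lin.genus})
    tree = simulate_tree(genus_names, seed=seed + 3)
    write_count_table(table, outdir / "counts.tsv")
    write_metadata(records, outdir / "metadata.csv")
    write_ko_table(ko, outdir / "ko.tsv")
    tree.write(str(outdir / "tree.nwk"))
    truth.to_json(outdir / "truth.json")
    return truth
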