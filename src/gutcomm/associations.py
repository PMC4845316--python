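"""Diet covariates, contingency tests, enrichment, and survival comparisons.

Diet complexity counts introduced items among potato, meat, vegetables,
fruit and formula at the sample date and is dichotomized at >3 vs <=3.
Unknown breast-feeding status is excluded from 2x2 tables. Survival is
compared with a Kaplan-Meier product-limit estimate, a log-rank test, and
a single-covariate proportional-hazards hazard ratio (Efron ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io import DIET_ITEMS, Lineage, SubjectRecord
from .stability import UNASSIGNED


@dataclass(frozen=True)
class DietStatus:
    child_id: str
    breastfed_at_sample: str  # "yes" | "no" | "unknown"
    n_ingredients: int
    complexity_class: str  # ">3" | "<=3"


@dataclass
class SurvivalInput:
    """Per-child time-to-event data with a group label."""

    child_ids: list[str]
    times: np.ndarray
    events: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if np.any(self.times <= 0):
            raise ValueError("nonpositive survival time")

    @property
    def group_levels(self) -> list[str]:
        return sorted(set(self.groups))


def food_complexity(record: SubjectRecord) -> DietStatus:
    """Count diet items introduced on or before the sample date."""
    n = sum(1 for item in DIET_ITEMS
            if item in record.intro_age_days
            and record.intro_age_days[item] <= record.sample_age_days)
    return DietStatus(record.child_id, record.breastfeeding_at_sample, n,
                      ">3" if n >= 4 else "<=3")


def fisher_exact(table, alternative: str = "two_sided") -> float:
    """Fisher's exact test on a 2x2 table of nonnegative integer counts."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0) or \
            not np.allclose(table, np.round(table)):
        raise ValueError("need a 2x2 table of nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 margins; p set to 1", stacklevel=2)
        return 1.0
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    return float(stats.fisher_exact(np.round(table).astype(int), alternative=alt).pvalue)


def contingency_table(labels_a: Sequence[str], labels_b: Sequence[str],
                      a_levels: tuple[str, str], b_levels: tuple[str, str]
                      ) -> np.ndarray:
    """2x2 counts; items whose label is outside the stated levels are excluded."""
    table = np.zeros((2, 2), dtype=int)
    for a, b in zip(labels_a, labels_b):
        if a in a_levels and b in b_levels:
            table[a_levels.index(a), b_levels.index(b)] += 1
    return table


def breastfeeding_table(statuses: Sequence[DietStatus], groups: Sequence[str],
                        group_levels: tuple[str, str]) -> np.ndarray:
    """Still vs no-longer breast-fed by subgroup; unknown status excluded."""
    return contingency_table(
        [s.breastfed_at_sample for s in statuses], list(groups),
        ("yes", "no"), group_levels)


def complexity_table(statuses: Sequence[DietStatus], groups: Sequence[str],
                     group_levels: tuple[str, str]) -> np.ndarray:
    return contingency_table(
        [s.complexity_class for s in statuses], list(groups),
        (">3", "<=3"), group_levels)


def taxon_enrichment(assignment: dict[str, int], lineages: dict[str, Lineage],
                     rank: str = "order") -> pd.DataFrame:
    """Per-community taxon composition with two-sided Fisher enrichment p.

    Percentage = genera of the taxon in the community / genera in the
    community; p compares the community against all other communities
    pooled. Genera lacking the rank are pooled under "unclassified".
    """
    assigned = {g: c for g, c in assignment.items() if c != UNASSIGNED}
    taxon_of = {}
    for g in assigned:
        name = lineages[g].rank(rank) if g in lineages else ""
        taxon_of[g] = name if name else "unclassified"
    rows = []
    communities = sorted(set(assigned.values()))
    for comm in communities:
        members = [g for g, c in assigned.items() if c == comm]
        others = [g for g, c in assigned.items() if c != comm]
        taxa = sorted({taxon_of[g] for g in members})
        for taxon in taxa:
            in_comm = sum(taxon_of[g] == taxon for g in members)
            in_others = sum(taxon_of[g] == taxon for g in others)
            table = np.array([[in_comm, len(members) - in_comm],
                              [in_others, len(others) - in_others]])
            rows.append({
                "community": comm,
                "taxon": taxon,
                "rank": rank,
                "n_genera": in_comm,
                "percent": 100.0 * in_comm / len(members),
                "p": fisher_exact(table, "two_sided"),
            })
    return pd.DataFrame(rows)


def km_curve(surv: SurvivalInput) -> dict[str, pd.DataFrame]:
    """Product-limit survival per group.

    At tied times the events are processed before censorings leave the
    risk set. Rows are emitted at event times (plus a t=0 row).
    """
    out = {}
    for level in surv.group_levels:
        mask = np.array([g == level for g in surv.groups])
        times = surv.times[mask]
        events = surv.events[mask]
        rows = [{"time": 0.0, "n_risk": int(mask.sum()), "n_events": 0, "survival": 1.0}]
        s = 1.0
        for t in np.unique(times):
            n_risk = int((times >= t).sum())
            d = int(((times == t) & events).sum())
            if d > 0:
                s *= 1.0 - d / n_risk
                rows.append({"time": float(t), "n_risk": n_risk,
                             "n_events": d, "survival": s})
        out[level] = pd.DataFrame(rows)
    return out


def hazard_ratio(surv: SurvivalInput, reference_group: str) -> dict:
    """Two-group hazard ratio (Efron ties) with Wald 95% CI and log-rank p."""
    levels = surv.group_levels
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if reference_group not in levels:
        raise ValueError(f"unknown reference group {reference_group!r}")
    if not surv.events.any():
        raise ValueError("no events in data")
    other = [g for g in levels if g != reference_group][0]
    indicator = np.array([1.0 if g == other else 0.0 for g in surv.groups])

    mask1 = indicator == 1
    lr = logrank_test(surv.times[mask1], surv.times[~mask1],
                      event_observed_A=surv.events[mask1],
                      event_observed_B=surv.events[~mask1])

    events_by_group = {g: int(surv.events[np.array([x == g for x in surv.groups])].sum())
                       for g in levels}
    if 0 in events_by_group.values():
        warnings.warn("all events in one group: monotone likelihood, HR unbounded",
                      stacklevel=2)
        hr = np.inf if events_by_group[other] > 0 else 0.0
        return {"hr": hr, "ci_low": np.nan, "ci_high": np.nan,
                "p_wald": np.nan, "p_logrank": float(lr.p_value),
                "group": other, "reference": reference_group}

    df = pd.DataFrame({"time": surv.times, "event": surv.events.astype(int),
                       "x": indicator})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["x"]
    return {"hr": float(np.exp(row["coef"])),
            "ci_low": float(np.exp(row["coef lower 95%"])),
            "ci_high": float(np.exp(row["coef upper 95%"])),
            "p_wald": float(row["p"]),
            "p_logrank": float(lr.p_value),
            "group": other, "reference": reference_group}


def group_abundance_test(values: Sequence[float], groups: Sequence[str],
                         group_levels: Optional[tuple[str, str]] = None) -> float:
    """Two-sided Wilcoxon rank-sum p between two groups of abundances.

    Exact enumeration when both groups have n <= 10 and there are no
    ties; otherwise the tie-corrected normal approximation.
    """
    values = np.asarray(values, dtype=float)
    groups = list(groups)
    if group_levels is None:
        levels = sorted(set(groups))
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        group_levels = (levels[0], levels[1])
    x = values[[g == group_levels[0] for g in groups]]
    y = values[[g == group_levels[1] for g in groups]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group is empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def abundance_trajectory(abundance_row: Sequence[float], sample_ids: Sequence[str],
                         records: Sequence[SubjectRecord],
                         group_of_child: dict[str, str],
                         age_bins: Sequence[float]) -> pd.DataFrame:
    """Group mean/sd of one genus's abundance per age bin.

    ``age_bins`` are bin edges in days; bin i covers [edge_i, edge_{i+1}).
    Samples of children without a group label are skipped.
    """
    values = dict(zip(sample_ids, np.asarray(abundance_row, dtype=float)))
    age_of = {r.sample_id: r.sample_age_days for r in records}
    child_of = {r.sample_id: r.child_id for r in records}
    edges = np.asarray(age_bins, dtype=float)
    rows = []
    groups = sorted(set(group_of_child.values()))
    for b in range(len(edges) - 1):
        for grp in groups:
            vals = [v for sid, v in values.items()
                    if sid in age_of
                    and edges[b] <= age_of[sid] < edges[b + 1]
                    and group_of_child.get(child_of[sid]) == grp]
            rows.append({
                "bin_low_days": edges[b], "bin_high_days": edges[b + 1],
                "group": grp, "n": len(vals),
                "mean": float(np.mean(vals)) if vals else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)
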