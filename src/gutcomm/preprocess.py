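"""OTU filtering, genus aggregation, relative abundances, sample selection.

Default thresholds: an OTU is kept when it reaches >= 50 reads in >= 10
samples; genera contributing < 0.01 % of total reads are dropped; per child
the sample closest to 183 days within the closed window [91, 275] days is
retained (ties go to the younger sample).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CountTable, Lineage, SubjectRecord

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Genus-by-sample proportions; every column sums to one."""

    genus_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genus_ids), len(self.sample_ids)):
            raise ValueError("abundance matrix shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, genus: str) -> np.ndarray:
        return self.values[self.genus_ids.index(genus)]

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(list(self.genus_ids), list(sample_ids), self.values[:, idx])

    def select_genera(self, genus_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.genus_ids.index(g) for g in genus_ids]
        return AbundanceTable(list(genus_ids), list(self.sample_ids), self.values[idx, :])


def filter_otus(table: CountTable, min_reads: int = 50, min_samples: int = 10) -> CountTable:
    """Keep OTUs present with >= ``min_reads`` reads in >= ``min_samples`` samples."""
    keep = (table.counts >= min_reads).sum(axis=1) >= min_samples
    n_before, n_after = len(table.feature_ids), int(keep.sum())
    logger.info("filter_otus: %d OTUs before, %d after (>=%d reads in >=%d samples)",
                n_before, n_after, min_reads, min_samples)
    if n_after == 0:
        warnings.warn("filter_otus removed every OTU", stacklevel=2)
    lineages = None
    if table.lineages is not None:
        lineages = [lin for lin, k in zip(table.lineages, keep) if k]
    return CountTable([f for f, k in zip(table.feature_ids, keep) if k],
                      list(table.sample_ids), table.counts[keep], lineages)


def aggregate_to_genus(table: CountTable) -> CountTable:
    """Sum counts of OTUs sharing a genus; drop OTUs unclassified at genus.

    The returned table carries one representative lineage per genus
    (ranks above genus taken from the first member OTU).
    """
    if table.lineages is None:
        raise ValueError("aggregate_to_genus requires lineages")
    classified = [i for i, lin in enumerate(table.lineages) if lin.classified_at_genus]
    if not classified:
        raise ValueError("no OTU classified at genus level")
    logger.info("aggregate_to_genus: %d classified OTUs aggregated (of %d)",
                len(classified), len(table.feature_ids))
    genera: list[str] = []
    rep_lineage: dict[str, Lineage] = {}
    rows: dict[str, np.ndarray] = {}
    for i in classified:
        g = table.lineages[i].genus
        if g not in rows:
            genera.append(g)
            rows[g] = np.zeros(len(table.sample_ids), dtype=table.counts.dtype)
            rep_lineage[g] = table.lineages[i]
        rows[g] = rows[g] + table.counts[i]
    counts = np.vstack([rows[g] for g in genera])
    return CountTable(genera, list(table.sample_ids), counts,
                      [rep_lineage[g] for g in genera])


def relative_abundance(table: CountTable) -> AbundanceTable:
    """Divide each sample column by its sum. All-zero samples are an error."""
    sums = table.counts.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}")
    return AbundanceTable(list(table.feature_ids), list(table.sample_ids),
                          table.counts / sums)


def filter_rare_genera(table: CountTable, frac: float = 1e-4) -> CountTable:
    """Drop genera whose share of the grand total read count is < ``frac``.

    The boundary is kept: a genus at exactly ``frac`` survives.
    """
    total = table.counts.sum()
    if total == 0 or len(table.feature_ids) == 0:
        return table
    keep = table.counts.sum(axis=1) / total >= frac
    lineages = None
    if table.lineages is not None:
        lineages = [lin for lin, k in zip(table.lineages, keep) if k]
    logger.info("filter_rare_genera: %d genera before, %d after (frac=%g)",
                len(table.feature_ids), int(keep.sum()), frac)
    return CountTable([f for f, k in zip(table.feature_ids, keep) if k],
                      list(table.sample_ids), table.counts[keep], lineages)


def select_window_samples(records: Sequence[SubjectRecord],
                          window_days: tuple[float, float] = (91, 275),
                          target_days: float = 183) -> dict[str, str]:
    """Pick per child the in-window sample closest to the target age.

    Children without a sample inside the closed window are absent from the
    result. Ties in |age - target| are broken toward the younger sample.
    """
    lo, hi = window_days
    best: dict[str, tuple[float, float, str]] = {}
    for rec in records:
        age = rec.sample_age_days
        if not (lo <= age <= hi):
            continue
        key = (abs(age - target_days), age, rec.sample_id)
        if rec.child_id not in best or key < best[rec.child_id]:
            best[rec.child_id] = key
    return {child: sid for child, (_, _, sid) in best.items()}
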