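"""Core record types and plain-text readers/writers.

All tabular artifacts are plain TSV/CSV; trees are newick. Ages are stored
in days throughout (6 months = 183 days; 1 month = 30.44 days).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import skbio

DAYS_PER_MONTH = 30.44
SIX_MONTHS_DAYS = 183

#: rank prefixes in canonical (root-to-tip) order
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: metadata columns that must be present
METADATA_REQUIRED = ("child_id", "sample_id", "sample_age_days", "outcome_age_days", "event")
DIET_ITEMS = ("potato", "meat", "vegetables", "fruit", "formula")

TAXONOMY_COLUMN_ALIASES = {"taxonomy", "lineage", "taxon"}


class FormatError(ValueError):
    """Raised when an input artifact violates its documented format."""


@dataclass(frozen=True)
class Lineage:
    """Greengenes-style taxonomic path, kingdom down to genus (species optional)."""

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def rank(self, name: str) -> str:
        key = "class_" if name == "class" else name
        return getattr(self, key)

    @property
    def classified_at_genus(self) -> bool:
        return self.genus != ""

    def __str__(self) -> str:
        values = [self.kingdom, self.phylum, self.class_, self.order,
                  self.family, self.genus, self.species]
        parts = [f"{p}__{v}" for p, v in zip(RANK_PREFIXES, values)]
        if self.species == "":
            parts = parts[:6]
        return "; ".join(parts)


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-separated ``k__...; p__...; ...; g__...`` string.

    Missing or empty ``g__`` token means unclassified at genus. Rank
    prefixes must appear in canonical order; violations raise FormatError.
    """
    values = dict.fromkeys(RANK_PREFIXES, "")
    last_idx = -1
    for token in str(text).split(";"):
        token = token.strip()
        if token == "":
            continue
        if len(token) < 3 or token[1:3] != "__":
            raise FormatError(f"malformed lineage token {token!r} in {text!r}")
        prefix, name = token[0].lower(), token[3:].strip()
        if prefix not in RANK_PREFIXES:
            raise FormatError(f"unknown rank prefix {prefix!r} in {text!r}")
        idx = RANK_PREFIXES.index(prefix)
        if idx <= last_idx:
            raise FormatError(f"rank prefixes out of order in {text!r}")
        last_idx = idx
        values[prefix] = name
    return Lineage(kingdom=values["k"], phylum=values["p"], class_=values["c"],
                   order=values["o"], family=values["f"], genus=values["g"],
                   species=values["s"])


@dataclass
class CountTable:
    """Feature-by-sample nonnegative count matrix with optional lineages."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineages: Optional[list[Lineage]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("negative counts")
        if self.lineages is not None and len(self.lineages) != len(self.feature_ids):
            raise FormatError("lineage list length does not match features")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def lineage_of(self, feature_id: str) -> Optional[Lineage]:
        if self.lineages is None:
            return None
        return self.lineages[self.feature_ids.index(feature_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.feature_ids), list(sample_ids),
                          self.counts[:, idx], self.lineages)


@dataclass(frozen=True)
class SubjectRecord:
    """One stool sample of one child, with diet history and outcome."""

    child_id: str
    sample_id: str
    sample_age_days: float
    breastfeeding_at_sample: str  # "yes" | "no" | "unknown"
    intro_age_days: dict  # item -> age in days; absent item means not introduced
    outcome_age_days: float
    event: bool

    def __post_init__(self) -> None:
        if self.outcome_age_days <= 0:
            raise FormatError(f"outcome_age_days must be > 0 (child {self.child_id})")
        for item, age in self.intro_age_days.items():
            if age < 0:
                raise FormatError(f"negative intro age for {item} (child {self.child_id})")
        if self.breastfeeding_at_sample not in ("yes", "no", "unknown"):
            raise FormatError(f"bad breastfeeding code {self.breastfeeding_at_sample!r}")


@dataclass
class KOTable:
    """KEGG-ortholog by sample relative abundances."""

    ko_ids: list[str]
    sample_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(set(self.ko_ids)) != len(self.ko_ids):
            raise FormatError("duplicate KO ids")
        if self.abundances.shape != (len(self.ko_ids), len(self.sample_ids)):
            raise FormatError("KO matrix shape mismatch")
        if self.abundances.size and self.abundances.min() < 0:
            raise FormatError("negative KO abundance")

    def row(self, ko_id: str) -> np.ndarray:
        return self.abundances[self.ko_ids.index(ko_id)]


def read_count_table(path, integer: bool = True) -> CountTable:
    """Read a feature-by-sample TSV.

    Layout: header row ``#FeatureID<TAB>sample1...<TAB>taxonomy`` where the
    final taxonomy column (named any of taxonomy/lineage/Taxon, case
    insensitive) is optional. Counts must be nonnegative; integers unless
    ``integer=False`` (genus-level derived tables may be real-valued).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature column and at least one sample column")
    df.columns = [str(c).lstrip("#") for c in df.columns]
    raw = pd.read_csv(path, sep="\t", dtype=str, header=None, nrows=1)
    header = [str(c).lstrip("#") for c in raw.iloc[0]]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"{path}: duplicated column header(s): {dupes}")

    feature_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise FormatError(f"{path}: duplicated feature id(s): {dupes}")

    lineages = None
    data = df.iloc[:, 1:]
    if data.columns[-1].strip().lower() in TAXONOMY_COLUMN_ALIASES:
        lineages = [parse_lineage(t) for t in data.iloc[:, -1].fillna("")]
        data = data.iloc[:, :-1]
    sample_ids = [str(c) for c in data.columns]

    try:
        counts = data.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count: {exc}") from exc
    if np.isnan(counts).any():
        r, c = np.argwhere(np.isnan(counts))[0]
        raise FormatError(f"{path}: missing count at row {feature_ids[r]}, column {sample_ids[c]}")
    if counts.min() < 0:
        r, c = np.argwhere(counts < 0)[0]
        raise FormatError(f"{path}: negative count at row {feature_ids[r]}, column {sample_ids[c]}")
    if integer:
        if not np.allclose(counts, np.round(counts)):
            r, c = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
            raise FormatError(
                f"{path}: non-integer count at row {feature_ids[r]}, column {sample_ids[c]}")
        counts = np.round(counts).astype(np.int64)
    return CountTable(feature_ids, sample_ids, counts, lineages)


def write_count_table(table: CountTable, path) -> None:
    """Write a CountTable as ``#FeatureID<TAB>samples...<TAB>taxonomy`` TSV."""
    df = pd.DataFrame(table.counts, index=table.feature_ids, columns=table.sample_ids)
    if table.lineages is not None:
        df["taxonomy"] = [str(lin) for lin in table.lineages]
    df.index.name = "#FeatureID"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> list[SubjectRecord]:
    """Read the per-sample subject metadata CSV.

    Columns: child_id, sample_id, sample_age_days, breastfeeding (0/1/empty),
    intro_<item>_days for each diet item (empty = never introduced),
    outcome_age_days, event (0/1). Empty breastfeeding is coded "unknown".
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {missing}")
    records = []
    for rownum, row in df.iterrows():
        child = row["child_id"]
        if pd.isna(child) or str(child).strip() == "":
            raise FormatError(f"{path}: row {rownum}: empty child_id")
        bf_raw = row.get("breastfeeding")
        if bf_raw is None or pd.isna(bf_raw) or str(bf_raw).strip() == "":
            bf = "unknown"
        else:
            bf = "yes" if float(bf_raw) != 0 else "no"
        intro = {}
        for item in DIET_ITEMS:
            col = f"intro_{item}_days"
            val = row.get(col)
            if val is not None and not pd.isna(val) and str(val).strip() != "":
                intro[item] = float(val)
        event_raw = row["event"]
        event = bool(int(float(event_raw))) if not pd.isna(event_raw) else False
        outcome_raw = row["outcome_age_days"]
        if pd.isna(outcome_raw) or str(outcome_raw).strip() == "":
            raise FormatError(
                f"{path}: row {rownum}: event flag without outcome age" if event
                else f"{path}: row {rownum}: missing outcome_age_days")
        records.append(SubjectRecord(
            child_id=str(child),
            sample_id=str(row["sample_id"]),
            sample_age_days=float(row["sample_age_days"]),
            breastfeeding_at_sample=bf,
            intro_age_days=intro,
            outcome_age_days=float(outcome_raw),
            event=event,
        ))
    return records


def write_metadata(records: Sequence[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "child_id": r.child_id,
            "sample_id": r.sample_id,
            "sample_age_days": r.sample_age_days,
            "breastfeeding": {"yes": 1, "no": 0, "unknown": ""}[r.breastfeeding_at_sample],
            "outcome_age_days": r.outcome_age_days,
            "event": int(r.event),
        }
        for item in DIET_ITEMS:
            row[f"intro_{item}_days"] = r.intro_age_days.get(item, "")
        rows.append(row)
    cols = ["child_id", "sample_id", "sample_age_days", "breastfeeding"] + \
        [f"intro_{i}_days" for i in DIET_ITEMS] + ["outcome_age_days", "event"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def read_newick(source) -> skbio.TreeNode:
    """Read a rooted newick tree; absent branch lengths default to 1.0.

    Raises FormatError on unbalanced parentheses or duplicate leaf names.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in newick string")
    try:
        tree = skbio.TreeNode.read(_io.StringIO(text))
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate leaf names in tree: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0
        elif node.length < 0:
            raise FormatError(f"negative branch length at {node.name}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_ko_table(path) -> KOTable:
    """Read a KO-by-sample TSV (``#KO<TAB>samples...``); values are floats >= 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [str(i) for i in df.index]
    if len(set(df.index)) != len(df.index):
        raise FormatError(f"{path}: duplicate KO ids")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing KO abundance value")
    return KOTable(list(df.index), [str(c) for c in df.columns], values)


def write_ko_table(table: KOTable, path) -> None:
    df = pd.DataFrame(table.abundances, index=table.ko_ids, columns=table.sample_ids)
    df.index.name = "#KO"
    df.to_csv(path, sep="\t")
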