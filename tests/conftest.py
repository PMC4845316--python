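import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gutcomm.io import CountTable, Lineage, SubjectRecord, parse_lineage


def make_lineage(genus, order="OrderA", phylum="PhylumA"):
    return Lineage(kingdom="Bacteria", phylum=phylum, class_="ClassA",
                   order=order, family="FamilyA", genus=genus)


@pytest.fixture
def toy_counts():
    """6 OTUs over 3 samples; 4 distinct genera, one unclassified OTU."""
    lineages = [
        make_lineage("Alpha"),
        make_lineage("Alpha"),
        make_lineage("Beta"),
        make_lineage("Gamma", order="OrderB"),
        make_lineage("Delta", order="OrderB", phylum="PhylumB"),
        make_lineage(""),
    ]
    counts = np.array([
        [3, 10, 0],
        [4, 0, 2],
        [5, 5, 5],
        [0, 1, 9],
        [7, 7, 7],
        [2, 2, 2],
    ])
    return CountTable([f"OTU{i}" for i in range(6)], ["s1", "s2", "s3"],
                      counts, lineages)


@pytest.fixture
def four_leaf_newick():
    return "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def records_6mo():
    def rec(child, sample, age, bf="yes", event=False, outcome=900.0, intro=None):
        return SubjectRecord(child_id=child, sample_id=sample, sample_age_days=age,
                             breastfeeding_at_sample=bf,
                             intro_age_days=intro or {}, outcome_age_days=outcome,
                             event=event)
    return [
        rec("c1", "c1_a", 120), rec("c1", "c1_b", 185), rec("c1", "c1_c", 400),
        rec("c2", "c2_a", 300), rec("c2", "c2_b", 400),
        rec("c3", "c3_a", 150), rec("c3", "c3_b", 216),
    ]


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic cohort shared by slower tests."""
    from gutcomm import synthetic

    table, truth = synthetic.simulate_counts(seed=0, otu_level=True)
    records = synthetic.simulate_metadata(truth, seed=1000)
    ko = synthetic.simulate_ko(truth, seed=3000)
    genus_names = sorted({lin.genus for lin in table.lineages if lin.genus})
    tree = synthetic.simulate_tree(genus_names, seed=4000)
    return table, truth, records, ko, tree
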