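"""but/buk butyrate-pathway ratio from KEGG-ortholog tables.

but = butyryl-CoA:acetate CoA-transferase route (K01034 + K01035);
buk = phosphotransbutyrylase + butyrate kinase route (K00634 + K00929).
The per-sample ratio but/buk is compared between subject groups with a
two-sided rank-sum test.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .associations import group_abundance_test
from .io import KOTable

logger = logging.getLogger(__name__)

BUT_KOS = ("K01034", "K01035")
BUK_KOS = ("K00634", "K00929")


def but_buk_ratio(ko: KOTable) -> pd.DataFrame:
    """Per-sample but and buk abundances and their ratio.

    A zero buk denominator is replaced by half the smallest nonzero buk
    abundance across samples (logged); all-zero buk everywhere is an error.
    """
    missing = [k for k in BUT_KOS + BUK_KOS if k not in ko.ko_ids]
    if missing:
        raise ValueError(f"KO table is missing required row(s): {missing}")
    but = ko.row(BUT_KOS[0]) + ko.row(BUT_KOS[1])
    buk = ko.row(BUK_KOS[0]) + ko.row(BUK_KOS[1])
    if np.all(buk == 0):
        raise ValueError("buk abundances are zero in every sample")
    denom = buk.astype(float).copy()
    if np.any(denom == 0):
        floor = 0.5 * denom[denom > 0].min()
        n_zero = int((denom == 0).sum())
        logger.info("but_buk_ratio: %d zero buk denominator(s) replaced by %g",
                    n_zero, floor)
        denom[denom == 0] = floor
    return pd.DataFrame({
        "sample_id": ko.sample_ids,
        "but_abundance": but,
        "buk_abundance": buk,
        "ratio": but / denom,
    })


def compare_ratio(ratios: pd.DataFrame, group_labels: Sequence[str]) -> dict:
    """Two-sided rank-sum comparison of the ratio between two groups."""
    groups = list(group_labels)
    if len(groups) != len(ratios):
        raise ValueError("one group label per sample required")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    p = group_abundance_test(ratios["ratio"].to_numpy(), groups,
                             (levels[0], levels[1]))
    medians = {lvl: float(np.median(
        ratios["ratio"].to_numpy()[[g == lvl for g in groups]])) for lvl in levels}
    direction = min(medians, key=medians.get)
    return {"p": p, "medians": medians, "lower_group": direction}
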