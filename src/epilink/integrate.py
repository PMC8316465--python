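"""Expression / histone-mark congruence — the integrative step.

A differentially expressed gene is *congruent* when at least one histone
mark changes in the direction its polarity predicts: for an upregulated
gene, any active mark (H3K4me3 / H3K4me1 / H3K27ac) significantly increased
or the repressive mark H3K27me3 significantly decreased; mirrored for
downregulated genes.  Non-significant occupancy never supports a call.
The minimum number of supporting marks is a knob (default 1).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .occupancy import mark_polarity

logger = logging.getLogger(__name__)


def congruence_classify(
    de_table: pd.DataFrame,
    occupancy_tables: Mapping[str, pd.DataFrame],
    min_supporting_marks: int = 1,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Classify each DE gene as congruent or not with its mark changes.

    Parameters
    ----------
    de_table
        Output of :func:`epilink.diffexpr.classify_de` (indexed by gene id,
        with a ``call`` column).
    occupancy_tables
        Mark name -> occupancy table (indexed by gene id, with
        ``direction_call``).

    Returns
    -------
    calls, summary
        ``calls`` has one row per DE (up/down) gene with its supporting
        marks; ``summary`` reports n_up, n_up_congruent, n_down,
        n_down_congruent.
    """
    if min_supporting_marks < 1:
        raise ValueError("min_supporting_marks must be >= 1")
    for mark in occupancy_tables:
        mark_polarity(mark)

    de_genes = de_table.index
    n_extra = 0
    for mark, tab in occupancy_tables.items():
        n_extra += int((~tab.index.isin(de_genes)).sum())
    if n_extra:
        logger.info("%d occupancy rows for genes absent from the DE table ignored", n_extra)

    rows: List[dict] = []
    for gene_id, de_row in de_table.iterrows():
        de_call = de_row["call"]
        if de_call not in ("up", "down"):
            continue
        expr_sign = 1 if de_call == "up" else -1
        supporting: List[Tuple[str, str]] = []
        for mark, tab in occupancy_tables.items():
            if gene_id not in tab.index:
                continue
            direction = tab.loc[gene_id, "direction_call"]
            if direction == "ns":
                continue
            occ_sign = 1 if direction == "increased" else -1
            if occ_sign * mark_polarity(mark) == expr_sign:
                supporting.append((mark, direction))
        rows.append(
            {
                "gene_id": gene_id,
                "de_call": de_call,
                "supporting_marks": supporting,
                "n_supporting": len(supporting),
                "congruent": len(supporting) >= min_supporting_marks,
            }
        )
    calls = pd.DataFrame(rows, columns=["gene_id", "de_call", "supporting_marks", "n_supporting", "congruent"])
    if not calls.empty:
        calls = calls.set_index("gene_id")
    summary = {
        "n_up": int((calls["de_call"] == "up").sum()) if not calls.empty else 0,
        "n_up_congruent": int(((calls["de_call"] == "up") & calls["congruent"]).sum()) if not calls.empty else 0,
        "n_down": int((calls["de_call"] == "down").sum()) if not calls.empty else 0,
        "n_down_congruent": int(((calls["de_call"] == "down") & calls["congruent"]).sum()) if not calls.empty else 0,
    }
    return calls, summary


def summarize_integration(
    calls: pd.DataFrame,
    occupancy_tables: Optional[Mapping[str, pd.DataFrame]] = None,
) -> Dict[str, object]:
    """Summarize congruence calls: counts, per-mark support frequencies and,
    when occupancy tables are given, a heatmap-ready genes x marks matrix of
    signed log2 occupancy ratios for the congruent genes."""
    report: Dict[str, object] = {}
    if calls.empty:
        report["counts"] = {"n_up": 0, "n_up_congruent": 0, "n_down": 0, "n_down_congruent": 0}
        report["mark_support_frequency"] = {}
        return report
    report["counts"] = {
        "n_up": int((calls["de_call"] == "up").sum()),
        "n_up_congruent": int(((calls["de_call"] == "up") & calls["congruent"]).sum()),
        "n_down": int((calls["de_call"] == "down").sum()),
        "n_down_congruent": int(((calls["de_call"] == "down") & calls["congruent"]).sum()),
    }
    freq: Dict[str, float] = {}
    n = len(calls)
    all_marks = sorted({m for marks in calls["supporting_marks"] for m, _ in marks})
    for mark in all_marks:
        freq[mark] = sum(
            any(m == mark for m, _ in marks) for marks in calls["supporting_marks"]
        ) / n
    report["mark_support_frequency"] = freq
    if occupancy_tables is not None:
        congruent_genes = calls.index[calls["congruent"]]
        heat = pd.DataFrame(index=congruent_genes, dtype=float)
        for mark, tab in occupancy_tables.items():
            heat[mark] = tab["log2_ratio"].reindex(congruent_genes)
        report["heatmap"] = heat
    return report
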