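"""Gene-set enrichment and regulator activation scoring.

Three statistics:

* ``gsea_es`` — the classic weighted Kolmogorov-Smirnov-like running-sum
  enrichment score: walking down the ranked list, hits increment by
  |metric|^p / sum_hits |metric|^p and misses decrement by 1/(N - N_h);
  ES is the signed maximum deviation from zero.
* ``gsea_significance`` — a gene-label permutation null per set size;
  NES = ES / mean(|ES_perm| of the matching sign); one-sided permutation p
  with +1 continuity; FDR by the sign-stratified NES procedure.
* ``overrepresentation`` — right-tailed hypergeometric test P(X >= k) per
  set, BH-adjusted across sets (an open stand-in for proprietary
  pathway-analysis scoring).
* ``regulator_z`` — a simplified activation z-score:
  (concordant - discordant) / sqrt(informative targets), unit weights.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 5


def _as_ranked(ranked) -> Tuple[np.ndarray, np.ndarray]:
    """Normalize a ranking to (gene array, metric array), sorted descending.

    Ties in the metric break by gene id for determinism.
    """
    if isinstance(ranked, pd.Series):
        genes = np.asarray(ranked.index.astype(str))
        metric = ranked.to_numpy(dtype=float)
    else:
        pairs = list(ranked)
        genes = np.asarray([str(g) for g, _ in pairs])
        metric = np.asarray([float(m) for _, m in pairs])
    if len(set(genes)) != len(genes):
        raise ValueError("gene ids in the ranking must be unique")
    if not np.all(np.isfinite(metric)):
        raise ValueError("ranking metric must be finite")
    order = np.lexsort((genes, -metric))
    return genes[order], metric[order]


def _es_from_positions(
    positions: np.ndarray, weights_at_pos: np.ndarray, n_total: int
) -> float:
    """ES given sorted 0-based hit positions and their |metric|^p weights.

    Evaluates the running sum just before and at each hit — the extrema of
    the piecewise-linear walk occur only there.
    """
    m = len(positions)
    wsum = weights_at_pos.sum()
    if wsum == 0:
        # all hit weights zero (e.g. zero metrics): fall back to equal steps
        weights_at_pos = np.ones(m)
        wsum = float(m)
    miss = 1.0 / (n_total - m)
    cum_hit = np.cumsum(weights_at_pos) / wsum
    ranks = np.arange(1, m + 1)
    at_hit = cum_hit - (positions + 1 - ranks) * miss
    before_hit = np.concatenate([[0.0], cum_hit[:-1]]) - (positions - (ranks - 1)) * miss
    lo = before_hit.min()
    hi = at_hit.max()
    return float(hi if hi >= -lo else lo)


def gsea_es(ranked, gene_set: Iterable[str], weight_p: float = 1.0) -> float:
    """Enrichment score of a gene set against a ranked list."""
    genes, metric = _as_ranked(ranked)
    gs = {str(g) for g in gene_set}
    mask = np.isin(genes, list(gs))
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set equals the whole ranked list")
    positions = np.nonzero(mask)[0]
    weights = np.abs(metric[positions]) ** weight_p
    return _es_from_positions(positions, weights, len(genes))


def _permuted_es(
    metric_abs_p: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-label permutation null: ES of n_perm random sets of this size."""
    n = len(metric_abs_p)
    out = np.empty(n_perm)
    for k in range(n_perm):
        positions = np.sort(rng.choice(n, size=set_size, replace=False))
        out[k] = _es_from_positions(positions, metric_abs_p[positions], n)
    return out


def gsea_significance(
    ranked,
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """ES, NES, permutation p and sign-stratified FDR for each gene set."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes, metric = _as_ranked(ranked)
    metric_abs_p = np.abs(metric) ** weight_p
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(genes)}

    rows = []
    perm_cache: Dict[int, np.ndarray] = {}
    perm_nes_pos: list = []
    perm_nes_neg: list = []
    for set_id in sorted(gene_sets):
        members = {str(g) for g in gene_sets[set_id]}
        positions = np.sort([gene_index[g] for g in members if g in gene_index])
        k = len(positions)
        if k < min_size or k >= len(genes):
            logger.info("set %s skipped (overlap %d)", set_id, k)
            continue
        es = _es_from_positions(positions, metric_abs_p[positions], len(genes))
        if k not in perm_cache:
            perm_cache[k] = _permuted_es(metric_abs_p, k, n_perm, rng)
        perm = perm_cache[k]
        same_sign = perm >= 0 if es >= 0 else perm < 0
        n_same = int(same_sign.sum())
        denom = np.abs(perm[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        p_perm = (1 + int((np.abs(perm[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        if np.isfinite(nes) and denom:
            scaled = perm[same_sign] / denom
            (perm_nes_pos if es >= 0 else perm_nes_neg).append(np.abs(scaled))
        rows.append(
            {"set_id": set_id, "n_overlap": k, "ES": es, "NES": nes, "p_perm": p_perm}
        )
    table = pd.DataFrame(rows, columns=["set_id", "n_overlap", "ES", "NES", "p_perm"])
    if table.empty:
        table["fdr"] = []
        return table.set_index("set_id")

    # sign-stratified FDR: for each observed NES, compare the permuted-NES
    # tail fraction with the observed-NES tail fraction within the same sign
    pooled = {
        1: np.concatenate(perm_nes_pos) if perm_nes_pos else np.array([]),
        -1: np.concatenate(perm_nes_neg) if perm_nes_neg else np.array([]),
    }
    fdrs = []
    for _, row in table.iterrows():
        nes = row["NES"]
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        sign = 1 if row["ES"] >= 0 else -1
        obs = np.abs(table.loc[np.sign(table["ES"]).replace(0, 1) == sign, "NES"].dropna())
        perm_pool = pooled[sign]
        if len(perm_pool) == 0 or len(obs) == 0:
            fdrs.append(np.nan)
            continue
        frac_perm = np.mean(perm_pool >= abs(nes))
        frac_obs = np.mean(obs >= abs(nes))
        fdrs.append(float(min(1.0, frac_perm / frac_obs)) if frac_obs > 0 else 1.0)
    table["fdr"] = fdrs
    return table.set_index("set_id")


def overrepresentation(
    hit_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Right-tailed hypergeometric over-representation per gene set.

    For a universe of M genes, a set of K and n hits with k overlapping,
    p = P(X >= k) under Hypergeometric(M, K, n); BH FDR across sets.
    """
    hits = {str(g) for g in hit_genes}
    uni = {str(g) for g in universe}
    if not hits <= uni:
        raise ValueError("hit genes must be a subset of the universe")
    M, n = len(uni), len(hits)
    rows = []
    for set_id in sorted(gene_sets):
        members = {str(g) for g in gene_sets[set_id]} & uni
        K = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        expected = K * n / M if M else 0.0
        rows.append(
            {
                "set_id": set_id,
                "n_set": K,
                "n_overlap": k,
                "expected": expected,
                "enrichment": (k / expected) if expected > 0 else np.nan,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("set_id")
    table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    return table


def gsea_rank_from_de(de_table: pd.DataFrame) -> pd.Series:
    """Ranking metric from a DE table: the log2 fold change, descending."""
    s = de_table["log2fc"].astype(float)
    return s.sort_values(ascending=False)


def regulator_z(
    model: Mapping[str, int], de_calls: Mapping[str, str]
) -> Optional[float]:
    """Simplified activation z-score of a regulator.

    ``model`` maps target gene -> expected sign (+1 activation, -1
    repression); ``de_calls`` maps gene -> up/down/ns.  Over targets with a
    non-ns call, z = (concordant - discordant) / sqrt(informative).  Returns
    None when no target is informative.
    """
    if not model:
        raise ValueError("regulator model has no targets")
    nc = nd = 0
    for target, sign in model.items():
        if sign not in (1, -1):
            raise ValueError(f"expected sign +1/-1 for target {target}, got {sign}")
        call = de_calls.get(str(target), "ns")
        if call == "ns":
            continue
        observed = 1 if call == "up" else -1
        if observed == sign:
            nc += 1
        else:
            nd += 1
    if nc + nd == 0:
        return None
    return (nc - nd) / np.sqrt(nc + nd)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> Dict[str, Set[str]]:
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            members = "\t".join(sorted({str(g) for g in gene_sets[set_id]}))
            fh.write(f"{set_id}\t{description}\t{members}\n")
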