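"""Two-group negative-binomial differential expression.

The model: counts K_ij ~ NB(mean = s_j * q_gi, dispersion alpha_i) with
variance mu + alpha * mu^2, where s_j is a per-sample size factor
(median-of-ratios) and q_gi the group-level expression.  Per-gene dispersion
is estimated by method of moments and shrunk in log space toward a fitted
mean-dispersion trend alpha(mu) = a1 + a0 / mu; the log2 fold change
(case vs control, 0.5 pseudocount on normalized means) is tested with a
Wald statistic against a standard-normal null.  Benjamini-Hochberg FDR is
applied across
tested genes; genes with all-zero counts are dropped beforehand.

Significance calls follow the thresholds FDR <= 0.01 and |log2FC| >= 1.5,
applied symmetrically to up- and downregulation.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.01
DEFAULT_LFC_MIN = 1.5

_MIN_DISP = 1e-8
_MAX_DISP = 10.0


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples input).

    The reference is the per-gene geometric mean over samples, computed on
    genes with no zero count; each sample's factor is the median ratio of
    its counts to the reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be a 2-D genes x samples array")
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    nonzero = np.all(mat > 0, axis=1)
    if not np.any(nonzero):
        raise ValueError(
            "no gene has nonzero counts in every sample; a pseudo-reference "
            "fallback (e.g. adding a pseudocount) is required for such data"
        )
    ref = mat[nonzero]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    if not np.all(np.isfinite(factors) & (factors > 0)):
        raise ValueError("size factors must be positive and finite")
    return factors


def _dispersion_trend(base_mean: np.ndarray, disp_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a1 + a0/mu on genes with a positive moment estimate."""
    ok = (disp_mom > 0) & (base_mean > 0)
    if ok.sum() < 10:
        fallback = float(np.median(disp_mom[ok])) if ok.any() else 0.1
        return np.full_like(base_mean, max(fallback, _MIN_DISP))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    y = disp_mom[ok]
    # one round of trimming guards the fit against outlier genes
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    keep = np.abs(resid) <= 3 * np.std(resid) + 1e-12
    if keep.sum() >= 10:
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    a1, a0 = max(coef[0], 0.0), max(coef[1], 0.0)
    trend = a1 + a0 / np.maximum(base_mean, 1e-8)
    return np.clip(trend, _MIN_DISP, _MAX_DISP)


def estimate_dispersions(
    norm_counts: np.ndarray, group_idx: Sequence[np.ndarray],
    inv_sf_mean: float, shrink_weight: float = 0.8,
) -> np.ndarray:
    """Moment dispersions shrunk toward the mean-dispersion trend (log space)."""
    means = [norm_counts[:, idx].mean(axis=1) for idx in group_idx]
    ns = [len(idx) for idx in group_idx]
    # pooled within-group variance
    sse = np.zeros(norm_counts.shape[0])
    for idx, m in zip(group_idx, means):
        sse += ((norm_counts[:, idx] - m[:, None]) ** 2).sum(axis=1)
    dof = sum(ns) - len(ns)
    pooled_var = sse / max(dof, 1)
    pooled_mean = sum(n * m for n, m in zip(ns, means)) / sum(ns)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (pooled_var - pooled_mean * inv_sf_mean) / pooled_mean**2
    disp_mom = np.where(np.isfinite(disp_mom), disp_mom, 0.0)
    base_mean = norm_counts.mean(axis=1)
    trend = _dispersion_trend(base_mean, disp_mom)
    gene_wise = np.clip(disp_mom, _MIN_DISP, _MAX_DISP)
    w = shrink_weight
    shrunk = np.exp(w * np.log(trend) + (1 - w) * np.log(gene_wise))
    return np.clip(shrunk, _MIN_DISP, _MAX_DISP)


def test_two_group(
    counts: pd.DataFrame,
    groups: Sequence[str],
    *,
    control: str | None = None,
    pseudocount: float = 0.5,
    shrink_weight: float = 0.8,
    sample_size_factors: Sequence[float] | None = None,
) -> pd.DataFrame:
    """NB Wald test of case vs control for every gene.

    Parameters
    ----------
    counts
        Genes x samples raw integer counts; the index holds gene ids.
    groups
        Per-sample labels with exactly two levels.  ``control`` names the
        reference level; if omitted, the lexicographically first level is
        treated as control and the other as case.

    Returns
    -------
    DataFrame indexed by gene id with columns ``baseMean``, ``log2fc``,
    ``se_log2fc``, ``p``, ``fdr`` and ``call`` (all ``ns`` until
    :func:`classify_de` thresholds are applied).
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(np.asarray(counts))
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != counts.shape[1]:
        raise ValueError("one group label per sample required")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    if control is None:
        control = levels[0]
    elif control not in levels:
        raise ValueError(f"control level {control!r} not among group labels {levels}")
    case = levels[0] if control == levels[1] else levels[1]
    idx_ctrl = np.where(groups == control)[0]
    idx_case = np.where(groups == case)[0]

    mat = counts.to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero genes before testing", n_dropped)
    mat = mat[nonzero]
    gene_ids = counts.index[nonzero]

    if sample_size_factors is not None:
        # externally known normalization (e.g. sequencing-depth-derived);
        # geometric-mean-centred so the fold-change scale is preserved
        sf = np.asarray(sample_size_factors, dtype=float)
        if len(sf) != mat.shape[1] or np.any(sf <= 0):
            raise ValueError("sample_size_factors must be positive, one per sample")
        sf = sf / np.exp(np.mean(np.log(sf)))
    else:
        sf = size_factors(mat)
    q = mat / sf
    m_ctrl = q[:, idx_ctrl].mean(axis=1)
    m_case = q[:, idx_case].mean(axis=1)
    base_mean = q.mean(axis=1)
    c = pseudocount
    log2fc = np.log2((m_case + c) / (m_ctrl + c))

    n_ctrl, n_case = len(idx_ctrl), len(idx_case)
    result = pd.DataFrame(
        {"baseMean": base_mean, "log2fc": log2fc}, index=gene_ids
    )
    result.index.name = "gene_id"

    if min(n_ctrl, n_case) < 2:
        logger.warning("fewer than 2 replicates per group: reporting log2fc only")
        result["se_log2fc"] = np.nan
        result["p"] = np.nan
        result["fdr"] = np.nan
        result["call"] = "ns"
        return result

    inv_sf_mean = float(np.mean(1.0 / sf))
    alpha = estimate_dispersions(q, [idx_ctrl, idx_case], inv_sf_mean, shrink_weight)

    # delta-method variance of log2((m_case+c)/(m_ctrl+c)) under the NB model:
    # Var(q_ij) = mu/s_j + alpha mu^2, group means are averages of independent
    # samples.
    def group_var(mean: np.ndarray, idx: np.ndarray) -> np.ndarray:
        inv_s = 1.0 / sf[idx]
        return (mean[:, None] * inv_s[None, :] + alpha[:, None] * mean[:, None] ** 2).sum(
            axis=1
        ) / len(idx) ** 2

    var_ctrl = group_var(m_ctrl, idx_ctrl)
    var_case = group_var(m_case, idx_case)
    ln2 = np.log(2.0)
    var_lfc = (var_case / (m_case + c) ** 2 + var_ctrl / (m_ctrl + c) ** 2) / ln2**2
    se = np.sqrt(np.maximum(var_lfc, 1e-300))
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = benjamini_hochberg(p)

    result["se_log2fc"] = se
    result["p"] = p
    result["fdr"] = fdr
    result["call"] = "ns"
    return result


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone in p-rank, capped at 1)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    de_table: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Apply the significance thresholds, returning a table with ``call`` set.

    ``up`` requires fdr <= fdr_max and log2fc >= lfc_min; ``down`` the
    mirrored condition; everything else (including untested genes) is ``ns``.
    """
    if not (0 < fdr_max <= 1):
        raise ValueError("fdr_max must be in (0, 1]")
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    out = de_table.copy()
    fdr = out["fdr"].to_numpy(dtype=float)
    lfc = out["log2fc"].to_numpy(dtype=float)
    ok = np.isfinite(fdr) & (fdr <= fdr_max)
    call = np.where(ok & (lfc >= lfc_min), "up", "ns")
    call = np.where(ok & (lfc <= -lfc_min), "down", call)
    out["call"] = call
    return out
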