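"""Normalization and expression summaries.

TMM (trimmed mean of M-values) between-sample normalization, FPKM, the
low-count filter, coefficient-of-variation gene selection for clustering,
row z-scaling, a PCA overview, Welch comparisons, and upset-style DEG set
associations.

TMM follows the published weighted-trimmed-mean formula: per-gene log
ratios M and average log intensities A against a reference sample, genes
with zero counts in either member of the pair excluded, a double trim (30%
of M, 5% of A by average ranks), precision weights from binomial
asymptotics, factor = 2^(weighted mean of kept M), and a final rescaling of
each normalization group to geometric mean 1.  The reference sample is the
one whose 75th-percentile count fraction is closest to the mean of those
fractions.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import (
    DimensionError,
    FormatError,
    NormFactors,
    NormalizationError,
    PCAResult,
    WelchResult,
)

logger = logging.getLogger("orthocompare")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _quantile_fraction(counts: np.ndarray, lib_sizes: np.ndarray, q: float = 0.75) -> np.ndarray:
    """Per-sample ``q``-quantile of counts divided by library size."""
    return np.quantile(counts, q, axis=0) / lib_sizes


def choose_reference(counts: pd.DataFrame) -> str:
    """Reference = sample whose 75th-percentile count fraction is closest
    to the mean of those fractions across samples."""
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise NormalizationError(f"samples with all-zero counts: {bad}")
    f75 = _quantile_fraction(arr, lib)
    idx = int(np.argmin(np.abs(f75 - f75.mean())))
    return str(counts.columns[idx])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> tuple[float, pd.DataFrame]:
    """TMM factor of one sample against the reference (log2 scale -> 2^f)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    both = (obs > 0) & (ref > 0)
    o = obs[both] / n_obs
    r = ref[both] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (n_ref * ref[both])
    diag = pd.DataFrame({"M": m, "A": a, "w": w})
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0, diag
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0, diag
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f), diag


def compute_tmm_factors(
    counts: pd.DataFrame,
    group: Optional[Mapping[str, str]] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    keep_diagnostics: bool = False,
) -> NormFactors:
    """TMM scaling factors, one per sample.

    ``group`` optionally maps sample ids to normalization groups; factors
    are computed and rescaled to geometric mean 1 within each group
    (default: all samples form one group).
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise NormalizationError(f"samples with all-zero counts: {bad}")
    samples = [str(s) for s in counts.columns]
    if group is None:
        group = {s: "all" for s in samples}
    factors = pd.Series(np.ones(len(samples)), index=samples, dtype=float)
    reference = None
    diagnostics: Optional[pd.DataFrame] = None
    for g in sorted(set(group.values())):
        members = [s for s in samples if group[s] == g]
        sub = counts.loc[:, members]
        ref_sample = choose_reference(sub)
        if reference is None:
            reference = ref_sample
        ref_col = sub[ref_sample].to_numpy(dtype=float)
        raw = {}
        for s in members:
            f, diag = _tmm_pair(sub[s].to_numpy(dtype=float), ref_col, trim_m, trim_a)
            raw[s] = f
            if keep_diagnostics and s != ref_sample and diagnostics is None:
                diagnostics = diag
        vals = pd.Series(raw)
        vals = vals / np.exp(np.log(vals).mean())  # geometric mean 1 per group
        factors.loc[members] = vals
    assert reference is not None
    logger.info("compute_tmm_factors: %d samples, reference=%s", len(samples), reference)
    return NormFactors(factors=factors, reference_sample=reference, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# filtering, FPKM, CV selection
# ---------------------------------------------------------------------------

def filter_low_count(counts: pd.DataFrame, min_total: int = 1) -> pd.DataFrame:
    """Drop genes whose total count across all samples is below ``min_total``."""
    if min_total < 0:
        raise FormatError("min_total must be >= 0")
    keep = counts.sum(axis=1) >= min_total
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_count: removed %d of %d genes (min_total=%d)",
                    n_removed, counts.shape[0], min_total)
    if keep.sum() == 0:
        logger.warning("filter_low_count: no genes survive the filter")
    return counts.loc[keep]


def effective_library_sizes(counts: pd.DataFrame, factors: NormFactors) -> pd.Series:
    """Column sums multiplied by the TMM factors."""
    lib = counts.sum(axis=0).astype(float)
    return lib * factors.factors.reindex(lib.index)


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    factors: NormFactors,
) -> pd.DataFrame:
    """FPKM_gs = count_gs / (effective library size_s / 1e6) / (length_g / 1e3)."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise FormatError(f"genes without a length entry: {missing.tolist()[:5]}")
    eff = effective_library_sizes(counts, factors).to_numpy()
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    fpkm = counts.to_numpy(dtype=float) / (eff[None, :] / 1e6) / (lens[:, None] / 1e3)
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


GROUP_SEP = "|"


def group_label(tissue: str, condition: str) -> str:
    return f"{tissue}{GROUP_SEP}{condition}"


def group_means(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-sample expression matrix to tissue x condition means.

    Column order follows the metadata's tissue order (first appearance),
    control before fed within a tissue.
    """
    cols: dict[str, list[str]] = {}
    for tissue in meta["tissue"].drop_duplicates():
        for condition in ("control", "fed"):
            ids = meta.loc[(meta["tissue"] == tissue) & (meta["condition"] == condition), "sample_id"]
            if len(ids):
                cols[group_label(tissue, condition)] = list(ids)
    out = pd.DataFrame({label: expr.loc[:, ids].mean(axis=1) for label, ids in cols.items()})
    return out


def select_high_cv_genes(
    expr_means: pd.DataFrame,
    top_frac: float = 0.10,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Rank genes by coefficient of variation across tissue x condition means.

    Eligible genes have max mean FPKM above ``min_fpkm`` in at least one
    column; the top ``ceil(top_frac * n_eligible)`` by CV (sample sd / mean)
    are selected, ties at the cutoff broken lexicographically by gene id.
    Returns a per-gene stats table with a boolean ``selected`` column.
    """
    means = expr_means.mean(axis=1)
    sds = expr_means.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, 0.0)
    cv = pd.Series(np.nan_to_num(cv, nan=0.0), index=expr_means.index)
    max_fpkm = expr_means.max(axis=1)
    eligible = max_fpkm > min_fpkm
    stats = pd.DataFrame(
        {"mean_fpkm": means, "cv": cv, "max_fpkm": max_fpkm, "selected": False},
        index=expr_means.index,
    )
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        logger.warning("select_high_cv_genes: no eligible genes (min_fpkm=%.3g)", min_fpkm)
        return stats
    n_select = math.ceil(top_frac * n_eligible)
    # deterministic tie-break: sort by gene id first, then stable-sort by CV
    order = stats.loc[eligible].sort_index(kind="mergesort")
    order = order.sort_values("cv", ascending=False, kind="mergesort")
    chosen = order.index[:n_select]
    stats.loc[chosen, "selected"] = True
    logger.info("select_high_cv_genes: %d of %d eligible selected (top_frac=%.3g)",
                n_select, n_eligible, top_frac)
    return stats


def zscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-center and variance-scale each row (sample sd, ddof=1).

    Rows with zero variance are dropped with a warning.
    """
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    keep = sds > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("zscale: dropped %d constant rows", n_dropped)
    sub = matrix.loc[keep]
    return sub.sub(means[keep], axis=0).div(sds[keep], axis=0)


# ---------------------------------------------------------------------------
# PCA overview and Welch tests
# ---------------------------------------------------------------------------

def pca_overview(expr_subset: pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA with samples as observations and genes as features.

    ``expr_subset`` is genes x samples (the pipeline's storage convention);
    it is transposed internally.  Features are centered; set ``scale`` to
    additionally divide by per-gene standard deviations.
    """
    from sklearn.decomposition import PCA

    X = expr_subset.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise DimensionError("PCA needs at least 2 samples")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr_subset.columns, columns=cols),
        variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's two-sided t-test (unequal variances, Satterthwaite df).

    The degenerate limit of zero variance in both groups with equal means
    is defined as t = 0, p = 1.
    """
    from scipy import stats

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DimensionError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, pvalue=1.0, df=float(a.size + b.size - 2),
                               mean_a=float(a.mean()), mean_b=float(b.mean()))
        t = math.inf if a.mean() > b.mean() else -math.inf
        return WelchResult(t=t, pvalue=0.0, df=float(a.size + b.size - 2),
                           mean_a=float(a.mean()), mean_b=float(b.mean()))
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        pvalue=float(res.pvalue),
        df=float(res.df),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


# ---------------------------------------------------------------------------
# upset-style DEG set associations
# ---------------------------------------------------------------------------

def deg_set_associations(
    deg_tables: Mapping[str, pd.DataFrame],
    direction: str,
) -> dict[tuple[str, ...], int]:
    """Tally genes by their exact tissue-membership pattern.

    ``deg_tables`` maps tissue -> DEG table; a gene contributes to exactly
    one association: the sorted tuple of tissues where its status equals
    ``direction``.  Associations with zero genes are omitted.
    """
    if direction not in ("up", "down"):
        raise FormatError("direction must be 'up' or 'down'")
    membership: dict[str, set[str]] = {}
    for tissue, table in deg_tables.items():
        hits = table.loc[table["status"] == direction, "gene_id"]
        for gene in hits:
            membership.setdefault(gene, set()).add(tissue)
    tallies: dict[tuple[str, ...], int] = {}
    for gene, tissues in membership.items():
        key = tuple(sorted(tissues))
        tallies[key] = tallies.get(key, 0) + 1
    return tallies
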