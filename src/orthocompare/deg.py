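"""Per-tissue differential expression between control and fed samples.

The engine is a single-pass negative-binomial likelihood-ratio test:
per-gene dispersions are estimated by method of moments from
within-condition residuals and shrunk toward a trimmed-mean common
dispersion, then equal-mean vs per-condition-mean NB models (effective
library sizes as offsets, dispersion held fixed) are compared against a
chi-squared distribution with 1 df.  Benjamini-Hochberg correction is
applied within each tissue, and genes are called up/down at FDR < 0.05 and
|log2 fold change| >= 1.0 by default.  Externally produced DEG tables can
be slotted in unchanged downstream.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .types import DomainError, EstimationError, NormFactors

logger = logging.getLogger("orthocompare")

DISPERSION_FLOOR = 1e-4
PSEUDO_COUNT = 0.5


def _tissue_design(meta: pd.DataFrame, tissue: str) -> tuple[pd.DataFrame, np.ndarray]:
    sub = meta.loc[meta["tissue"] == tissue]
    if sub.empty:
        raise EstimationError(f"no samples for tissue {tissue!r}")
    is_fed = (sub["condition"] == "fed").to_numpy()
    for cond, mask in (("control", ~is_fed), ("fed", is_fed)):
        if mask.sum() < 2:
            raise EstimationError(
                f"tissue {tissue!r} has {int(mask.sum())} {cond} replicate(s); need >= 2"
            )
    return sub, is_fed


def estimate_dispersion(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    factors: Optional[NormFactors] = None,
    prior_df: float = 20.0,
    common_trim: float = 0.125,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments NB dispersions with df-weighted shrinkage.

    Counts are scaled to a common library size; per-condition means and
    variances give phi_c = (var - mean) / mean^2, pooled over conditions by
    residual df, then shrunk toward the trimmed-mean common dispersion with
    weight df / (df + prior_df) and floored at ``floor``.
    """
    sub, is_fed = _tissue_design(meta, tissue)
    y = counts.loc[:, list(sub["sample_id"])].to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if factors is not None:
        lib = lib * factors.factors.reindex(sub["sample_id"]).to_numpy()
    scale = np.exp(np.mean(np.log(lib)))
    z = y / lib[None, :] * scale

    num = np.zeros(y.shape[0])
    den = 0.0
    for mask in (~is_fed, is_fed):
        zc = z[:, mask]
        n_c = int(mask.sum())
        m = zc.mean(axis=1)
        v = zc.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += (n_c - 1) * np.nan_to_num(phi_c, nan=0.0, posinf=0.0, neginf=0.0)
        den += n_c - 1
    phi_gene = num / den
    clipped = np.clip(phi_gene, 0.0, None)
    lo, hi = np.quantile(clipped, [common_trim, 1 - common_trim])
    mid = clipped[(clipped >= lo) & (clipped <= hi)]
    phi_common = float(mid.mean()) if mid.size else float(clipped.mean())
    w = den / (den + prior_df)
    phi = w * phi_gene + (1 - w) * phi_common
    phi = np.clip(phi, floor, None)
    return pd.Series(phi, index=counts.index, name="dispersion")


def _nb_fit_mean(y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Vectorized Fisher scoring for the NB mean with a log link.

    Fits mu_gi = exp(beta_g) * offsets_i per gene with dispersion phi_g
    fixed.  Returns exp(beta_g); genes whose counts are all zero get 0.
    """
    tot = y.sum(axis=1)
    off_tot = offsets.sum()
    with np.errstate(divide="ignore"):
        beta = np.log(np.maximum(tot, 1e-300) / off_tot)
    active = tot > 0
    b = beta[active]
    ya = y[active]
    ph = phi[active][:, None]
    for _ in range(n_iter):
        mu = np.exp(b)[:, None] * offsets[None, :]
        denom = 1.0 + ph * mu
        score = ((ya - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step), initial=0.0) < 1e-12:
            break
    out = np.zeros_like(beta)
    out[active] = np.exp(b)
    return out


def _nb_loglik_terms(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood, dropping terms that cancel in the LRT."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(mu, 1e-300)), 0.0)
    term2 = (y + 1.0 / phi[:, None]) * np.log1p(phi[:, None] * mu)
    return (term1 - term2).sum(axis=1)


def test_de(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: NormFactors,
    tissue: str,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    dispersion: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """NB likelihood-ratio test of fed vs control for one tissue.

    Returns a DEG table (gene_id, tissue, log2fc, pvalue, fdr, status).
    log2fc is computed on per-million normalized means with pseudo-count
    0.5, making it invariant to a global rescaling of counts.
    """
    sub, is_fed = _tissue_design(meta, tissue)
    sample_ids = list(sub["sample_id"])
    y = counts.loc[:, sample_ids].to_numpy(dtype=float)
    eff = counts.loc[:, sample_ids].sum(axis=0).to_numpy(dtype=float)
    eff = eff * factors.factors.reindex(sample_ids).to_numpy()
    if dispersion is None:
        dispersion = estimate_dispersion(counts, meta, tissue, factors=factors)
    phi = dispersion.reindex(counts.index).to_numpy(dtype=float)

    offsets = eff / 1e6  # per-million scale
    mu_null = _nb_fit_mean(y, offsets, phi)[:, None] * offsets[None, :]
    mu_alt = np.empty_like(y)
    for mask in (~is_fed, is_fed):
        m = _nb_fit_mean(y[:, mask], offsets[mask], phi)
        mu_alt[:, mask] = m[:, None] * offsets[mask][None, :]
    lrt = 2.0 * (_nb_loglik_terms(y, mu_alt, phi) - _nb_loglik_terms(y, mu_null, phi))
    lrt = np.clip(lrt, 0.0, None)
    pvals = chi2.sf(lrt, df=1)

    cpm = y / offsets[None, :]
    mean_control = cpm[:, ~is_fed].mean(axis=1)
    mean_fed = cpm[:, is_fed].mean(axis=1)
    log2fc = np.log2(mean_fed + PSEUDO_COUNT) - np.log2(mean_control + PSEUDO_COUNT)

    fdr = bh_adjust(pvals)
    status = classify_deg(log2fc, fdr, fdr_threshold, lfc_threshold)
    table = pd.DataFrame(
        {
            "gene_id": counts.index,
            "tissue": tissue,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "status": status,
        }
    ).reset_index(drop=True)
    n_up = int((table["status"] == "up").sum())
    n_down = int((table["status"] == "down").sum())
    logger.info("test_de: tissue=%s genes=%d up=%d down=%d", tissue, len(table), n_up, n_down)
    return table


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1; rank-based, so the
    result is invariant to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def classify_deg(log2fc, fdr, fdr_threshold: float = 0.05, lfc_threshold: float = 1.0):
    """up if fdr < threshold and log2fc >= +lfc; down if <= -lfc; else ns.

    FDR is compared strictly (<), the fold-change bound inclusively (>=).
    Accepts scalars or arrays; returns the matching shape.
    """
    lfc = np.asarray(log2fc, dtype=float)
    q = np.asarray(fdr, dtype=float)
    sig = q < fdr_threshold
    status = np.where(
        sig & (lfc >= lfc_threshold),
        "up",
        np.where(sig & (lfc <= -lfc_threshold), "down", "ns"),
    )
    if status.ndim == 0:
        return str(status)
    return status
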