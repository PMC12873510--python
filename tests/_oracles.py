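"""Independent oracles, written as direct transcriptions of the published
definitions, deliberately separate in style and code path from the package
implementation."""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# TMM: weighted trimmed mean of M-values, plain-Python per-sample loops
# ---------------------------------------------------------------------------

def _quantile_type7(values, q):
    vals = sorted(values)
    h = (len(vals) - 1) * q
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 < len(vals):
        return vals[lo] + frac * (vals[lo + 1] - vals[lo])
    return vals[lo]


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # 1-based average rank
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _tmm_one_sample(obs, ref, trim_m, trim_a):
    n_obs = sum(obs)
    n_ref = sum(ref)
    m_vals, a_vals, w_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / n_obs, r / n_ref
            m_vals.append(math.log2(po / pr))
            a_vals.append(0.5 * math.log2(po * pr))
            w_vals.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if not m_vals or max(abs(m) for m in m_vals) < 1e-6:
        return 1.0
    n = len(m_vals)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = _average_ranks(m_vals)
    rank_a = _average_ranks(a_vals)
    num = den = 0.0
    kept = False
    for m, rm, ra, w in zip(m_vals, rank_m, rank_a, w_vals):
        if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
            num += m / w
            den += 1.0 / w
            kept = True
    if not kept:
        return 1.0
    return 2.0 ** (num / den)


def tmm_factors_oracle(table, trim_m=0.30, trim_a=0.05):
    """TMM factors for a genes x samples table (list of row-lists).

    Returns one factor per column, rescaled to geometric mean 1.
    """
    n_samples = len(table[0])
    cols = [[row[s] for row in table] for s in range(n_samples)]
    libs = [sum(c) for c in cols]
    fracs = [_quantile_type7(c, 0.75) / lib for c, lib in zip(cols, libs)]
    mean_frac = sum(fracs) / n_samples
    ref_idx = min(range(n_samples), key=lambda s: (abs(fracs[s] - mean_frac), s))
    factors = [_tmm_one_sample(cols[s], cols[ref_idx], trim_m, trim_a) for s in range(n_samples)]
    log_mean = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_mean) for f in factors]


# ---------------------------------------------------------------------------
# BH step-up, literal definition
# ---------------------------------------------------------------------------

def bh_oracle(pvalues):
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    for rank_pos, idx in enumerate(order, start=1):
        q = min(
            pvalues[order[j]] * n / (j + 1) for j in range(rank_pos - 1, n)
        )
        adjusted[idx] = min(q, 1.0)
    return adjusted


# ---------------------------------------------------------------------------
# Majority-vote orthogroup call, literal rule
# ---------------------------------------------------------------------------

def majority_oracle(statuses):
    """Call for a multiset of member DEG statuses ('up'/'down'/'ns')."""
    ups = sum(1 for s in statuses if s == "up")
    downs = sum(1 for s in statuses if s == "down")
    if ups + downs == 0:
        return "none"
    if ups == downs:
        return "conflict"
    return "up" if ups > downs else "down"


# ---------------------------------------------------------------------------
# Permutation-null Jaccard p, exhaustive enumeration over subsets
# ---------------------------------------------------------------------------

def exact_jaccard_p(set_a, set_b, universe_a, universe_b):
    """P(JC_perm >= JC_obs) when each set is redrawn as a uniformly random
    subset of its universe with the observed size (the image of a uniform
    bijection)."""
    obs_i = len(set_a & set_b)
    obs_u = len(set_a | set_b)
    obs_jc = obs_i / obs_u if obs_u else 0.0
    a, b = len(set_a), len(set_b)
    hits = total = 0
    for sa in itertools.combinations(universe_a, a):
        sa_set = set(sa)
        for sb in itertools.combinations(universe_b, b):
            inter = len(sa_set & set(sb))
            union = a + b - inter
            jc = inter / union if union else 0.0
            total += 1
            if jc >= obs_jc:
                hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Welch's t, direct formula transcription
# ---------------------------------------------------------------------------

def welch_oracle(group_a, group_b):
    na, nb = len(group_a), len(group_b)
    ma = sum(group_a) / na
    mb = sum(group_b) / nb
    va = sum((x - ma) ** 2 for x in group_a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in group_b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p, df
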