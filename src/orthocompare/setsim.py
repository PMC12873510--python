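"""Jaccard similarity between orthogroup sets with a constrained
permutation null.

The null model redraws each "side" (a species/tissue or one species' SOM
run) by a uniformly random bijection of that side's orthogroup universe
onto itself, applied jointly to *all* of the side's observed sets.  A
bijection preserves set sizes and co-membership structure and can never
map one orthogroup into two mutually exclusive categories, so the
no-contradiction constraint (an orthogroup cannot become both up and down
in the same tissue) holds by construction.  The Jaccard coefficient is
recomputed for every draw and p = (#{JC_perm >= JC_obs} + 1) / (n + 1);
a ``p_literal`` flag switches to the plain r/n estimate.  Benjamini-
Hochberg correction is applied across all pairs of one matrix.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .deg import bh_adjust
from .types import DomainError, SetSimilarityResult

logger = logging.getLogger("orthocompare")


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; defined as 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass(frozen=True)
class SetPair:
    """One cell of a similarity matrix: two sets and their side keys.

    Sets sharing a side key are co-permuted through one bijection per
    draw (the constraint that forbids contradictory assignments).
    """

    label: str
    side_a: str
    side_b: str
    set_a: frozenset
    set_b: frozenset


def _side_rng(seed: int, side_key: str) -> np.random.Generator:
    sub = zlib.crc32(side_key.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def similarity_matrix(
    pairs: Sequence[SetPair],
    universes: Mapping[str, Sequence[str]],
    n_perm: int = 10000,
    seed: int = 0,
    p_literal: bool = False,
    chunk: int = 256,
) -> list[SetSimilarityResult]:
    """Permutation tests for every pair, BH-corrected as one family.

    ``universes`` maps each side key to its ordered orthogroup universe.
    Each side's bijection stream is seeded from the master seed and the
    side key, so a side permutes identically no matter which pairs
    reference it.
    """
    if not pairs:
        return []
    if n_perm < 100:
        logger.warning("similarity_matrix: n_perm=%d is very small", n_perm)

    side_keys = sorted({p.side_a for p in pairs} | {p.side_b for p in pairs})
    uni: dict[str, list[str]] = {}
    pos: dict[str, dict[str, int]] = {}
    for key in side_keys:
        if key not in universes:
            raise DomainError(f"no universe declared for side {key!r}")
        u = list(universes[key])
        if len(set(u)) != len(u):
            raise DomainError(f"universe for side {key!r} contains duplicates")
        uni[key] = u
        pos[key] = {g: i for i, g in enumerate(u)}
    for p in pairs:
        for side, s in ((p.side_a, p.set_a), (p.side_b, p.set_b)):
            extra = set(s) - set(uni[side])
            if extra:
                raise DomainError(
                    f"set of pair {p.label!r} not a subset of universe {side!r}: {sorted(extra)[:5]}"
                )

    # distinct sets per side, as boolean indicators over the universe
    side_sets: dict[str, list[frozenset]] = {k: [] for k in side_keys}
    set_index: dict[tuple[str, frozenset], int] = {}
    for p in pairs:
        for side, s in ((p.side_a, p.set_a), (p.side_b, p.set_b)):
            if (side, s) not in set_index:
                set_index[(side, s)] = len(side_sets[side])
                side_sets[side].append(s)
    indicators: dict[str, np.ndarray] = {}
    for key in side_keys:
        mat = np.zeros((len(side_sets[key]), len(uni[key])), dtype=bool)
        for i, s in enumerate(side_sets[key]):
            for g in s:
                mat[i, pos[key][g]] = True
        indicators[key] = mat

    # pairs grouped by (side_a, side_b); shared-id position maps per block
    blocks: dict[tuple[str, str], list[int]] = {}
    for i, p in enumerate(pairs):
        blocks.setdefault((p.side_a, p.side_b), []).append(i)
    shared_idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for ka, kb in blocks:
        shared = [g for g in uni[ka] if g in pos[kb]]
        ia = np.array([pos[ka][g] for g in shared], dtype=np.intp)
        ib = np.array([pos[kb][g] for g in shared], dtype=np.intp)
        shared_idx[(ka, kb)] = (ia, ib)

    obs_inter = np.array([len(p.set_a & p.set_b) for p in pairs])
    sizes_a = np.array([len(p.set_a) for p in pairs])
    sizes_b = np.array([len(p.set_b) for p in pairs])
    exceed = np.zeros(len(pairs), dtype=np.int64)

    rngs = {key: _side_rng(seed, key) for key in side_keys}
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        perms = {
            key: np.argsort(rngs[key].random((c, len(uni[key]))), axis=1)
            for key in side_keys
        }
        for (ka, kb), idxs in blocks.items():
            ia, ib = shared_idx[(ka, kb)]
            if ia.size == 0:
                # disjoint universes: permuted intersection is always 0
                exceed[idxs] += c * (obs_inter[np.array(idxs)] <= 0)
                continue
            mem_a = indicators[ka][:, perms[ka][:, ia]].astype(np.float32)  # (A, c, m)
            mem_b = indicators[kb][:, perms[kb][:, ib]].astype(np.float32)  # (B, c, m)
            inter = np.matmul(mem_a.transpose(1, 0, 2), mem_b.transpose(1, 2, 0))  # (c, A, B)
            inter = np.rint(inter).astype(np.int64)
            for i in idxs:
                p = pairs[i]
                ai = set_index[(p.side_a, p.set_a)]
                bi = set_index[(p.side_b, p.set_b)]
                exceed[i] += int((inter[:, ai, bi] >= obs_inter[i]).sum())
        done += c

    results = []
    pvals = (exceed / n_perm) if p_literal else ((exceed + 1) / (n_perm + 1))
    fdrs = bh_adjust(np.clip(pvals, 0.0, 1.0))
    for i, p in enumerate(pairs):
        union = int(sizes_a[i] + sizes_b[i] - obs_inter[i])
        results.append(
            SetSimilarityResult(
                label=p.label,
                intersection_size=int(obs_inter[i]),
                union_size=union,
                jc=(obs_inter[i] / union) if union else 0.0,
                pvalue=float(min(pvals[i], 1.0)),
                fdr=float(fdrs[i]),
                n_permutations=n_perm,
            )
        )
    return results


def null_intersection_counts(
    set_a: Iterable,
    set_b: Iterable,
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Tally of |pi_A(A) n pi_B(B)| over the permutation null.

    Diagnostic for the bijection null model: in a shared universe the
    counts should follow the hypergeometric law for random fixed-size
    subsets.  Returns an array of length min(|A|, |B|) + 1.
    """
    uni_a, uni_b = list(universe_a), list(universe_b)
    pos_a = {g: i for i, g in enumerate(uni_a)}
    pos_b = {g: i for i, g in enumerate(uni_b)}
    shared = [g for g in uni_a if g in pos_b]
    in_a = np.zeros(len(uni_a), dtype=bool)
    in_b = np.zeros(len(uni_b), dtype=bool)
    for g in set_a:
        in_a[pos_a[g]] = True
    for g in set_b:
        in_b[pos_b[g]] = True
    idx_a = np.array([pos_a[g] for g in shared], dtype=np.intp)
    idx_b = np.array([pos_b[g] for g in shared], dtype=np.intp)
    rng_a = _side_rng(seed, "A")
    rng_b = _side_rng(seed, "B")
    perm_a = np.argsort(rng_a.random((n_perm, len(uni_a))), axis=1)
    perm_b = np.argsort(rng_b.random((n_perm, len(uni_b))), axis=1)
    mem_a = in_a[perm_a[:, idx_a]]
    mem_b = in_b[perm_b[:, idx_b]]
    inter = (mem_a & mem_b).sum(axis=1)
    k_max = min(int(in_a.sum()), int(in_b.sum()))
    return np.bincount(inter, minlength=k_max + 1)


def permutation_test(
    set_a: Iterable,
    set_b: Iterable,
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
    p_literal: bool = False,
) -> SetSimilarityResult:
    """Single-pair permutation test (its BH-adjusted fdr equals its p)."""
    pair = SetPair(
        label="A x B",
        side_a="A",
        side_b="B",
        set_a=frozenset(set_a),
        set_b=frozenset(set_b),
    )
    (res,) = similarity_matrix(
        [pair], {"A": universe_a, "B": universe_b}, n_perm=n_perm, seed=seed, p_literal=p_literal
    )
    return res
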