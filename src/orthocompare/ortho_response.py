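"""Orthogroup-level feeding responses.

Per-gene DEG calls are lifted to orthogroups by majority vote of member
DEGs: only genes called up or down vote; ns members abstain.  The group is
"up" when up-voters outnumber down-voters, "down" in the opposite case,
"conflict" on a tie with at least one voter, and "none" with no voters.
Cross-species consistent sets and the tissue-pair comparison grid feed the
set-similarity stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .types import ConsistencyError, OrthogroupMap

logger = logging.getLogger("orthocompare")


def majority_call(n_up: int, n_down: int) -> str:
    """Majority decision over up/down voters (ns members do not vote)."""
    if n_up == 0 and n_down == 0:
        return "none"
    if n_up > n_down:
        return "up"
    if n_down > n_up:
        return "down"
    return "conflict"


def classify_orthogroup_response(
    deg_table: pd.DataFrame,
    ortho_map: OrthogroupMap,
    species: str,
    tissue: str,
    missing: str = "warn",
) -> pd.DataFrame:
    """Per-orthogroup feeding-response call for one species and tissue.

    ``missing`` controls genes present in the map but absent from the DEG
    table: "warn" counts them as ns with a logged warning, "error" raises.
    """
    sub = deg_table.loc[deg_table["tissue"] == tissue]
    status = dict(zip(sub["gene_id"], sub["status"]))
    rows = []
    n_missing = 0
    for gid in sorted(ortho_map.groups):
        members = ortho_map.groups[gid].get(species, ())
        if not members:
            continue
        n_up = n_down = n_ns = 0
        for gene in members:
            s = status.get(gene)
            if s is None:
                n_missing += 1
                if missing == "error":
                    raise ConsistencyError(f"gene {gene!r} in map but absent from DEG table")
                s = "ns"
            if s == "up":
                n_up += 1
            elif s == "down":
                n_down += 1
            else:
                n_ns += 1
        rows.append(
            {
                "group_id": gid,
                "species": species,
                "tissue": tissue,
                "call": majority_call(n_up, n_down),
                "n_up": n_up,
                "n_down": n_down,
                "n_ns": n_ns,
            }
        )
    if n_missing:
        logger.warning(
            "classify_orthogroup_response: %d member genes absent from DEG table (%s, %s), counted as ns",
            n_missing, species, tissue,
        )
    return pd.DataFrame(rows, columns=["group_id", "species", "tissue", "call", "n_up", "n_down", "n_ns"])


def _calls(resp: pd.DataFrame, tissue: str) -> pd.Series:
    sub = resp.loc[resp["tissue"] == tissue]
    return pd.Series(sub["call"].to_numpy(), index=sub["group_id"].to_numpy())


def consistent_sets(
    resp_a: pd.DataFrame,
    tissue_a: str,
    resp_b: pd.DataFrame,
    tissue_b: str,
) -> dict[str, set[str]]:
    """Orthogroups called up (resp. down) in both species' focal tissues.

    Conflict and none calls never enter either set.  The two responses must
    be built over the same hierarchical orthogroup universe.
    """
    a = _calls(resp_a, tissue_a)
    b = _calls(resp_b, tissue_b)
    if set(a.index) != set(b.index):
        raise ConsistencyError("orthogroup universes differ between the two responses")
    shared_up = {g for g in a.index if a[g] == "up" and b[g] == "up"}
    shared_down = {g for g in a.index if a[g] == "down" and b[g] == "down"}
    return {"shared_up": shared_up, "shared_down": shared_down}


@dataclass
class TissuePair:
    """One cell of the tissue-comparison grid handed to the setsim stage."""

    tissue_a: str
    tissue_b: str
    up_a: frozenset
    up_b: frozenset
    down_a: frozenset
    down_b: frozenset


def response_sets(resp: pd.DataFrame, tissue: str) -> dict[str, frozenset]:
    calls = _calls(resp, tissue)
    return {
        "up": frozenset(calls.index[calls == "up"]),
        "down": frozenset(calls.index[calls == "down"]),
    }


def response_matrix(
    resp_a: pd.DataFrame,
    tissues_a: Sequence[str],
    resp_b: pd.DataFrame,
    tissues_b: Sequence[str],
) -> list[TissuePair]:
    """Ordered grid of (up-set, down-set) pairs over all tissue pairs.

    In the study configuration one species contributes a single tissue (the
    digestive zone) against all six of the other's.
    """
    pairs = []
    for ta in tissues_a:
        sets_a = response_sets(resp_a, ta)
        for tb in tissues_b:
            sets_b = response_sets(resp_b, tb)
            pairs.append(
                TissuePair(
                    tissue_a=ta,
                    tissue_b=tb,
                    up_a=sets_a["up"],
                    up_b=sets_b["up"],
                    down_a=sets_a["down"],
                    down_b=sets_b["down"],
                )
            )
    return pairs
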