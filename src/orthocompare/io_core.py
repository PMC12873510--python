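"""Readers and writers for every file the pipeline touches.

All tabular formats are plain TSV.  Writers are deterministic: fixed column
order, floats at 6 significant digits, rows sorted lexicographically, so
re-running a stage on the same inputs yields byte-identical files.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ConsistencyError,
    FormatError,
    OrthogroupMap,
    validate_counts,
    validate_sample_meta,
)

logger = logging.getLogger("orthocompare")

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.6g"


def _fmt_float(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return FLOAT_FORMAT % x


# ---------------------------------------------------------------------------
# counts / metadata / lengths
# ---------------------------------------------------------------------------

def read_sample_meta(path: PathLike, tissues: Optional[Sequence[str]] = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str, "tissue": str, "condition": str})
    return validate_sample_meta(meta, tissues=tissues)


def read_counts(path: PathLike, meta_path: PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples count TSV together with its sample metadata.

    The first column of the count TSV holds gene ids; the header row holds
    sample ids.  Columns are reordered to the metadata's sample order.
    """
    meta = read_sample_meta(meta_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns.name = None
    counts = validate_counts(raw, meta)
    logger.info("read_counts: %d genes x %d samples from %s", counts.shape[0], counts.shape[1], path)
    return counts, meta


def write_counts(counts: pd.DataFrame, path: PathLike, sort_rows: bool = True) -> None:
    out = counts.sort_index() if sort_rows else counts
    out.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_meta(meta: pd.DataFrame, path: PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise FormatError("gene length table needs columns gene_id, length_bp")
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in gene length table")
    lengths = pd.to_numeric(df["length_bp"], errors="coerce")
    if lengths.isna().any() or (lengths < 1).any():
        raise FormatError("gene lengths must be integers >= 1")
    return pd.Series(lengths.astype(int).to_numpy(), index=df["gene_id"].to_numpy(), name="length_bp")


def write_gene_lengths(lengths: pd.Series, path: PathLike) -> None:
    df = lengths.sort_index().rename("length_bp").rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthogroup tables (OrthoFinder-style dialects)
# ---------------------------------------------------------------------------

_N0_FIXED = ("HOG", "OG", "Gene Tree Parent Clade")


def read_orthogroups(
    path: PathLike,
    flavor: str,
    min_species_frac: float = 0.0,
    node: Optional[str] = None,
) -> OrthogroupMap:
    """Parse an orthogroup TSV and drop sparsely represented groups.

    ``nonhierarchical`` expects the classic layout (first column the group
    id, one column per species); ``hierarchical`` expects the N0-style
    layout (HOG, OG, Gene Tree Parent Clade, then species columns).  Groups
    containing genes from fewer than ``ceil(min_species_frac * n_species)``
    of the declared species are discarded.
    """
    if not 0.0 <= min_species_frac <= 1.0:
        raise FormatError("min_species_frac must lie in [0, 1]")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        logger.warning("read_orthogroups: empty table at %s", path)
        return OrthogroupMap(flavor=flavor, groups={}, node=node)
    if flavor == "hierarchical":
        missing = [c for c in _N0_FIXED if c not in df.columns]
        if missing:
            raise FormatError(f"hierarchical orthogroup table missing columns {missing}")
        id_col = "HOG"
        species_cols = [c for c in df.columns if c not in _N0_FIXED]
    else:
        id_col = df.columns[0]
        species_cols = list(df.columns[1:])
    if not species_cols:
        raise FormatError("orthogroup table has no species columns")
    n_species = len(species_cols)
    required = math.ceil(min_species_frac * n_species)

    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    n_dropped = 0
    for _, row in df.iterrows():
        gid = row[id_col]
        members: dict[str, tuple[str, ...]] = {}
        for sp in species_cols:
            cell = row[sp]
            if isinstance(cell, str) and cell.strip():
                genes = tuple(g.strip() for g in cell.split(",") if g.strip())
                if genes:
                    members[sp] = genes
        if len(members) < max(required, 1):
            n_dropped += 1
            continue
        if gid in groups:
            raise FormatError(f"duplicate group id {gid!r}")
        groups[gid] = members
    if n_dropped:
        logger.info(
            "read_orthogroups: dropped %d groups below %.0f%% species coverage (need >= %d of %d)",
            n_dropped, 100 * min_species_frac, required, n_species,
        )
    return OrthogroupMap(flavor=flavor, groups=groups, node=node, species=tuple(species_cols))


def write_orthogroups(omap: OrthogroupMap, path: PathLike) -> None:
    species = list(omap.species)
    rows = []
    for gid in sorted(omap.groups):
        members = omap.groups[gid]
        row: dict[str, str] = {}
        if omap.flavor == "hierarchical":
            row["HOG"] = gid
            row["OG"] = gid.split(".")[-1] if "." in gid else gid
            row["Gene Tree Parent Clade"] = omap.node or ""
        else:
            row["Orthogroup"] = gid
        for sp in species:
            row[sp] = ", ".join(members.get(sp, ()))
        rows.append(row)
    lead = list(_N0_FIXED) if omap.flavor == "hierarchical" else ["Orthogroup"]
    pd.DataFrame(rows, columns=lead + species).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

DEG_COLUMNS = ("gene_id", "tissue", "log2fc", "pvalue", "fdr", "status")
ORTHO_RESPONSE_COLUMNS = ("group_id", "species", "tissue", "call", "n_up", "n_down", "n_ns")
SETSIM_COLUMNS = ("pair", "intersection", "union", "jc", "p", "fdr")
SOM_ASSIGN_COLUMNS = ("gene_id", "unit")
CONVERGENCE_COLUMNS = ("group_id", "branch_pair", "omega_c", "ocn")

_FLOAT_COLS = {"log2fc", "pvalue", "fdr", "jc", "p", "omega_c", "ocn", "mean_fpkm", "cv", "max_fpkm"}


def write_table(df: pd.DataFrame, path: PathLike, columns: Optional[Sequence[str]] = None) -> None:
    """Write a result table deterministically (fixed columns, sorted rows)."""
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(f"result table missing columns {missing}")
        df = df.loc[:, list(columns)]
    df = df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)
    out = df.copy()
    for c in out.columns:
        if c in _FLOAT_COLS or pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(_fmt_float)
    out.to_csv(path, sep="\t", index=False)


def write_deg_table(deg: pd.DataFrame, path: PathLike) -> None:
    write_table(deg, path, columns=DEG_COLUMNS)


def read_deg_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str, "status": str})
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DEG table missing columns {missing}")
    bad = set(df["status"]) - {"up", "down", "ns"}
    if bad:
        raise FormatError(f"unknown DEG status values {sorted(bad)}")
    return df.loc[:, list(DEG_COLUMNS)]


def write_ortho_response(resp: pd.DataFrame, path: PathLike) -> None:
    write_table(resp, path, columns=ORTHO_RESPONSE_COLUMNS)


def write_setsim(results: Sequence, path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "pair": r.label,
                "intersection": r.intersection_size,
                "union": r.union_size,
                "jc": r.jc,
                "p": r.pvalue,
                "fdr": r.fdr,
            }
            for r in results
        ],
        columns=SETSIM_COLUMNS,
    )
    write_table(df, path, columns=SETSIM_COLUMNS)


def write_som_assignments(assignment: pd.Series, path: PathLike) -> None:
    df = assignment.rename("unit").rename_axis("gene_id").reset_index()
    write_table(df, path, columns=SOM_ASSIGN_COLUMNS)


def read_som_assignments(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "unit"} <= set(df.columns):
        raise FormatError("SOM assignment table needs columns gene_id, unit")
    return pd.Series(df["unit"].astype(int).to_numpy(), index=df["gene_id"].to_numpy(), name="unit")


def read_convergence_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str, "branch_pair": str})
    missing = [c for c in CONVERGENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"convergence table missing columns {missing}")
    for c in ("omega_c", "ocn"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or not np.isfinite(vals).all():
            raise FormatError(f"column {c} must be finite and non-negative")
        df[c] = vals
    return df.loc[:, list(CONVERGENCE_COLUMNS)]


def log_stage(stage: str, **params) -> None:
    """One log line per pipeline stage with its parameters and counts."""
    rendered = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s %s", stage, rendered)
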