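"""Domain types shared by every pipeline stage.

Tabular data (counts, sample metadata, DEG tables, expression matrices)
lives in :class:`pandas.DataFrame` / :class:`pandas.Series` containers with
validated schemas; structured results (normalization factors, SOM models,
set-similarity records) are dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
FED = "fed"
CONDITIONS = (CONTROL, FED)

#: Default tissue list: the six dissected pitcher parts of Cephalotus.
CEPHALOTUS_TISSUES = (
    "lid",
    "neck and rim",
    "upper pitcher wall",
    "lower pitcher wall",
    "central keel",
    "petiole",
)

#: Six-tissue dissection of a Nepenthes-style pitcher leaf.
NEPENTHES_TISSUES = (
    "lid",
    "peristome",
    "waxy zone",
    "digestive zone",
    "tendril",
    "flat part",
)

DEG_STATUS = ("up", "down", "ns")
ORTHO_CALLS = ("up", "down", "conflict", "none")


class OrthocompareError(Exception):
    """Base class for all typed pipeline errors."""


class FormatError(OrthocompareError):
    """Malformed input file (bad values, duplicate ids, wrong columns)."""


class ConsistencyError(OrthocompareError):
    """Inputs that are individually valid but mutually inconsistent."""


class ConfigError(OrthocompareError):
    """Invalid configuration."""


class NormalizationError(OrthocompareError):
    """Normalization cannot proceed (e.g. an all-zero sample)."""


class EstimationError(OrthocompareError):
    """Statistical estimation cannot proceed (e.g. a single replicate)."""


class DomainError(OrthocompareError):
    """Argument outside its mathematical domain."""


class DimensionError(OrthocompareError):
    """Too few observations/features for the requested computation."""


SAMPLE_META_COLUMNS = ("sample_id", "species", "tissue", "condition", "replicate")


def validate_sample_meta(meta: pd.DataFrame, tissues: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Validate a sample-metadata table and return it with a clean index.

    Required columns: sample_id, species, tissue, condition (control/fed),
    replicate (positive integer).  sample_id must be unique; tissue labels,
    when ``tissues`` is given, must come from that declared list.
    """
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")
    meta = meta.loc[:, list(SAMPLE_META_COLUMNS)].reset_index(drop=True)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids: {dup}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
    rep = pd.to_numeric(meta["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.astype(int)).any():
        raise FormatError("replicate must be a positive integer")
    meta["replicate"] = rep.astype(int)
    if tissues is not None:
        bad = set(meta["tissue"]) - set(tissues)
        if bad:
            raise FormatError(f"tissue labels {sorted(bad)} not in declared list {list(tissues)}")
    return meta


def validate_counts(counts: pd.DataFrame, meta: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Validate a genes x samples count matrix.

    Entries must be non-negative integers; gene and sample labels must be
    duplicate-free.  When ``meta`` is given, columns are reordered to the
    metadata's sample order and must match it 1:1.
    """
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].tolist()
        raise FormatError(f"duplicate gene ids: {dup[:5]}")
    if counts.columns.duplicated().any():
        raise FormatError("duplicate sample ids in count matrix")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("non-numeric values in count matrix")
    if np.isnan(arr.astype(float)).any():
        raise FormatError("missing values in count matrix")
    if (arr < 0).any():
        raise FormatError("negative values in count matrix")
    if not np.allclose(arr, np.round(arr.astype(float))):
        raise FormatError("non-integer values in count matrix")
    counts = counts.astype(np.int64)
    if meta is not None:
        matrix_samples = set(counts.columns)
        meta_samples = set(meta["sample_id"])
        if matrix_samples != meta_samples:
            only_m = sorted(matrix_samples - meta_samples)
            only_s = sorted(meta_samples - matrix_samples)
            raise ConsistencyError(
                f"count matrix / metadata sample mismatch: only in matrix {only_m}, only in metadata {only_s}"
            )
        counts = counts.loc[:, list(meta["sample_id"])]
    return counts


@dataclass
class NormFactors:
    """TMM scaling factors for one normalization group.

    ``factors`` multiply raw library sizes to give effective library sizes;
    within each group they are rescaled to geometric mean 1.
    """

    factors: pd.Series  # sample_id -> factor > 0
    reference_sample: str
    diagnostics: Optional[pd.DataFrame] = None  # per-gene M, A, w vs the reference

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise NormalizationError("TMM factors must be positive")


@dataclass
class PCAResult:
    """Per-sample component scores and variance fractions, ordered by PC."""

    scores: pd.DataFrame  # samples x components, columns PC1, PC2, ...
    variance_fraction: np.ndarray


@dataclass
class WelchResult:
    """Welch's two-sided t-test with Satterthwaite degrees of freedom."""

    t: float
    pvalue: float
    df: float
    mean_a: float
    mean_b: float


@dataclass
class OrthogroupMap:
    """Gene -> orthogroup membership for one flavor.

    ``groups`` maps group id -> {species -> tuple of gene ids}.  Within a
    flavor each gene belongs to at most one group.  The hierarchical flavor
    is resolved at a named species-tree node (a config string).
    """

    flavor: str  # "hierarchical" | "nonhierarchical"
    groups: dict[str, dict[str, tuple[str, ...]]]
    node: Optional[str] = None
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.flavor not in ("hierarchical", "nonhierarchical"):
            raise ConfigError(f"unknown orthogroup flavor {self.flavor!r}")
        if not self.species:
            sp: set[str] = set()
            for members in self.groups.values():
                sp.update(members)
            self.species = tuple(sorted(sp))
        seen: dict[str, str] = {}
        for gid, members in self.groups.items():
            for genes in members.values():
                for g in genes:
                    if g in seen:
                        raise ConsistencyError(
                            f"gene {g!r} appears in groups {seen[g]!r} and {gid!r} ({self.flavor})"
                        )
                    seen[g] = gid

    def gene_to_group(self, species: Optional[str] = None) -> dict[str, str]:
        """Mapping gene id -> group id, optionally restricted to one species."""
        out: dict[str, str] = {}
        for gid, members in self.groups.items():
            for sp, genes in members.items():
                if species is not None and sp != species:
                    continue
                for g in genes:
                    out[g] = gid
        return out

    def genes_of(self, species: str) -> set[str]:
        return {g for members in self.groups.values() for g in members.get(species, ())}


@dataclass
class SOMModel:
    """A trained batch self-organizing map on a hexagonal grid."""

    rows: int
    cols: int
    topology: str
    unit_positions: np.ndarray  # n_units x 2 planar coordinates, spacing 1.0
    codebook: np.ndarray  # n_units x n_features
    assignment: pd.Series  # gene id -> unit index
    feature_names: tuple[str, ...]
    epochs: int
    radius_start: float
    radius_end: float
    seed: int
    quantization_errors: tuple[float, ...] = ()

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


@dataclass
class SetSimilarityResult:
    """Jaccard similarity of two orthogroup sets with its permutation test."""

    label: str
    intersection_size: int
    union_size: int
    jc: float
    pvalue: float
    fdr: float
    n_permutations: int

    def __post_init__(self) -> None:
        if self.union_size > 0:
            expected = self.intersection_size / self.union_size
            if abs(self.jc - expected) > 1e-12:
                raise ConsistencyError("jc != intersection/union")
        elif self.jc != 0.0:
            raise ConsistencyError("jc must be 0 for two empty sets")


def group_sizes(meta: pd.DataFrame) -> pd.Series:
    """Replicate counts per (species, tissue, condition) group."""
    return meta.groupby(["species", "tissue", "condition"], sort=True)["sample_id"].count()


def check_replication(meta: pd.DataFrame, min_replicates: int = 2) -> None:
    """Raise if any (species, tissue, condition) group is under-replicated."""
    sizes = group_sizes(meta)
    bad = sizes[sizes < min_replicates]
    if len(bad):
        raise ConsistencyError(
            f"groups with fewer than {min_replicates} replicates: {bad.index.tolist()}"
        )
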