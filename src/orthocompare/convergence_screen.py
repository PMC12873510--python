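"""Candidate selection for protein-convergence testing.

An orthogroup (nonhierarchical flavor) is a convergence candidate when it
contains, from EACH of the two focal species, at least one gene that is
either upregulated in a configured gland tissue (FDR < 0.05 and
log2 fold change > 1, both strict on this route) or assigned to a
configured gland-specific SOM cluster.  Externally computed convergence
statistics (omega_C, O_C^N) are then filtered at strict thresholds
omega_C > 3.0 and O_C^N > 3.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .types import ConfigError, FormatError, OrthogroupMap

logger = logging.getLogger("orthocompare")


@dataclass
class GlandConfig:
    """Per-species definition of gland tissues and gland-specific clusters."""

    gland_tissues: tuple[str, ...] = ()
    cluster_ids: tuple[int, ...] = ()
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0  # strict >, upregulation only
    n_units: Optional[int] = None  # grid size for validating cluster ids


def _qualifying_genes(
    deg_table: Optional[pd.DataFrame],
    som_assign: Optional[pd.Series],
    config: GlandConfig,
) -> set[str]:
    genes: set[str] = set()
    if deg_table is not None and config.gland_tissues:
        sub = deg_table.loc[
            deg_table["tissue"].isin(config.gland_tissues)
            & (deg_table["fdr"] < config.fdr_threshold)
            & (deg_table["log2fc"] > config.lfc_threshold)
        ]
        genes.update(sub["gene_id"])
    if som_assign is not None and config.cluster_ids:
        if config.n_units is not None:
            valid = set(range(config.n_units))
        else:  # no grid declared: validate against the observed units
            valid = set(int(u) for u in som_assign.unique())
        missing = set(config.cluster_ids) - valid
        if missing:
            raise ConfigError(f"configured SOM clusters absent from the model: {sorted(missing)}")
        genes.update(som_assign.index[som_assign.isin(list(config.cluster_ids))])
    return genes


def select_candidate_orthogroups(
    deg_a: Optional[pd.DataFrame],
    deg_b: Optional[pd.DataFrame],
    som_assign_a: Optional[pd.Series],
    som_assign_b: Optional[pd.Series],
    ortho_map: OrthogroupMap,
    species_a: str,
    species_b: str,
    config_a: GlandConfig,
    config_b: GlandConfig,
) -> list[str]:
    """Sorted ids of orthogroups with qualifying genes from both species."""
    qual_a = _qualifying_genes(deg_a, som_assign_a, config_a)
    qual_b = _qualifying_genes(deg_b, som_assign_b, config_b)
    selected = []
    for gid in sorted(ortho_map.groups):
        members = ortho_map.groups[gid]
        has_a = any(g in qual_a for g in members.get(species_a, ()))
        has_b = any(g in qual_b for g in members.get(species_b, ()))
        if has_a and has_b:
            selected.append(gid)
    logger.info(
        "select_candidate_orthogroups: %d candidates (%d qualifying %s genes, %d qualifying %s genes)",
        len(selected), len(qual_a), species_a, len(qual_b), species_b,
    )
    return selected


def filter_convergence(
    records: pd.DataFrame,
    omega_min: float = 3.0,
    ocn_min: float = 3.0,
) -> pd.DataFrame:
    """Keep records with omega_c > omega_min AND ocn > ocn_min (strict)."""
    for c in ("group_id", "branch_pair", "omega_c", "ocn"):
        if c not in records.columns:
            raise FormatError(f"convergence records missing column {c!r}")
    kept = records.loc[(records["omega_c"] > omega_min) & (records["ocn"] > ocn_min)].copy()
    logger.info(
        "filter_convergence: %d of %d branch pairs survive (omega_c > %.3g, ocn > %.3g); %d distinct orthogroups",
        len(kept), len(records), omega_min, ocn_min, kept["group_id"].nunique(),
    )
    return kept.reset_index(drop=True)
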