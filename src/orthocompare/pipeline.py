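"""End-to-end orchestration: simulate -> normalize -> DEG -> orthogroup
classification -> SOM -> cross-species comparison -> convergence screen.

``run_all`` drives every stage from one flat configuration and records a
manifest of parameters, seeds, and per-stage record counts.  Stages
communicate only through the declared table formats / containers, and the
run is bit-reproducible given the master seed: per-stage sub-seeds are
derived as crc32(stage name) mixed with the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .convergence_screen import GlandConfig, filter_convergence, select_candidate_orthogroups
from .deg import test_de
from .expression import (
    compute_fpkm,
    compute_tmm_factors,
    filter_low_count,
    group_means,
    pca_overview,
    select_high_cv_genes,
    zscale,
)
from .ortho_response import classify_orthogroup_response, response_matrix
from .setsim import SetPair, similarity_matrix
from .som import cluster_profiles, match_clusters, train_som
from .synthetic_data import SyntheticConfig, SyntheticDataset, generate
from .types import OrthocompareError, OrthogroupMap

logger = logging.getLogger("orthocompare")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, kept below 2^31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


def species_universe(omap: OrthogroupMap, genes, species: str) -> list[str]:
    """Hierarchical orthogroups containing >= 1 tested gene of a species."""
    tested = set(genes)
    out = []
    for gid in sorted(omap.groups):
        members = omap.groups[gid].get(species, ())
        if any(g in tested for g in members):
            out.append(gid)
    return out


def gland_clusters(profiles: pd.DataFrame, gland_tissue: str) -> list[int]:
    """SOM units whose mean z-profile peaks in the gland tissue."""
    units = []
    for u, row in profiles.iterrows():
        peak = row.idxmax()
        if str(peak).split("|")[0] == gland_tissue:
            units.append(int(u))
    return units


def run_all(
    config: Optional[SyntheticConfig] = None,
    out_dir: Optional[Path] = None,
    n_perm: int = 10000,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    top_cv_frac: float = 0.10,
    min_fpkm: float = 1.0,
    som_rows: int = 3,
    som_cols: int = 4,
    som_epochs: int = 100,
    seed: int = 0,
    convergence_table: Optional[pd.DataFrame] = None,
    dataset: Optional[SyntheticDataset] = None,
) -> dict[str, Any]:
    """Run the full synthetic analysis; returns a result bundle + manifest.

    A pre-generated ``dataset`` can be supplied; otherwise one is simulated
    from ``config`` (whose seed is overridden by the ``seed`` argument).
    """
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "n_perm": n_perm,
            "fdr_threshold": fdr_threshold,
            "lfc_threshold": lfc_threshold,
            "top_cv_frac": top_cv_frac,
            "min_fpkm": min_fpkm,
            "som_grid": [som_rows, som_cols],
            "som_epochs": som_epochs,
        },
        "stages": {},
    }
    try:
        if dataset is None:
            config = config or SyntheticConfig()
            config = dataclasses.replace(config, seed=stage_seed(seed, "simulate"))
            dataset = generate(config)
        manifest["stages"]["simulate"] = {
            sp: {"genes": int(df.shape[0]), "samples": int(df.shape[1])}
            for sp, df in dataset.counts.items()
        }
    except OrthocompareError as err:
        raise OrthocompareError(f"stage simulate failed: {err}") from err

    species_names = list(dataset.counts)
    results: dict[str, Any] = {"dataset": dataset, "manifest": manifest}

    deg_tables: dict[str, pd.DataFrame] = {}
    expr_means: dict[str, pd.DataFrame] = {}
    fpkms: dict[str, pd.DataFrame] = {}
    filtered_counts: dict[str, pd.DataFrame] = {}
    for sp in species_names:
        try:
            counts = filter_low_count(dataset.counts[sp], min_total=1)
            factors = compute_tmm_factors(counts)
            fpkm = compute_fpkm(counts, dataset.lengths[sp], factors)
            means = group_means(fpkm, dataset.meta[sp])
            filtered_counts[sp] = counts
            expr_means[sp] = means
            fpkms[sp] = fpkm
            manifest["stages"][f"normalize:{sp}"] = {
                "genes_kept": int(counts.shape[0]),
                "reference_sample": factors.reference_sample,
            }
        except OrthocompareError as err:
            raise OrthocompareError(f"stage normalize:{sp} failed: {err}") from err
        try:
            tissues = list(dataset.meta[sp]["tissue"].drop_duplicates())
            tables = [
                test_de(
                    counts,
                    dataset.meta[sp],
                    factors,
                    tissue,
                    fdr_threshold=fdr_threshold,
                    lfc_threshold=lfc_threshold,
                )
                for tissue in tissues
            ]
            deg_tables[sp] = pd.concat(tables, ignore_index=True)
            manifest["stages"][f"deg:{sp}"] = {
                "tissues": len(tissues),
                "n_up": int((deg_tables[sp]["status"] == "up").sum()),
                "n_down": int((deg_tables[sp]["status"] == "down").sum()),
            }
        except OrthocompareError as err:
            raise OrthocompareError(f"stage deg:{sp} failed: {err}") from err

    # orthogroup-level responses (hierarchical flavor)
    responses: dict[str, pd.DataFrame] = {}
    for sp in species_names:
        tissues = list(dataset.meta[sp]["tissue"].drop_duplicates())
        parts = [
            classify_orthogroup_response(deg_tables[sp], dataset.hog_map, sp, tissue)
            for tissue in tissues
        ]
        responses[sp] = pd.concat(parts, ignore_index=True)
        manifest["stages"][f"ortho_response:{sp}"] = {
            "calls": int(len(responses[sp])),
            "up": int((responses[sp]["call"] == "up").sum()),
            "down": int((responses[sp]["call"] == "down").sum()),
        }
    results["deg_tables"] = deg_tables
    results["responses"] = responses
    results["expr_means"] = expr_means

    # PCA overview of feeding-responsive genes, per species
    pca_results = {}
    for sp in species_names:
        table = deg_tables[sp]
        responsive = sorted(set(table.loc[table["status"] != "ns", "gene_id"]))
        if len(responsive) >= 2:
            pca = pca_overview(np.log2(fpkms[sp].loc[responsive] + 1.0))
            pca_results[sp] = pca
            manifest["stages"][f"pca:{sp}"] = {
                "genes": len(responsive),
                "pc1_variance_pct": round(100 * float(pca.variance_fraction[0]), 2),
                "pc2_variance_pct": round(100 * float(pca.variance_fraction[1]), 2),
            }
    results["pca"] = pca_results

    # tissue-pair similarity matrices (up / down corrected separately)
    sp_a, sp_b = species_names
    tissues_a = list(dataset.meta[sp_a]["tissue"].drop_duplicates())
    tissues_b = list(dataset.meta[sp_b]["tissue"].drop_duplicates())
    grid = response_matrix(responses[sp_a], tissues_a, responses[sp_b], tissues_b)
    universes = {}
    for sp, counts in filtered_counts.items():
        uni = species_universe(dataset.hog_map, counts.index, sp)
        for tissue in dataset.meta[sp]["tissue"].drop_duplicates():
            universes[f"{sp}:{tissue}"] = uni
    setsim_seed = stage_seed(seed, "setsim")
    matrices: dict[str, list] = {}
    for direction in ("up", "down"):
        pairs = [
            SetPair(
                label=f"{cell.tissue_a} x {cell.tissue_b}",
                side_a=f"{sp_a}:{cell.tissue_a}",
                side_b=f"{sp_b}:{cell.tissue_b}",
                set_a=cell.up_a if direction == "up" else cell.down_a,
                set_b=cell.up_b if direction == "up" else cell.down_b,
            )
            for cell in grid
        ]
        matrices[direction] = similarity_matrix(
            pairs, universes, n_perm=n_perm, seed=stage_seed(setsim_seed, direction)
        )
        manifest["stages"][f"setsim:{direction}"] = {
            "pairs": len(pairs),
            "significant": sum(r.fdr < fdr_threshold for r in matrices[direction]),
        }
    results["tissue_similarity"] = matrices

    # SOM per species on high-CV genes
    som_models = {}
    som_profiles = {}
    zmats = {}
    for sp in species_names:
        stats = select_high_cv_genes(expr_means[sp], top_frac=top_cv_frac, min_fpkm=min_fpkm)
        selected = stats.index[stats["selected"]]
        zm = zscale(expr_means[sp].loc[selected])
        model = train_som(
            zm,
            rows=som_rows,
            cols=som_cols,
            epochs=som_epochs,
            seed=stage_seed(seed, f"som:{sp}"),
        )
        prof, sizes = cluster_profiles(model, zm)
        som_models[sp] = model
        som_profiles[sp] = prof
        zmats[sp] = zm
        manifest["stages"][f"som:{sp}"] = {
            "genes_clustered": int(len(model.assignment)),
            "units": model.n_units,
        }
    results["som_models"] = som_models
    results["som_profiles"] = som_profiles

    cluster_matches = match_clusters(
        som_models[sp_a].assignment,
        som_models[sp_b].assignment,
        dataset.hog_map.gene_to_group(sp_a),
        dataset.hog_map.gene_to_group(sp_b),
        n_units_a=som_models[sp_a].n_units,
        n_units_b=som_models[sp_b].n_units,
        n_perm=n_perm,
        seed=stage_seed(seed, "match_clusters"),
        label_a="A",
        label_b="B",
    )
    manifest["stages"]["match_clusters"] = {
        "pairs": len(cluster_matches),
        "significant": sum(r.fdr < fdr_threshold for r in cluster_matches),
    }
    results["cluster_matches"] = cluster_matches

    # convergence candidate screen (nonhierarchical flavor)
    cfg = dataset.truth.config
    gland_a = cfg.gland_tissue_a
    gland_b = cfg.gland_tissue_b
    config_a = GlandConfig(
        gland_tissues=(gland_a,),
        cluster_ids=tuple(gland_clusters(som_profiles[sp_a], gland_a)),
        n_units=som_models[sp_a].n_units,
    )
    config_b = GlandConfig(
        gland_tissues=(gland_b,),
        cluster_ids=tuple(gland_clusters(som_profiles[sp_b], gland_b)),
        n_units=som_models[sp_b].n_units,
    )
    candidates = select_candidate_orthogroups(
        deg_tables[sp_a],
        deg_tables[sp_b],
        som_models[sp_a].assignment,
        som_models[sp_b].assignment,
        dataset.og_map,
        sp_a,
        sp_b,
        config_a,
        config_b,
    )
    manifest["stages"]["convergence_screen"] = {"candidates": len(candidates)}
    results["candidates"] = candidates
    if convergence_table is not None:
        surviving = filter_convergence(
            convergence_table.loc[convergence_table["group_id"].isin(candidates)]
        )
        manifest["stages"]["convergence_filter"] = {
            "branch_pairs": int(len(surviving)),
            "orthogroups": int(surviving["group_id"].nunique()),
        }
        results["convergence"] = surviving

    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def _write_outputs(results: dict[str, Any], out: Path) -> None:
    from . import io_core
    from .synthetic_data import write_dataset

    out.mkdir(parents=True, exist_ok=True)
    write_dataset(results["dataset"], out / "data")
    for sp, table in results["deg_tables"].items():
        io_core.write_deg_table(table, out / f"deg_{sp}.tsv")
    for sp, resp in results["responses"].items():
        io_core.write_ortho_response(resp, out / f"ortho_response_{sp}.tsv")
    for direction, mats in results["tissue_similarity"].items():
        io_core.write_setsim(mats, out / f"setsim_tissue_{direction}.tsv")
    io_core.write_setsim(results["cluster_matches"], out / "setsim_clusters.tsv")
    for sp, model in results["som_models"].items():
        io_core.write_som_assignments(model.assignment, out / f"som_assignments_{sp}.tsv")
    with open(out / "candidates.txt", "w") as fh:
        fh.write("\n".join(results["candidates"]) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=1, sort_keys=True)
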