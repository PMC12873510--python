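"""Two-species synthetic count datasets with known ground truth.

The generator emulates the study design: two independently evolved pitcher
plant species, six dissected pitcher tissues each, a water control (4
replicates) and a prey-mimic feeding treatment (8 replicates), gene-level
negative-binomial counts, planted feeding-response DEGs, planted
tissue-specific expression modules shared between orthologous genes, and
orthogroup tables in both OrthoFinder-style flavors.  Every planted signal
is recorded in a truth object so downstream stages can be scored.

Counts are drawn as NB with mean

    baseline_g * tissue_profile_{g,t} * condition_effect_{g,t,c} * libsize_s / mean_libsize

and per-gene dispersion.  One random stream per species is derived from
the master seed, so adding or regenerating one species never perturbs the
other's data; a separate structural stream drives the cross-species
skeleton (orthology, modules, shared responses).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ortho_response import majority_call
from .types import (
    CEPHALOTUS_TISSUES,
    NEPENTHES_TISSUES,
    ConfigError,
    DomainError,
    OrthogroupMap,
)

logger = logging.getLogger("orthocompare")


@dataclass
class SpeciesConfig:
    name: str
    tissues: tuple[str, ...]
    n_genes: int = 5000


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-species dataset.

    Defaults mirror the experimental design (6 tissues, 4 control / 8 fed
    replicates) with conventional bulk RNA-seq parameters; the gland
    tissue pair (lower pitcher wall <-> digestive zone) carries the planted
    shared feeding response.
    """

    species_a: SpeciesConfig = field(
        default_factory=lambda: SpeciesConfig("cephalotus_like", CEPHALOTUS_TISSUES)
    )
    species_b: SpeciesConfig = field(
        default_factory=lambda: SpeciesConfig("nepenthes_like", NEPENTHES_TISSUES)
    )
    n_orthogroups: int = 3000
    frac_one_to_one: float = 0.6
    merge_frac: float = 0.10  # HOG pairs merged into one coarser OG
    n_modules: int = 12
    tissue_specific_frac: float = 0.085
    module_peak: float = 12.0
    peak_log2_spread: float = 0.5  # per-gene amplitude = peak * 2^U(-s, s)
    module_attenuation_log2: float = 2.0
    shared_module_frac: float = 0.9
    n_control: int = 4
    n_fed: int = 8
    de_fraction: float = 0.05
    lfc_min: float = 1.5
    lfc_max: float = 2.5
    n_shared_up: int = 150
    n_shared_down: int = 60
    n_conflict: int = 30
    gland_tissue_a: str = "lower pitcher wall"
    gland_tissue_b: str = "digestive zone"
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.0
    length_range: tuple[int, int] = (300, 10000)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.n_control < 2 or self.n_fed < 2:
            raise ConfigError("each condition needs >= 2 replicates")
        if not 0.0 <= self.frac_one_to_one <= 1.0:
            raise ConfigError("frac_one_to_one must lie in [0, 1]")
        if self.lfc_min < 1.0:
            raise ConfigError("planted |log2 effect| minimum must be >= 1.0")
        if len(self.species_a.tissues) != len(self.species_b.tissues):
            raise ConfigError("both species need equally many tissues (positional correspondence)")
        for sp, gland in (
            (self.species_a, self.gland_tissue_a),
            (self.species_b, self.gland_tissue_b),
        ):
            if gland not in sp.tissues:
                raise ConfigError(f"gland tissue {gland!r} not in {sp.name} tissue list")
        if self.dispersion_range[0] <= 0 or self.dispersion_range[0] > self.dispersion_range[1]:
            raise ConfigError("invalid dispersion range")


@dataclass
class SyntheticTruth:
    """Complete description of every planted signal."""

    planted: pd.DataFrame  # species, tissue, gene_id, direction, log2_effect
    modules: dict[str, pd.Series]  # species -> gene_id -> module id (-1 = flat)
    shared_module_groups: set[str]  # hierarchical ids of 1:1 pairs sharing a module
    shared_up_groups: set[str]
    shared_down_groups: set[str]
    conflict_groups: dict[str, set[str]]  # species -> hierarchical ids
    dispersions: dict[str, pd.Series]
    lib_sizes: dict[str, pd.Series]
    hog_map: OrthogroupMap = None  # hierarchical flavor
    og_map: OrthogroupMap = None  # nonhierarchical flavor
    config: SyntheticConfig = None
    seed: int = 0
    amplitudes: dict[str, pd.Series] = None  # peak multiplier per gene, shared within ortholog pairs


@dataclass
class SyntheticDataset:
    counts: dict[str, pd.DataFrame]
    meta: dict[str, pd.DataFrame]
    lengths: dict[str, pd.Series]
    hog_map: OrthogroupMap
    og_map: OrthogroupMap
    truth: SyntheticTruth


def _stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode()) & 0x7FFFFFFF])
    )


def generate(config: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Generate the full two-species dataset plus its truth object."""
    config = config or SyntheticConfig()
    config.validate()
    seed = config.seed
    rng_struct = _stream(seed, "structure")
    species = (config.species_a, config.species_b)
    names = tuple(sp.name for sp in species)

    # ----- orthogroup skeleton ---------------------------------------------
    n_og = config.n_orthogroups
    n_one = int(round(config.frac_one_to_one * n_og))
    gene_counts: list[dict[str, int]] = []
    for i in range(n_og):
        if i < n_one:
            gene_counts.append({names[0]: 1, names[1]: 1})
        else:
            while True:
                ca, cb = rng_struct.choice(4, size=2, p=[0.15, 0.45, 0.25, 0.15])
                if ca or cb:
                    break
            gene_counts.append({names[0]: int(ca), names[1]: int(cb)})

    next_idx = {n: 0 for n in names}
    hog_groups: dict[str, dict[str, tuple[str, ...]]] = {}
    for i, counts_i in enumerate(gene_counts):
        gid = f"N0.HOG{i:07d}"
        members: dict[str, tuple[str, ...]] = {}
        for sp_name in names:
            k = counts_i.get(sp_name, 0)
            if k:
                genes = tuple(
                    f"{sp_name}_g{next_idx[sp_name] + j:05d}" for j in range(k)
                )
                next_idx[sp_name] += k
                members[sp_name] = genes
        hog_groups[gid] = members
    # pad each species with unmapped singleton genes up to n_genes
    gene_lists: dict[str, list[str]] = {}
    for sp in species:
        n_used = next_idx[sp.name]
        if n_used > sp.n_genes:
            raise ConfigError(
                f"orthogroup skeleton needs {n_used} {sp.name} genes > n_genes={sp.n_genes}"
            )
        gene_lists[sp.name] = [f"{sp.name}_g{i:05d}" for i in range(sp.n_genes)]

    # nonhierarchical flavor: merge a fraction of consecutive HOG pairs
    hog_ids = sorted(hog_groups)
    og_groups: dict[str, dict[str, tuple[str, ...]]] = {}
    i = 0
    og_idx = 0
    while i < len(hog_ids):
        merge = (
            i + 1 < len(hog_ids) and rng_struct.random() < config.merge_frac
        )
        chunk = hog_ids[i : i + 2] if merge else hog_ids[i : i + 1]
        members: dict[str, list[str]] = {}
        for hid in chunk:
            for sp_name, genes in hog_groups[hid].items():
                members.setdefault(sp_name, []).extend(genes)
        og_groups[f"OG{og_idx:07d}"] = {k: tuple(v) for k, v in members.items()}
        og_idx += 1
        i += len(chunk)

    hog_map = OrthogroupMap(
        flavor="hierarchical", groups=hog_groups, node="MRCA(two focal species)", species=names
    )
    og_map = OrthogroupMap(flavor="nonhierarchical", groups=og_groups, species=names)

    # ----- modules ----------------------------------------------------------
    n_t = len(config.species_a.tissues)
    modules: dict[str, pd.Series] = {
        n: pd.Series(-1, index=gene_lists[n], dtype=int) for n in names
    }
    amplitudes: dict[str, pd.Series] = {
        n: pd.Series(1.0, index=gene_lists[n], dtype=float) for n in names
    }
    spread = config.peak_log2_spread

    def _amp() -> float:
        return float(config.module_peak * 2.0 ** rng_struct.uniform(-spread, spread))

    shared_module_groups: set[str] = set()
    one_to_one_ids = hog_ids[:n_one]
    module_cycle = 0
    for gid in one_to_one_ids:
        if rng_struct.random() >= config.tissue_specific_frac:
            continue
        # round-robin over modules: planted modules are equal-sized
        m = module_cycle % config.n_modules
        module_cycle += 1
        ga = hog_groups[gid][names[0]][0]
        gb = hog_groups[gid][names[1]][0]
        if rng_struct.random() < config.shared_module_frac:
            # conserved tissue specificity: same profile class AND strength
            amp = _amp()
            modules[names[0]][ga] = m
            modules[names[1]][gb] = m
            amplitudes[names[0]][ga] = amp
            amplitudes[names[1]][gb] = amp
            shared_module_groups.add(gid)
        else:
            m2 = int(rng_struct.integers(config.n_modules))
            modules[names[0]][ga] = m
            modules[names[1]][gb] = m2
            amplitudes[names[0]][ga] = _amp()
            amplitudes[names[1]][gb] = _amp()
    for sp in species:
        # top up each species to exactly the configured specific fraction
        unassigned = [g for g in gene_lists[sp.name] if modules[sp.name][g] < 0]
        n_assigned = sp.n_genes - len(unassigned)
        n_more = max(0, int(round(config.tissue_specific_frac * sp.n_genes)) - n_assigned)
        picks = rng_struct.choice(len(unassigned), size=min(n_more, len(unassigned)), replace=False)
        mods_extra = rng_struct.integers(config.n_modules, size=len(picks))
        for gi, m in zip(picks, mods_extra):
            g = unassigned[int(gi)]
            modules[sp.name][g] = int(m)
            amplitudes[sp.name][g] = _amp()

    # ----- planted feeding responses ---------------------------------------
    planted_rows: list[dict] = []
    planted_index: dict[str, set[tuple[str, str]]] = {n: set() for n in names}

    def plant(sp_name: str, tissue: str, gene: str, direction: str, effect: float) -> bool:
        key = (gene, tissue)
        if key in planted_index[sp_name]:
            return False
        planted_index[sp_name].add(key)
        planted_rows.append(
            {
                "species": sp_name,
                "tissue": tissue,
                "gene_id": gene,
                "direction": direction,
                "log2_effect": effect if direction == "up" else -effect,
            }
        )
        return True

    glands = {names[0]: config.gland_tissue_a, names[1]: config.gland_tissue_b}
    candidates = list(one_to_one_ids)
    rng_struct.shuffle(candidates)
    shared_up = set(candidates[: config.n_shared_up])
    shared_down = set(
        candidates[config.n_shared_up : config.n_shared_up + config.n_shared_down]
    )
    for gid in sorted(shared_up | shared_down):
        direction = "up" if gid in shared_up else "down"
        effect = float(rng_struct.uniform(config.lfc_min, config.lfc_max))
        for sp_name in names:
            gene = hog_groups[gid][sp_name][0]
            plant(sp_name, glands[sp_name], gene, direction, effect)

    conflict_groups: dict[str, set[str]] = {n: set() for n in names}
    for sp_name in names:
        pool = [
            gid
            for gid in hog_ids[n_one:]
            if len(hog_groups[gid].get(sp_name, ())) >= 2
        ]
        rng_struct.shuffle(pool)
        for gid in pool[: config.n_conflict]:
            g1, g2 = hog_groups[gid][sp_name][:2]
            e1 = float(rng_struct.uniform(config.lfc_min, config.lfc_max))
            e2 = float(rng_struct.uniform(config.lfc_min, config.lfc_max))
            plant(sp_name, glands[sp_name], g1, "up", e1)
            plant(sp_name, glands[sp_name], g2, "down", e2)
            conflict_groups[sp_name].add(gid)

    # feeding-attenuated modules: the repression in the peak tissue is a
    # real planted down response, recorded like any other effect
    for sp in species:
        mods_sp = modules[sp.name]
        for gene, m in mods_sp[mods_sp >= n_t].items():
            plant(
                sp.name,
                sp.tissues[int(m) % n_t],
                gene,
                "down",
                config.module_attenuation_log2,
            )

    for sp in species:
        rng_sp = _stream(seed, sp.name + ":plant")
        n_de = int(round(config.de_fraction * sp.n_genes))
        for tissue in sp.tissues:
            picks = rng_sp.choice(sp.n_genes, size=n_de, replace=False)
            dirs = rng_sp.random(n_de) < 0.5
            effects = rng_sp.uniform(config.lfc_min, config.lfc_max, size=n_de)
            for gi, is_up, eff in zip(picks, dirs, effects):
                gene = gene_lists[sp.name][int(gi)]
                plant(sp.name, tissue, gene, "up" if is_up else "down", float(eff))

    planted = pd.DataFrame(
        planted_rows, columns=["species", "tissue", "gene_id", "direction", "log2_effect"]
    )

    # ----- counts -----------------------------------------------------------
    counts: dict[str, pd.DataFrame] = {}
    metas: dict[str, pd.DataFrame] = {}
    lengths: dict[str, pd.Series] = {}
    dispersions: dict[str, pd.Series] = {}
    lib_sizes: dict[str, pd.Series] = {}

    for sp in species:
        rng_sp = _stream(seed, sp.name)
        genes = gene_lists[sp.name]
        n_g = len(genes)
        baseline = rng_sp.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_g)
        lo, hi = config.dispersion_range
        phi = np.exp(rng_sp.uniform(np.log(lo), np.log(hi), n_g))
        lens = np.exp(
            rng_sp.uniform(np.log(config.length_range[0]), np.log(config.length_range[1]), n_g)
        ).astype(int)

        rows = []
        for t_idx, tissue in enumerate(sp.tissues):
            for condition, n_rep in (("control", config.n_control), ("fed", config.n_fed)):
                for rep in range(1, n_rep + 1):
                    rows.append(
                        {
                            "sample_id": f"{sp.name}_t{t_idx}_{condition}{rep}",
                            "species": sp.name,
                            "tissue": tissue,
                            "condition": condition,
                            "replicate": rep,
                        }
                    )
        meta = pd.DataFrame(rows)
        libs = rng_sp.uniform(*config.libsize_range, size=len(meta))
        lib_factor = libs / libs.mean()

        mod = modules[sp.name].to_numpy()
        amp = amplitudes[sp.name].to_numpy()
        tissue_mult = np.ones((n_g, n_t))
        specific = np.flatnonzero(mod >= 0)
        tissue_mult[specific, mod[specific] % n_t] = amp[specific]

        effect_mult = np.ones((n_g, n_t))
        sub = planted.loc[planted["species"] == sp.name]
        gene_pos = {g: i for i, g in enumerate(genes)}
        t_pos = {t: i for i, t in enumerate(sp.tissues)}
        for _, row in sub.iterrows():
            effect_mult[gene_pos[row["gene_id"]], t_pos[row["tissue"]]] = 2.0 ** row["log2_effect"]

        mat = np.empty((n_g, len(meta)), dtype=np.int64)
        for s_idx, (_, srow) in enumerate(meta.iterrows()):
            t_idx = t_pos[srow["tissue"]]
            mu = baseline * tissue_mult[:, t_idx]
            if srow["condition"] == "fed":
                mu = mu * effect_mult[:, t_idx]
            mu = mu * lib_factor[s_idx]
            r = 1.0 / phi
            p = r / (r + mu)
            mat[:, s_idx] = rng_sp.negative_binomial(r, p)

        counts[sp.name] = pd.DataFrame(mat, index=genes, columns=list(meta["sample_id"]))
        metas[sp.name] = meta
        lengths[sp.name] = pd.Series(lens, index=genes, name="length_bp")
        dispersions[sp.name] = pd.Series(phi, index=genes, name="dispersion")
        lib_sizes[sp.name] = pd.Series(libs, index=meta["sample_id"], name="lib_size")
        logger.info("synthetic_data: generated %s (%d genes, %d samples)", sp.name, n_g, len(meta))

    truth = SyntheticTruth(
        planted=planted,
        modules=modules,
        amplitudes=amplitudes,
        shared_module_groups=shared_module_groups,
        shared_up_groups=shared_up,
        shared_down_groups=shared_down,
        conflict_groups=conflict_groups,
        dispersions=dispersions,
        lib_sizes=lib_sizes,
        hog_map=hog_map,
        og_map=og_map,
        config=config,
        seed=seed,
    )
    return SyntheticDataset(
        counts=counts, meta=metas, lengths=lengths, hog_map=hog_map, og_map=og_map, truth=truth
    )


def truth_sets(truth: SyntheticTruth, species: str, tissue: str) -> dict[str, set[str]]:
    """Expected orthogroup-level up/down sets from the planted effects.

    Applies the same majority rule as the pipeline to the planted gene
    directions (every planted gene is a true DEG by construction).
    """
    if species not in truth.modules:
        raise DomainError(f"unknown species {species!r}")
    cfg = truth.config
    tissues = (
        cfg.species_a.tissues if species == cfg.species_a.name else cfg.species_b.tissues
    )
    if tissue not in tissues:
        raise DomainError(f"unknown tissue {tissue!r} for species {species!r}")
    sub = truth.planted.loc[
        (truth.planted["species"] == species) & (truth.planted["tissue"] == tissue)
    ]
    direction = dict(zip(sub["gene_id"], sub["direction"]))
    up: set[str] = set()
    down: set[str] = set()
    for gid, members in truth.hog_map.groups.items():
        genes = members.get(species, ())
        if not genes:
            continue
        n_up = sum(1 for g in genes if direction.get(g) == "up")
        n_down = sum(1 for g in genes if direction.get(g) == "down")
        call = majority_call(n_up, n_down)
        if call == "up":
            up.add(gid)
        elif call == "down":
            down.add(gid)
    return {"up": up, "down": down}


def write_dataset(data: SyntheticDataset, out_dir) -> None:
    """Emit all io_core formats plus a truth.json summary."""
    from . import io_core

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp_name in data.counts:
        io_core.write_counts(data.counts[sp_name], out / f"counts_{sp_name}.tsv")
        io_core.write_sample_meta(data.meta[sp_name], out / f"samples_{sp_name}.tsv")
        io_core.write_gene_lengths(data.lengths[sp_name], out / f"gene_lengths_{sp_name}.tsv")
    io_core.write_orthogroups(data.hog_map, out / "N0.tsv")
    io_core.write_orthogroups(data.og_map, out / "Orthogroups.tsv")
    truth = data.truth
    payload = {
        "seed": truth.seed,
        "planted": truth.planted.to_dict(orient="records"),
        "modules": {sp: s[s >= 0].to_dict() for sp, s in truth.modules.items()},
        "shared_module_groups": sorted(truth.shared_module_groups),
        "shared_up_groups": sorted(truth.shared_up_groups),
        "shared_down_groups": sorted(truth.shared_down_groups),
        "conflict_groups": {sp: sorted(v) for sp, v in truth.conflict_groups.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
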