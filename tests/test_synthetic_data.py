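import dataclasses

import numpy as np
import pandas as pd
import pytest

from orthocompare import synthetic_data as sd
from orthocompare.types import ConfigError, DomainError

from conftest import small_config
from _oracles import majority_oracle


class TestDeterminism:
    def test_same_seed_is_bit_identical(self):
        d1 = sd.generate(small_config(seed=3))
        d2 = sd.generate(small_config(seed=3))
        for sp in d1.counts:
            pd.testing.assert_frame_equal(d1.counts[sp], d2.counts[sp])
        pd.testing.assert_frame_equal(d1.truth.planted, d2.truth.planted)

    def test_renaming_one_species_leaves_the_other_untouched(self):
        base = small_config(seed=3)
        d1 = sd.generate(base)
        renamed = small_config(
            seed=3,
            species_b=sd.SpeciesConfig("other_pitcher", base.species_b.tissues, n_genes=400),
        )
        d2 = sd.generate(renamed)
        spa = base.species_a.name
        pd.testing.assert_frame_equal(d1.counts[spa], d2.counts[spa])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"de_fraction": 1.5},
            {"n_control": 1},
            {"lfc_min": 0.5},
            {"gland_tissue_a": "not a tissue"},
            {"dispersion_range": (0.0, 0.3)},
        ],
    )
    def test_inconsistent_config_rejected(self, overrides):
        with pytest.raises(ConfigError):
            small_config(**overrides).validate()


class TestCountDistribution:
    def test_near_poisson_at_vanishing_dispersion(self):
        cfg = small_config(
            seed=9,
            dispersion_range=(1e-6, 2e-6),
            tissue_specific_frac=0.0,
            de_fraction=0.0,
            n_shared_up=0,
            n_shared_down=0,
            n_conflict=0,
            baseline_log_mean=float(np.log(300.0)),
            baseline_log_sd=0.2,
        )
        cfg = dataclasses.replace(
            cfg,
            species_a=sd.SpeciesConfig(cfg.species_a.name, cfg.species_a.tissues, 1200),
            species_b=sd.SpeciesConfig(cfg.species_b.name, cfg.species_b.tissues, 1200),
        )
        data = sd.generate(cfg)
        sp = cfg.species_a.name
        meta = data.meta[sp]
        fed = meta.loc[
            (meta["tissue"] == cfg.species_a.tissues[0]) & (meta["condition"] == "fed"),
            "sample_id",
        ]
        libs = data.truth.lib_sizes[sp].reindex(list(fed))
        lib_factor = (libs / data.truth.lib_sizes[sp].mean()).to_numpy()
        block = data.counts[sp].loc[:, list(fed)].to_numpy(dtype=float) / lib_factor
        ratio = block.var(axis=1, ddof=1) / block.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_dispersion_recovered_by_method_of_moments(self):
        cfg = small_config(
            seed=5,
            dispersion_range=(0.15, 0.15000001),
            de_fraction=0.0,
            tissue_specific_frac=0.0,
            n_shared_up=0,
            n_shared_down=0,
            n_conflict=0,
            baseline_log_mean=float(np.log(400.0)),
            baseline_log_sd=0.3,
        )
        cfg = dataclasses.replace(
            cfg,
            species_a=sd.SpeciesConfig(cfg.species_a.name, cfg.species_a.tissues, 2000),
            species_b=sd.SpeciesConfig(cfg.species_b.name, cfg.species_b.tissues, 500),
        )
        data = sd.generate(cfg)
        sp = cfg.species_a.name
        meta = data.meta[sp]
        fed = meta.loc[
            (meta["tissue"] == cfg.species_a.tissues[0]) & (meta["condition"] == "fed"),
            "sample_id",
        ]
        block = data.counts[sp].loc[:, list(fed)].to_numpy(dtype=float)
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        phi_hat = np.median((v - m) / m**2)
        assert abs(phi_hat - 0.15) / 0.15 < 0.20

    def test_planted_effects_respect_declared_minimum(self, small_dataset):
        assert (small_dataset.truth.planted["log2_effect"].abs() >= 1.5).all()


class TestModuleStructure:
    def test_shared_module_pairs_have_identical_class_and_amplitude(self, small_dataset):
        truth = small_dataset.truth
        cfg = truth.config
        spa, spb = cfg.species_a.name, cfg.species_b.name
        assert truth.shared_module_groups
        for gid in truth.shared_module_groups:
            ga = small_dataset.hog_map.groups[gid][spa][0]
            gb = small_dataset.hog_map.groups[gid][spb][0]
            assert truth.modules[spa][ga] == truth.modules[spb][gb] >= 0
            assert truth.amplitudes[spa][ga] == truth.amplitudes[spb][gb]

    def test_within_module_profiles_more_similar_than_between(self, small_dataset):
        from orthocompare.expression import group_means, zscale

        truth = small_dataset.truth
        sp = truth.config.species_a.name
        fpkm_like = small_dataset.counts[sp].astype(float)
        means = group_means(fpkm_like, small_dataset.meta[sp])
        mods = truth.modules[sp]
        z = zscale(means.loc[mods.index[mods >= 0]])
        mods = mods.reindex(z.index)
        corr = np.corrcoef(z.to_numpy())
        same = (mods.to_numpy()[:, None] == mods.to_numpy()[None, :])
        off_diag = ~np.eye(len(z), dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same & off_diag].mean()
        assert within > between


class TestTruthSets:
    def test_singleton_planted_up_group_is_in_up_set(self, small_dataset):
        truth = small_dataset.truth
        cfg = truth.config
        sets = sd.truth_sets(truth, cfg.species_a.name, cfg.gland_tissue_a)
        assert truth.shared_up_groups <= sets["up"]
        assert truth.shared_down_groups <= sets["down"]

    def test_conflict_groups_in_neither_set(self, small_dataset):
        truth = small_dataset.truth
        cfg = truth.config
        spa = cfg.species_a.name
        sets = sd.truth_sets(truth, spa, cfg.gland_tissue_a)
        for gid in truth.conflict_groups[spa]:
            assert gid not in sets["up"] and gid not in sets["down"]

    def test_unknown_tissue_is_lookup_error(self, small_dataset):
        with pytest.raises(DomainError):
            sd.truth_sets(small_dataset.truth, small_dataset.truth.config.species_a.name, "nope")

    def test_matches_brute_force_enumeration(self, small_dataset):
        truth = small_dataset.truth
        cfg = truth.config
        sp, tissue = cfg.species_b.name, cfg.gland_tissue_b
        sets = sd.truth_sets(truth, sp, tissue)
        planted = truth.planted
        sub = planted.loc[(planted.species == sp) & (planted.tissue == tissue)]
        direction = dict(zip(sub.gene_id, sub.direction))
        for gid, members in truth.hog_map.groups.items():
            genes = members.get(sp, ())
            if not genes:
                continue
            statuses = [direction.get(g, "ns") for g in genes]
            call = majority_oracle(statuses)
            assert (gid in sets["up"]) == (call == "up")
            assert (gid in sets["down"]) == (call == "down")


class TestWriteDataset:
    def test_emits_all_formats(self, small_dataset, tmp_path):
        sd.write_dataset(small_dataset, tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {"N0.tsv", "Orthogroups.tsv", "truth.json"} <= names
        assert any(n.startswith("counts_") for n in names)
        assert any(n.startswith("samples_") for n in names)
        assert any(n.startswith("gene_lengths_") for n in names)
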