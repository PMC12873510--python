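import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthocompare import expression as ex
from orthocompare.types import DimensionError, FormatError, NormFactors, NormalizationError

from _oracles import tmm_factors_oracle, welch_oracle


def _factors(counts, values=None):
    vals = pd.Series(1.0 if values is None else values, index=counts.columns, dtype=float)
    return NormFactors(factors=vals, reference_sample=str(counts.columns[0]))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=list("abc"))
        nf = ex.compute_tmm_factors(counts)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_change_gives_unit_factor(self):
        col = pd.Series([10, 25, 40, 80, 120, 7, 33, 51])
        counts = pd.DataFrame({"s1": col, "s2": col, "s3": col * 2}, index=[f"g{i}" for i in range(8)])
        nf = ex.compute_tmm_factors(counts)
        # doubled depth leaves all M-values at zero: every factor is exactly 1
        np.testing.assert_allclose(nf.factors.to_numpy(), 1.0, atol=1e-12)

    def test_toy_table_matches_independent_formula_oracle(self, toy_counts):
        nf = ex.compute_tmm_factors(toy_counts)
        expected = tmm_factors_oracle(toy_counts.to_numpy().tolist())
        np.testing.assert_allclose(nf.factors.to_numpy(), expected, atol=1e-12)

    def test_all_zero_sample_is_normalization_error(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.raises(NormalizationError):
            ex.compute_tmm_factors(counts)

    def test_geometric_mean_of_factors_is_one(self, toy_counts):
        nf = ex.compute_tmm_factors(toy_counts)
        assert abs(np.log(nf.factors).mean()) < 1e-9

    def test_edger_cross_check(self, toy_counts, tmp_path):
        """The factors agree with Bioconductor edgeR's calcNormFactors."""
        import subprocess

        toy_counts.to_csv(tmp_path / "c.tsv", sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/c.tsv", row.names=1))\n'
            'f <- calcNormFactors(x, method="TMM")\n'
            'cat(sprintf("%.12f", f), sep="\\n")\n'
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        expected = [float(v) for v in proc.stdout.split()]
        nf = ex.compute_tmm_factors(toy_counts)
        np.testing.assert_allclose(nf.factors.to_numpy(), expected, atol=1e-6)


class TestFilterAndFPKM:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 5]}, index=["z", "k"])
        out = ex.filter_low_count(counts, min_total=1)
        assert list(out.index) == ["k"]

    def test_zero_threshold_is_identity(self, toy_counts):
        pd.testing.assert_frame_equal(ex.filter_low_count(toy_counts, 0), toy_counts)

    def test_toy_survivors_match_hand_count(self):
        totals = [0, 1, 4, 5, 6, 2, 9, 3, 10, 7]
        counts = pd.DataFrame({"s1": totals}, index=[f"g{i}" for i in range(10)])
        out = ex.filter_low_count(counts, min_total=5)
        assert set(out.index) == {"g3", "g4", "g6", "g8", "g9"}

    def test_fpkm_unit_definition(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        lengths = pd.Series([1000], index=["g"])
        nf = _factors(counts, 1e6 / counts["s1"].sum())  # effective library 1e6
        fpkm = ex.compute_fpkm(counts, lengths, nf)
        assert fpkm.loc["g", "s1"] == pytest.approx(100.0)

    def test_zero_count_gives_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["g0", "g1"])
        fpkm = ex.compute_fpkm(counts, pd.Series([500, 500], index=["g0", "g1"]), _factors(counts))
        assert fpkm.loc["g0", "s1"] == 0.0

    def test_three_gene_toy_matches_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 20, 70]}, index=["a", "b", "c"])
        lengths = pd.Series([1000, 2000, 500], index=["a", "b", "c"])
        nf = _factors(counts, 0.5)  # effective library = 100 * 0.5 = 50
        fpkm = ex.compute_fpkm(counts, lengths, nf)
        # FPKM = count / (50/1e6) / (len/1e3)
        np.testing.assert_allclose(
            fpkm["s1"].to_numpy(), [10 / 50e-6 / 1, 20 / 50e-6 / 2, 70 / 50e-6 / 0.5]
        )

    def test_missing_length_is_error(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g"])
        with pytest.raises(FormatError):
            ex.compute_fpkm(counts, pd.Series(dtype=int), _factors(counts))

    def test_fpkm_linear_in_counts(self, toy_counts):
        lengths = pd.Series(1000, index=toy_counts.index)
        nf = _factors(toy_counts)
        a = ex.compute_fpkm(toy_counts, lengths, nf)
        scaled = toy_counts * 3
        b = ex.compute_fpkm(scaled, lengths, _factors(scaled, nf.factors * 1.0))
        # library sizes triple too, so FPKM is unchanged; per-count linearity
        # shows at fixed effective library
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestCVSelection:
    def test_constant_gene_never_selected_while_varying_exists(self):
        means = pd.DataFrame({"c1": [5.0, 5.0], "c2": [5.0, 50.0]}, index=["flat", "var"])
        stats = ex.select_high_cv_genes(means, top_frac=0.5)
        assert stats.loc["flat", "cv"] == 0.0
        assert not stats.loc["flat", "selected"]
        assert stats.loc["var", "selected"]

    def test_low_expression_gene_ineligible_regardless_of_cv(self):
        means = pd.DataFrame(
            {"c1": [0.01, 5.0], "c2": [0.9, 6.0]}, index=["low_but_variable", "high"]
        )
        stats = ex.select_high_cv_genes(means, top_frac=1.0, min_fpkm=1.0)
        assert not stats.loc["low_but_variable", "selected"]

    def test_twenty_gene_toy_selects_two_highest_cv(self, rng):
        base = rng.uniform(2, 10, size=(20, 4))
        means = pd.DataFrame(base, index=[f"g{i:02d}" for i in range(20)],
                             columns=["c1", "c2", "c3", "c4"])
        means.iloc[3] = [2, 2, 2, 40]  # very high CV
        means.iloc [7] = [2, 2, 2, 30]
        stats = ex.select_high_cv_genes(means, top_frac=0.10)
        hand_cv = means.std(axis=1, ddof=1) / means.mean(axis=1)
        expected = set(hand_cv.sort_values(ascending=False).index[:2])
        assert set(stats.index[stats["selected"]]) == expected == {"g03", "g07"}

    def test_selection_size_is_ceiling_of_fraction(self):
        means = pd.DataFrame(
            np.abs(np.random.default_rng(0).normal(10, 3, size=(25, 3))),
            index=[f"g{i}" for i in range(25)],
        )
        stats = ex.select_high_cv_genes(means, top_frac=0.10)
        assert int(stats["selected"].sum()) == math.ceil(0.10 * 25)


class TestZScale:
    def test_postconditions(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"])
        z = ex.zscale(m)
        assert abs(z.loc["g"].mean()) < 1e-10
        assert abs(z.loc["g"].std(ddof=1) - 1) < 1e-10

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"g{i}" for i in range(5)])
        once = ex.zscale(m)
        twice = ex.zscale(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_row_dropped(self):
        m = pd.DataFrame({"a": [1.0, 4.0], "b": [1.0, 5.0]}, index=["flat", "ok"])
        z = ex.zscale(m)
        assert list(z.index) == ["ok"]


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 6)))
        res = ex.pca_overview(m)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()

    def test_collinear_data_loads_on_pc1(self):
        t = np.arange(6, dtype=float)
        m = pd.DataFrame([t, 2 * t])  # samples lie on a line in gene space
        res = ex.pca_overview(m)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_spectral_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 4)))  # genes x samples
        res = ex.pca_overview(m)
        X = m.to_numpy().T
        X = X - X.mean(axis=0)
        cov = X.T @ X / (X.shape[0] - 1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        frac = eig[: len(res.variance_fraction)] / eig.sum()
        np.testing.assert_allclose(res.variance_fraction, frac, atol=1e-10)

    def test_single_sample_is_dimension_error(self):
        with pytest.raises(DimensionError):
            ex.pca_overview(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestWelch:
    def test_identical_groups(self):
        res = ex.welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_swap_flips_sign_keeps_p(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0]
        r1 = ex.welch_t(a, b)
        r2 = ex.welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_matches_formula_oracle(self):
        t, p, df = welch_oracle([1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0])
        res = ex.welch_t([1, 2, 3], [2, 3, 4, 5])
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.pvalue == pytest.approx(p, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-9)

    def test_zero_variance_equal_means_defined_limit(self):
        res = ex.welch_t([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.pvalue) == (0.0, 1.0)

    def test_single_value_group_rejected(self):
        with pytest.raises(DimensionError):
            ex.welch_t([1.0], [1.0, 2.0])


def _deg(genes_status):
    return pd.DataFrame(
        {
            "gene_id": list(genes_status),
            "tissue": "t",
            "log2fc": 0.0,
            "pvalue": 0.5,
            "fdr": 0.5,
            "status": list(genes_status.values()),
        }
    )


class TestSetAssociations:
    def test_singleton_association(self):
        tables = {
            "lower pitcher wall": _deg({"g1": "up"}),
            "lid": _deg({"g1": "ns"}),
        }
        tally = ex.deg_set_associations(tables, "up")
        assert tally == {("lower pitcher wall",): 1}

    def test_partition_conserves_total(self, rng):
        tissues = ["t1", "t2", "t3"]
        genes = [f"g{i}" for i in range(30)]
        tables = {
            t: _deg({g: ("up" if rng.random() < 0.4 else "ns") for g in genes})
            for t in tissues
        }
        tally = ex.deg_set_associations(tables, "up")
        up_any = {
            g for t in tissues for g in tables[t].loc[tables[t].status == "up", "gene_id"]
        }
        assert sum(tally.values()) == len(up_any)

    def test_toy_truth_table_matches_enumeration(self):
        patterns = {
            "g1": ("t1",),
            "g2": ("t1",),
            "g3": ("t1", "t2"),
            "g4": ("t2", "t3"),
            "g5": (),
            "g6": ("t1", "t2", "t3"),
        }
        tables = {
            t: _deg({g: ("up" if t in pat else "ns") for g, pat in patterns.items()})
            for t in ["t1", "t2", "t3"]
        }
        tally = ex.deg_set_associations(tables, "up")
        assert tally == {("t1",): 2, ("t1", "t2"): 1, ("t2", "t3"): 1, ("t1", "t2", "t3"): 1}


@pytest.mark.parametrize("which", range(4))
def test_tmm_nearly_invariant_under_sample_rescaling(which):
    """Scaling one sample's counts leaves TMM factors essentially
    unchanged at realistic depths: the per-gene M and A values are
    depth-free, so only the binomial precision weights shift (and only
    when the scaled sample serves as the reference)."""
    rng = np.random.default_rng(123)
    counts = pd.DataFrame(
        rng.poisson(150, size=(60, 4)), columns=["s0", "s1", "s2", "s3"],
        index=[f"g{i:02d}" for i in range(60)],
    )
    scaled = counts.copy()
    scaled[f"s{which}"] = scaled[f"s{which}"] * 7
    f1 = ex.compute_tmm_factors(counts).factors
    f2 = ex.compute_tmm_factors(scaled).factors
    np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=0.01)
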