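"""Normalisation, NB GLM Wald testing, BH adjustment, heatmap matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from hepatox.diffexpr import (
    ConcentrationResponseDE,
    bh_adjust,
    fit_gene_glm,
    log2cpm,
    run_de,
    size_factors,
    top_gene_zscore_matrix,
)
from tests.conftest import make_design


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60],
                               "c": [10, 20, 30]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert sf["a"] == pytest.approx(sf["c"])
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_single_sample_is_one(self):
        assert size_factors(pd.DataFrame({"a": [5, 7]}))["a"] == 1.0

    def test_fallback_without_zero_free_gene(self, caplog):
        counts = pd.DataFrame({"a": [0, 10], "b": [10, 0]})
        with caplog.at_level("WARNING"):
            sf = size_factors(counts)
        assert "total-count" in caplog.text
        assert np.allclose(sf, 1.0)  # equal totals


class TestLog2Cpm:
    def test_pseudocount_closed_form(self):
        # 1023 reads in a 10^6-read library: log2(1024) = 10
        counts = pd.DataFrame({"s": [1023, 10 ** 6 - 1023]})
        assert log2cpm(counts).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"s": [0, 100]})
        assert log2cpm(counts).iloc[0, 0] == 0.0

    def test_depth_invariance(self):
        counts = pd.DataFrame({"s": [5, 10, 85]})
        pd.testing.assert_frame_equal(log2cpm(counts), log2cpm(counts * 2))


class TestBHAdjust:
    def test_worked_example(self):
        got = bh_adjust([0.01, 0.04, 0.03, 0.002])
        assert np.allclose(got, [0.02, 0.04, 0.04, 0.008])

    def test_single_and_tied_pvalues(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bounds_and_dominance(self, pvals):
        adj = bh_adjust(pvals)
        assert ((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1.0)).all()


class TestFitGeneGlm:
    def test_constant_counts_null_slope(self):
        rec = fit_gene_glm([50] * 6, [0, 0, 1, 1, 2, 2])
        assert rec["beta"] == pytest.approx(0.0, abs=1e-8)
        assert rec["p"] == pytest.approx(1.0, abs=1e-6)

    def test_poisson_limit_matches_direct_likelihood_oracle(self):
        """With dispersion pinned to 0 the GLM must agree with direct
        Poisson log-likelihood maximisation by a generic optimizer."""
        y = np.array([12.0, 18, 25, 30, 52, 65])
        conc = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])

        def negll(params):
            mu = np.exp(params[0] + params[1] * conc)
            return float(np.sum(mu - y * np.log(mu)))

        opt = optimize.minimize(negll, [np.log(y.mean()), 0.0],
                                method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14})
        rec = fit_gene_glm(y, conc, dispersion=0.0)
        assert rec["beta"] == pytest.approx(opt.x[1] / np.log(2), abs=1e-6)
        # Wald SE against the analytic Fisher information X' diag(mu) X
        mu = np.exp(opt.x[0] + opt.x[1] * conc)
        X = np.column_stack([np.ones_like(conc), conc])
        se_nat = np.sqrt(np.linalg.inv(X.T @ (mu[:, None] * X))[1, 1])
        assert rec["se"] == pytest.approx(se_nat / np.log(2), abs=1e-6)

    def test_all_zero_gene_untestable(self):
        rec = fit_gene_glm([0, 0, 0, 0, 0, 0], [0, 0, 1, 1, 2, 2])
        assert rec["status"] == "untestable" and rec["p"] == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_gene_glm([1, 2], [0, 1])
        with pytest.raises(ValueError):
            fit_gene_glm([1, 2, 3], [1, 1, 1])


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(4)
    design = make_design(["d"], [0.0, 1.0, 2.0], replicates=3)
    genes = [f"G{i}" for i in range(30)]
    counts = pd.DataFrame(
        rng.poisson(200.0, size=(30, len(design))),
        index=genes, columns=design["sample_id"],
    )
    # two genes with identical counts must tie exactly
    counts.iloc[1] = counts.iloc[0]
    return counts, design


class TestRunDe:
    def test_identical_genes_get_identical_pvalues(self, toy):
        counts, design = toy
        table = run_de(counts, design, "d").set_index("gene")
        assert table.loc["G0", "p"] == table.loc["G1", "p"]

    def test_column_order_invariance(self, toy):
        counts, design = toy
        shuffled = counts[list(counts.columns[::-1])]
        a = run_de(counts, design, "d").set_index("gene")
        b = run_de(shuffled, design, "d").set_index("gene")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_chemical_rejected(self, toy):
        counts, design = toy
        with pytest.raises(KeyError):
            run_de(counts, design, "nothere")

    def test_null_dataset_de_rate_bounded(self, toy):
        counts, design = toy
        table = run_de(counts, design, "d")
        # null data: the BH-controlled DE set should be essentially empty
        assert (table.p_adj < 0.05).sum() <= 2


@pytest.fixture(scope="module")
def planted_de(planted_dataset):
    counts = planted_dataset["counts"]
    design = planted_dataset["design"]
    table = run_de(counts, design, "drugX")
    expr = log2cpm(counts)
    return table, expr, design


class TestTopGeneZscoreMatrix:
    def test_rows_standardised(self, planted_de):
        table, expr, design = planted_de
        z = top_gene_zscore_matrix(table, expr, design, k=20)
        assert z.shape == (20, 3)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_monotone_expression_gives_monotone_row(self, planted_de):
        table, expr, design = planted_de
        z = top_gene_zscore_matrix(table, expr, design, k=20)
        # planted effects increase with concentration; induced genes keep
        # their ordering after standardisation
        top_gene = table.iloc[0]["gene"]
        if table.iloc[0]["beta"] > 0:
            assert z.loc[top_gene].is_monotonic_increasing

    def test_k1_selects_smallest_adjusted_p(self, planted_de):
        table, expr, design = planted_de
        z = top_gene_zscore_matrix(table, expr, design, k=1)
        assert list(z.index) == [table.iloc[0]["gene"]]


def test_glm_invariant_to_size_factor_rescaling():
    """A common positive rescaling of all size factors is absorbed by the
    intercept through the offset: slope, SE and p are unchanged."""
    y = np.array([30.0, 45, 50, 80, 120, 160])
    conc = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
    sf = np.array([0.8, 1.2, 0.9, 1.1, 1.0, 1.0])
    a = fit_gene_glm(y, conc, sf)
    b = fit_gene_glm(y, conc, 7.3 * sf)
    assert a["beta"] == pytest.approx(b["beta"], abs=1e-8)
    assert a["se"] == pytest.approx(b["se"], abs=1e-8)
    assert a["p"] == pytest.approx(b["p"], abs=1e-8)
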