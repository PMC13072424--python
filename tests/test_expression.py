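"""Expression quantification and testing: closed-form checks, invariances,
simulation calibration and agreement with an independent NB likelihood-ratio
oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovisepi import expression as ex
from ovisepi.genomic_io import InvalidParameterError
from ovisepi.synthetic_epigenome import simulate_counts

SAMPLES = ["HU_1", "HU_2", "HU_3", "SH_1", "SH_2", "SH_3"]
BREEDS = pd.Series(["HU"] * 3 + ["SH"] * 3, index=SAMPLES)


def nb_counts(n_genes, log2fc, seed, dispersion=0.1, depth=500.0,
              lognormal_sigma=0.8):
    rng = np.random.default_rng(seed)
    means = depth * rng.lognormal(-lognormal_sigma ** 2 / 2,
                                  lognormal_sigma, n_genes)
    fc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_genes,))
    return simulate_counts(means, fc, SAMPLES, list(BREEDS), dispersion, rng)


class TestTPM:
    def test_two_gene_closed_form(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 2000})
        out = ex.tpm(counts, lengths)
        np.testing.assert_allclose(out["s1"], [2e6 / 3, 1e6 / 3])

    def test_single_gene_is_one_million(self):
        out = ex.tpm(pd.DataFrame({"s": [7]}, index=["a"]),
                     pd.Series({"a": 500}))
        assert out.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 4)),
                              index=[f"g{i}" for i in range(50)])
        lengths = pd.Series(rng.integers(200, 5000, 50).astype(float),
                            index=counts.index)
        out = ex.tpm(counts, lengths)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.raises(InvalidParameterError):
            ex.tpm(counts, pd.Series({"a": 100, "b": 100}))


class TestSizeFactors:
    def test_factor_ratios_track_depth_scaling(self, rng):
        # factors are defined up to the geometric-mean reference, so only
        # their ratios are equivariant under per-sample depth changes
        counts = pd.DataFrame(rng.integers(10, 500, (100, 4)),
                              columns=list("abcd"))
        sf = ex.size_factors(counts)
        scaled = counts.copy()
        scaled["a"] = scaled["a"] * 3
        sf2 = ex.size_factors(scaled)
        ratio = (sf2["a"] / sf2["b"]) / (sf["a"] / sf["b"])
        assert ratio == pytest.approx(3, rel=1e-9)

    def test_invariant_to_global_scaling(self, rng):
        # a common factor moves the geometric-mean reference identically,
        # so relative size factors are unchanged
        counts = pd.DataFrame(rng.integers(10, 500, (100, 4)),
                              columns=list("abcd"))
        sf = ex.size_factors(counts)
        sf2 = ex.size_factors(counts * 5)
        np.testing.assert_allclose(sf2, sf, rtol=1e-9)


class TestDifferentialExpression:
    def test_identical_groups_give_zero_log2fc(self):
        rng = np.random.default_rng(0)
        block = rng.integers(10, 500, (100, 3))
        counts = pd.DataFrame(np.hstack([block, block]), columns=SAMPLES,
                              index=[f"g{i}" for i in range(100)])
        lengths = pd.Series(1000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        np.testing.assert_allclose(de.table["log2fc"], 0.0, atol=1e-12)
        assert (de.table["status"] == "not_DE").all()

    def test_breed_label_swap_negates_log2fc_and_swaps_calls(self):
        counts = nb_counts(300, np.where(np.arange(300) < 40, 2.5, 0.0),
                           seed=5)
        lengths = pd.Series(1000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        swapped = BREEDS.map({"HU": "SH", "SH": "HU"})
        de2 = ex.differential_expression(counts, swapped, lengths=lengths)
        np.testing.assert_allclose(de2.table["log2fc"],
                                   -de.table["log2fc"], atol=1e-9)
        remap = {"SH_up": "HU_up", "HU_up": "SH_up"}
        assert list(de2.table["status"]) == [
            remap.get(s, s) for s in de.table["status"]]

    def test_calls_invariant_to_depth_scaling(self):
        counts = nb_counts(200, np.where(np.arange(200) < 30, 2.5, 0.0),
                           seed=9)
        lengths = pd.Series(1000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        scaled = (counts * pd.Series([2, 1, 3, 1, 2, 1],
                                     index=SAMPLES)).astype(int)
        de2 = ex.differential_expression(scaled, BREEDS, lengths=lengths)
        agree = (de.table["status"] == de2.table["status"]).mean()
        assert agree > 0.97  # integer truncation may flip borderline genes

    def test_zero_count_gene_not_tested(self):
        counts = nb_counts(20, 0.0, seed=2)
        counts.iloc[0] = 0
        lengths = pd.Series(1000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        assert de.table.iloc[0]["status"] == "not_expressed"
        assert np.isnan(de.table.iloc[0]["p_value"])

    def test_null_type_one_error_calibrated(self):
        """Empirical type-I error at alpha=0.05 within 0.05 +/- 0.015 on a
        2,000-gene null NB simulation with 3 replicates per group."""
        counts = nb_counts(2000, 0.0, seed=7)
        lengths = pd.Series(2000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        p = de.table["p_value"].dropna()
        assert 0.035 <= (p < 0.05).mean() <= 0.065

    def test_planted_effect_sensitivity(self):
        counts = nb_counts(2000, np.where(np.arange(2000) < 200, 2.5, 0.0),
                           seed=8)
        lengths = pd.Series(2000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        sens = (de.table.iloc[:200]["status"] == "SH_up").mean()
        assert sens >= 0.9

    def test_agrees_with_nb_likelihood_ratio_oracle(self):
        """Call-level agreement >= 95% with per-gene NB GLM likelihood-ratio
        tests (statsmodels), an independent estimation route."""
        sm = pytest.importorskip("statsmodels.api")
        counts = nb_counts(200, np.where(np.arange(200) < 30, 2.5, 0.0),
                           seed=3)
        lengths = pd.Series(1000.0, index=counts.index)
        de = ex.differential_expression(counts, BREEDS, lengths=lengths)
        sf = ex.size_factors(counts)
        offset = np.log(sf.to_numpy())
        design = np.column_stack([np.ones(6), (BREEDS == "SH").astype(float)])
        oracle_calls = []
        for gi in range(len(counts)):
            y = counts.iloc[gi].to_numpy(dtype=float)
            if y.sum() == 0:
                oracle_calls.append("not_tested")
                continue
            alpha = max(de.table.iloc[gi]["dispersion"], 1e-6)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            try:
                full = sm.GLM(y, design, family=fam, offset=offset).fit()
                null = sm.GLM(y, design[:, :1], family=fam,
                              offset=offset).fit()
                lr = 2 * (full.llf - null.llf)
                p = stats.chi2.sf(max(lr, 0), df=1)
                lfc = full.params[1] / np.log(2)
            except Exception:
                oracle_calls.append("failed")
                continue
            if p < 0.05 and abs(lfc) > 1:
                oracle_calls.append("SH_up" if lfc > 0 else "HU_up")
            else:
                oracle_calls.append("not_DE")
        ours = list(de.table["status"])
        usable = [i for i, c in enumerate(oracle_calls)
                  if c not in ("failed", "not_tested")]
        agree = np.mean([ours[i] == oracle_calls[i] for i in usable])
        assert len(usable) > 150
        assert agree >= 0.95


class TestDeltaDeltaCt:
    @pytest.mark.parametrize("args,expected", [
        ((20, 15, 20, 15), 1.0),
        ((20, 15, 22, 15), 4.0),
        ((21, 15, 20, 15), 0.5),
    ])
    def test_worked_cases(self, args, expected):
        assert ex.delta_delta_ct(*args) == pytest.approx(expected)


class TestPhenotypeTest:
    def test_extreme_separation_exact_p(self):
        _, p = ex.phenotype_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = ex.phenotype_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            _, p = ex.phenotype_test(x, y)
            assert p == pytest.approx(ex.exact_ranksum_p(x, y), abs=1e-9)

    def test_ties_handled(self):
        _, p = ex.phenotype_test([1, 1, 2, 3], [2, 2, 3, 4])
        assert 0 < p <= 1

    def test_too_small_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            ex.phenotype_test([1], [2, 3])


class TestSpearman:
    def test_monotone_extremes(self):
        tpm_rows = pd.DataFrame(
            {"s1": [1, 8], "s2": [2, 4], "s3": [3, 2], "s4": [4, 1]},
            index=["up", "down"])
        pheno = pd.DataFrame({"trait": [10, 20, 30, 40]},
                             index=["s1", "s2", "s3", "s4"])
        out = ex.gene_phenotype_correlation(tpm_rows, pheno)
        assert out.loc[out.gene_id == "up", "rho"].iloc[0] == pytest.approx(1)
        assert out.loc[out.gene_id == "down", "rho"].iloc[0] == pytest.approx(-1)

    def test_matches_rank_then_pearson_oracle(self, rng):
        g = rng.normal(size=8)
        t = rng.normal(size=8)
        tpm_rows = pd.DataFrame([g], index=["g"],
                                columns=[f"s{i}" for i in range(8)])
        pheno = pd.DataFrame({"trait": t},
                             index=[f"s{i}" for i in range(8)])
        out = ex.gene_phenotype_correlation(tpm_rows, pheno)
        oracle = np.corrcoef(stats.rankdata(g), stats.rankdata(t))[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_is_missing(self):
        tpm_rows = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g"],
                                columns=[f"s{i}" for i in range(4)])
        pheno = pd.DataFrame({"trait": [1, 2, 3, 4.0]},
                             index=[f"s{i}" for i in range(4)])
        out = ex.gene_phenotype_correlation(tpm_rows, pheno)
        assert np.isnan(out["rho"].iloc[0])
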