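"""DE engine: size factors, normalization, dispersions, Wald test, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txcompare.data_model import GeneCountMatrix
from txcompare.de import (
    adjust_bh,
    estimate_dispersions,
    estimate_size_factors,
    normalize_counts,
    run_de,
    wald_test,
)
from conftest import make_sample_table


def brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Literal median-of-ratios: per sample, the median over positive-geomean
    genes of count / geometric mean; rescaled to unit geometric mean."""
    values = counts.to_numpy(float)
    geomeans = np.array([np.prod(row) ** (1.0 / len(row)) for row in values])
    keep = geomeans > 0
    out = []
    for j in range(values.shape[1]):
        out.append(np.median(values[keep, j] / geomeans[keep]))
    out = np.array(out)
    return out / np.prod(out) ** (1.0 / len(out))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5.0, 10.0, 3.0], "b": [5.0, 10.0, 3.0]})
        assert np.allclose(estimate_size_factors(counts).to_numpy(), 1.0)

    def test_doubled_sample_splits_geometrically(self):
        counts = pd.DataFrame({"a": [5.0, 10.0, 3.0], "b": [10.0, 20.0, 6.0]})
        sf = estimate_size_factors(counts).to_numpy()
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            counts = pd.DataFrame(
                rng.uniform(0.5, 500, (50, 6)),
                columns=[f"s{j}" for j in range(6)],
            )
            mine = estimate_size_factors(counts).to_numpy()
            assert np.allclose(mine, brute_force_size_factors(counts), atol=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.uniform(1, 100, (40, 4)), columns=list("abcd"))
        sf1 = estimate_size_factors(counts)
        sf2 = estimate_size_factors(counts.sample(frac=1.0, random_state=0))
        assert np.allclose(sf1.to_numpy(), sf2.to_numpy(), atol=1e-12)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [0.0, 5.0], "b": [5.0, 0.0]})
        with pytest.raises(ValueError, match="fallback"):
            estimate_size_factors(counts)


class TestNormalize:
    def test_unit_factors_identity_and_halving(self):
        m = GeneCountMatrix(pd.DataFrame({"a": [10.0, 4.0], "b": [6.0, 8.0]}))
        same = normalize_counts(m, pd.Series({"a": 1.0, "b": 1.0}))
        assert same.counts.equals(m.counts)
        halved = normalize_counts(m, pd.Series({"a": 1.0, "b": 2.0}))
        assert np.allclose(halved.counts["b"], [3.0, 4.0])

    def test_normalization_fixed_point(self):
        rng = np.random.default_rng(5)
        m = GeneCountMatrix(
            pd.DataFrame(rng.uniform(1, 1000, (200, 5)), columns=list("abcde"))
        )
        sf = estimate_size_factors(m.counts)
        renorm = estimate_size_factors(normalize_counts(m, sf).counts)
        assert np.allclose(renorm.to_numpy(), 1.0, atol=1e-9)


class TestDispersions:
    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(10)
        samples = make_sample_table(24, 24)
        mu = rng.uniform(20, 500, 1000)
        counts = pd.DataFrame(
            rng.poisson(mu[:, None], (1000, 48)).astype(float), columns=samples.sample_ids
        )
        m = GeneCountMatrix(counts)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(m, sf, samples)
        assert np.nanmedian(disp.to_numpy()) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(11)
        samples = make_sample_table(24, 24)
        alpha = 0.2
        mu = rng.uniform(50, 500, 2000)
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], (2000, 48))
        counts = pd.DataFrame(rng.poisson(lam).astype(float), columns=samples.sample_ids)
        disp = estimate_dispersions(GeneCountMatrix(counts), pd.Series(1.0, index=counts.columns), samples)
        assert 0.1 <= np.nanmedian(disp.to_numpy()) <= 0.4

    def test_all_zero_gene_excluded(self, small_sim):
        counts = small_sim.genes.counts.copy()
        counts.iloc[0] = 0.0
        m = GeneCountMatrix(counts)
        sf = estimate_size_factors(counts)
        disp = estimate_dispersions(m, sf, small_sim.samples)
        assert np.isnan(disp.iloc[0])
        res = wald_test(m, sf, small_sim.samples, disp)
        assert np.isnan(res.frame["padj"].iloc[0])


class TestWald:
    def test_lfc_recovery_within_half_unit(self):
        # 200 genes with true log2FC = 2 against a null background (the
        # background anchors the median-of-ratios normalization)
        rng = np.random.default_rng(12)
        samples = make_sample_table(24, 3)
        n_signal, n_null = 200, 800
        mu = rng.uniform(100, 1000, n_signal + n_null)
        fold = np.ones(n_signal + n_null)
        fold[:n_signal] = 4.0
        alpha = 0.05
        lam_c = rng.gamma(1 / alpha, alpha * mu[:, None], (len(mu), 24))
        lam_t = rng.gamma(1 / alpha, alpha * (fold * mu)[:, None], (len(mu), 3))
        counts = np.hstack([rng.poisson(lam_c), rng.poisson(lam_t)]).astype(float)
        m = GeneCountMatrix(pd.DataFrame(counts, columns=samples.sample_ids))
        res = run_de(m, samples)
        hits = (res.frame["log2FoldChange"].iloc[:n_signal].sub(2.0).abs() <= 0.5).mean()
        assert hits >= 0.9

    def test_zero_control_group_is_finite_and_significant(self):
        samples = make_sample_table(4, 4)
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.uniform(50, 200, (50, 8)), columns=samples.sample_ids
        )
        counts.iloc[0, :4] = 0.0
        counts.iloc[0, 4:] = [500.0, 520.0, 480.0, 510.0]
        m = GeneCountMatrix(counts)
        res = run_de(m, samples)
        row = res.frame.iloc[0]
        assert np.isfinite(row["log2FoldChange"]) and row["log2FoldChange"] > 0
        assert row["pvalue"] < 1e-4

    def test_determinism_bitwise(self, small_sim):
        a = run_de(small_sim.genes, small_sim.samples).frame
        b = run_de(small_sim.genes, small_sim.samples).frame
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_padj_at_least_pvalue_and_monotone(self, small_sim):
        frame = run_de(small_sim.genes, small_sim.samples).frame.dropna()
        assert (frame["padj"] >= frame["pvalue"] - 1e-15).all()
        ordered = frame.sort_values("pvalue")
        assert ordered["padj"].is_monotonic_increasing


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_caps_and_identity(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert adjust_bh([0.04]) == pytest.approx(0.04)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(14)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(adjust_bh(p), expected, atol=1e-12)


class TestCrossValidationAgainstReferenceImplementation:
    def test_pvalues_and_lfc_concordant_with_pydeseq2(self, small_sim):
        """Independent route: a full DESeq2 reimplementation (pydeseq2) should
        rank genes the same way on identical input, despite differing
        dispersion machinery."""
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        from pydeseq2.ds import DeseqStats

        sim = small_sim
        mine = run_de(sim.genes, sim.samples).frame
        counts = sim.genes.counts.T.round().astype(int)
        meta = pd.DataFrame(
            {"condition": ["control"] * 8 + ["test"] * 4}, index=counts.index
        )
        dds = pydeseq2_dds.DeseqDataSet(
            counts=counts, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "test", "control"], quiet=True)
        st.summary()
        ref = st.results_df
        both = mine.join(ref, rsuffix="_ref").dropna(subset=["pvalue", "pvalue_ref"])
        rho = stats.spearmanr(both["pvalue"], both["pvalue_ref"]).statistic
        r_lfc = np.corrcoef(both["log2FoldChange"], both["log2FoldChange_ref"])[0, 1]
        assert rho > 0.95
        assert r_lfc > 0.98
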