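import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polreloc import differential as dm


def _nb_counts(rng, mu, disp, size):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _design(samples, conditions):
    return pd.DataFrame({"sample": samples, "condition": conditions})


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = dm.size_factors(counts)
        assert sf.tolist() == [1.0, 1.0]

    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = dm.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame({"a": [10, 0, 30], "b": [10, 0, 30]})
        assert dm.size_factors(counts).tolist() == [1.0, 1.0]

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 30]})
        with pytest.raises(ValueError, match="all-positive"):
            dm.size_factors(counts)


class TestNbWaldTest:
    samples = ["a1", "a2", "b1", "b2"]
    design = _design(samples, ["x", "x", "y", "y"])

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            {s: _nb_counts(rng, 100, 0.05, 2000) for s in self.samples},
            index=[f"g{i}" for i in range(2000)],
        )
        res = dm.nb_wald_test(counts, self.design, dm.size_factors(counts))
        ks = stats.kstest(res["pvalue"].dropna(), "uniform").statistic
        assert ks < 0.08

    def test_planted_fourfold_change_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        counts = pd.DataFrame(
            {
                "a1": _nb_counts(rng, 200, 0.05, n),
                "a2": _nb_counts(rng, 200, 0.05, n),
                "b1": _nb_counts(rng, 800, 0.05, n),
                "b2": _nb_counts(rng, 800, 0.05, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        # equal-depth samples: unit size factors isolate the estimator
        sf = pd.Series(1.0, index=self.samples)
        res = dm.nb_wald_test(counts, self.design, sf)
        assert abs(res["log2fc"].median() - 2.0) < 0.15

    def test_all_zero_gene_is_na_and_excluded_from_fdr(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {s: _nb_counts(rng, 50, 0.05, 20) for s in self.samples}
        )
        counts.iloc[0] = 0
        res = dm.classify_genes(
            dm.nb_wald_test(counts, self.design, pd.Series(1.0, index=self.samples))
        )
        assert np.isnan(res["pvalue"].iloc[0])
        assert res["klass"].iloc[0] == "NA"
        assert res["fdr"].iloc[1:].notna().all()

    def test_fdr_control_under_null(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            counts = pd.DataFrame(
                {s: _nb_counts(rng, 100, 0.05, 400) for s in self.samples}
            )
            res = dm.classify_genes(
                dm.nb_wald_test(counts, self.design, dm.size_factors(counts))
            )
            hits.append((res["fdr"] < 0.01).mean())
        assert np.mean(hits) <= 0.015


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "log2fc,fdr,expected",
        [
            (-1.5, 0.001, "repressed"),
            (0.5, 0.0001, "unchanged"),
            (-2.0, 0.02, "unchanged"),
            (1.0, 0.005, "induced"),
        ],
    )
    def test_threshold_rules(self, log2fc, fdr, expected):
        # craft p-values so that BH-adjusted fdr equals the raw p (m=1)
        res = pd.DataFrame(
            {"baseMean": [10.0], "log2fc": [log2fc], "pvalue": [fdr],
             "dispersion": [0.05]},
            index=["g"],
        )
        out = dm.classify_genes(res)
        assert out["klass"].iloc[0] == expected

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(5)
        res = pd.DataFrame(
            {
                "baseMean": rng.uniform(10, 100, 200),
                "log2fc": rng.normal(0, 2, 200),
                "pvalue": rng.uniform(0, 1, 200) ** 3,
                "dispersion": 0.05,
            },
            index=[f"g{i}" for i in range(200)],
        )
        loose = dm.classify_genes(res, fdr_threshold=0.05)
        tight = dm.classify_genes(res, fdr_threshold=0.005)
        assert set(loose["klass"]) <= {"repressed", "induced", "unchanged"}
        assert loose["klass"].notna().all()
        for k in ("repressed", "induced"):
            assert set(tight.index[tight["klass"] == k]) <= set(
                loose.index[loose["klass"] == k]
            )


class TestOccupancyChangeCorrelation:
    def test_perfect_linear(self):
        x = pd.Series([1.0, 2, 3, 4])
        r, n = dm.occupancy_change_correlation(2 * x + 1, x)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_anticorrelation(self):
        x = pd.Series([1.0, 2, 3, 4])
        r, _ = dm.occupancy_change_correlation(-x, x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        a = pd.Series([1.0, 2, 3, 4])
        b = pd.Series([2.0, 1, 4, 3])
        r, _ = dm.occupancy_change_correlation(a, b)
        assert r == pytest.approx(0.6)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">=3"):
            dm.occupancy_change_correlation(
                pd.Series([1.0, 2]), pd.Series([2.0, 1])
            )

    def test_na_pairs_dropped(self):
        a = pd.Series([1.0, 2, np.nan, 4, 5])
        b = pd.Series([1.0, 2, 3, 4, np.nan])
        _, n = dm.occupancy_change_correlation(a, b)
        assert n == 3


def test_spike_size_factors_normalized():
    class SC:
        def __init__(self, s):
            self.spike_reads = s

    sf = dm.spike_size_factors({"a": SC(100), "b": SC(400)}, ["a", "b"])
    assert sf["b"] / sf["a"] == pytest.approx(4.0)
    assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)
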