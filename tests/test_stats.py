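import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from straindiff import stats
from straindiff.config import AnalysisConfig
from straindiff.io import GeneLocus, ValidationError


def comb_tail_p(k, K, n, N):
    """Exact one-sided hypergeometric tail from binomial coefficients."""
    denom = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / denom


def comb_two_sided_p(table):
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    lo, hi = max(0, n - (N - K)), min(n, K)
    pmf = {x: math.comb(K, x) * math.comb(N - K, n - x) / denom
           for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisher:
    def test_hand_value_one_sided(self):
        """[[2,0],[0,2]]: one-sided p = C(2,2)C(2,0)/C(4,2) = 1/6."""
        assert stats.hypergeom_tail_p(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_hand_value_two_sided(self):
        assert stats.fisher_two_sided_p([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, 4)
            table = [[int(a), int(b)], [int(c), int(d)]]
            ours = stats.fisher_two_sided_p(table)
            ref = sps.fisher_exact(table)[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_oracle_equivalence_small_tables(self):
        for N in range(1, 26):
            for n in range(N + 1):
                for K in range(N + 1):
                    lo = max(0, n - (N - K))
                    hi = min(n, K)
                    for k in range(lo, hi + 1):
                        assert stats.hypergeom_tail_p(k, K, n, N) == \
                            pytest.approx(comb_tail_p(k, K, n, N), abs=1e-10)


class TestEnrichment:
    def _setup(self):
        background = {f"g{i}" for i in range(40)}
        ann = {f"g{i}": {"T_big"} for i in range(10)}
        for i in range(5):
            ann.setdefault(f"g{i}", set()).add("T_small")
        flagged = {f"g{i}" for i in range(8)}
        return flagged, background, ann

    def test_small_terms_excluded(self, config):
        flagged, background, ann = self._setup()
        results = stats.fisher_enrichment(flagged, background, ann, config)
        terms = {r.term for r in results}
        assert "T_small" not in terms  # 5 background genes is not > 5
        assert "T_big" in terms

    def test_flagged_equals_background_p_one(self, config):
        background = {f"g{i}" for i in range(20)}
        ann = {f"g{i}": {"T"} for i in range(10)}
        results = stats.fisher_enrichment(background, background, ann, config)
        assert results[0].p == pytest.approx(1.0)

    def test_flag_subset_enforced(self, config):
        with pytest.raises(ValidationError):
            stats.fisher_enrichment({"x"}, {"y"}, {}, config)

    def test_empty_background_rejected(self, config):
        with pytest.raises(ValidationError):
            stats.fisher_enrichment(set(), set(), {}, config)

    def test_planted_term_significant(self, config):
        background = {f"g{i}" for i in range(200)}
        ann = {f"g{i}": {"T"} for i in range(30)}
        flagged = {f"g{i}" for i in range(20)}  # all flagged carry T
        results = {r.term: r for r in
                   stats.fisher_enrichment(flagged, background, ann, config)}
        assert results["T"].enriched
        assert results["T"].p == pytest.approx(
            comb_tail_p(20, 30, 20, 200), rel=1e-9)


class TestThreeStrain:
    @pytest.mark.parametrize("nm,nz,mz,expected", [
        (1, 1, 1, "three_way"),
        (1, 1, 0, "common_ji"),
        (0, 1, 1, "indica_indica"),
        (1, 0, 1, "indica_indica"),
        (1, 0, 0, "inconsistent"),
        (0, 1, 0, "inconsistent"),
        (0, 0, 1, "inconsistent"),
        (0, 0, 0, "similar"),
    ])
    def test_pattern_truth_table(self, nm, nz, mz, expected):
        assert stats._pattern(bool(nm), bool(nz), bool(mz)) == expected

    def test_patterns_partition(self):
        """Every boolean combination maps to exactly one pattern."""
        seen = [stats._pattern(a, b, c)
                for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        assert all(p in stats.THREE_STRAIN_PATTERNS for p in seen)

    def _de(self, genes, flags, expr=9.0):
        return pd.DataFrame({
            "gene_id": genes, "tissue": "t1",
            "is_de": flags, "measurable": True,
            "expr_a": expr, "expr_b": expr})

    def test_classify_three_strain_table(self, config):
        genes = ["g1", "g2", "g3"]
        out = stats.classify_three_strain(
            self._de(genes, [True, True, False]),
            self._de(genes, [True, True, False]),
            self._de(genes, [True, False, False]),
            "t1", config)
        assert dict(zip(out["gene_id"], out["pattern"])) == {
            "g1": "three_way", "g2": "common_ji", "g3": "similar"}

    def test_low_expression_dropped(self, config):
        genes = ["g1", "g2"]
        out = stats.classify_three_strain(
            self._de(genes, [True, False], expr=5.0),
            self._de(genes, [True, False], expr=5.0),
            self._de(genes, [False, False], expr=5.0),
            "t1", config)
        assert len(out) == 0


class TestExpectedThreeway:
    def test_printed_inputs(self):
        assert round(stats.expected_threeway(446, 109, 13533), 1) == 3.6
        assert round(stats.expected_threeway(670, 464, 13993), 1) == 22.2

    def test_zero_mzde(self):
        assert stats.expected_threeway(100, 0, 5000) == 0.0

    def test_homogeneous_scaling(self):
        base = stats.expected_threeway(50, 20, 1000)
        assert stats.expected_threeway(150, 60, 3000) == pytest.approx(3 * base)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            stats.expected_threeway(10, 5, 0)
        with pytest.raises(ValidationError):
            stats.expected_threeway(10, 50, 40)


class TestThreewayTest:
    def test_two_sided_hand_value(self):
        assert stats.threeway_test(2, 2, 0, 2) == pytest.approx(1 / 3)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            common = int(rng.integers(2, 40))
            he = int(rng.integers(50, 400))
            mz = int(rng.integers(0, he // 2))
            obs = int(rng.integers(0, common))
            ours = stats.threeway_test(obs, common, mz, he)
            ref = sps.fisher_exact([[obs, common - obs],
                                    [mz, he - mz]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_null_pvalues_uniform(self, rng):
        """Observed drawn from the null hypergeometric: p ~ U(0,1)."""
        common, mz, he = 30, 50, 500
        draws = rng.hypergeometric(mz, he - mz, common, size=1000)
        ps = [stats.threeway_test(int(x), common, mz, he) for x in draws]
        rejections = np.mean(np.array(ps) < 0.05)
        assert rejections <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_observed_bounded(self):
        with pytest.raises(ValidationError):
            stats.threeway_test(10, 5, 1, 100)


class TestEqtlSummary:
    def _loci(self):
        return {"g1": GeneLocus("g1", "chr1", 1_000_000, 1_003_000),
                "g2": GeneLocus("g2", "chr1", 9_000_000, 9_003_000)}

    def test_sum_boundary_is_strict(self, config):
        records = pd.DataFrame({
            "gene_id": ["g1", "g1"], "chrom": ["chr1", "chr2"],
            "start": [900_000, 0], "end": [1_100_000, 100],
            "var_explained": [50.0, 30.0]})
        summary, _ = stats.summarize_eqtl(records, self._loci(), None, config)
        row = summary.set_index("gene_id").loc["g1"]
        assert row["sum_explained"] == pytest.approx(80.0)
        assert row["group"] == "intermediate"  # > 80 required, strictly

    def test_no_records_unexplained(self, config):
        records = pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                        "var_explained"])
        summary, _ = stats.summarize_eqtl(records, self._loci(), None, config)
        assert (summary["group"] == "unexplained").all()
        assert (summary["sum_explained"] == 0).all()

    def test_cis_margin(self, config):
        records = pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "start": [1_500_000, 1_500_000], "end": [1_600_000, 1_600_000],
            "var_explained": [90.0, 90.0]})
        summary, _ = stats.summarize_eqtl(records, self._loci(), None, config)
        s = summary.set_index("gene_id")
        assert bool(s.loc["g1", "has_cis"])      # within 1 Mb margin
        assert not bool(s.loc["g2", "has_cis"])  # 7.4 Mb away

    def test_cohort_stats_by_class(self, config):
        records = pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "start": [900_000, 8_900_000], "end": [1_100_000, 9_100_000],
            "var_explained": [90.0, 30.0]})
        _, cohort = stats.summarize_eqtl(
            records, self._loci(), None, config,
            gene_class={"g1": "global", "g2": "changed"})
        assert cohort["global"]["mean_explained"] == pytest.approx(90.0)
        assert cohort["changed"]["mean_explained"] == pytest.approx(30.0)
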