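import numpy as np
import pytest
from scipy import stats as sps

from hetrad.features.names import FEATURE_NAMES
from hetrad.stats import (
    HabitatComparison,
    bonferroni_threshold,
    correlation_matrix,
    paired_differences,
    pca_regions,
    run_statistics,
    wilcoxon_signed_rank_p,
)
from hetrad.stats import test_feature as feature_test

from conftest import make_feature_vector
from oracles import wilcoxon_two_sided_exact


class TestBonferroni:
    def test_forty_seven_tests_displays_as_point_001(self):
        t = bonferroni_threshold(0.05, 47)
        assert t == pytest.approx(0.0010638297872, rel=1e-9)
        assert round(t, 3) == 0.001

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 50, 0.001)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestPairedDifferences:
    def test_identical_pairs_zero(self):
        rec = [make_feature_vector(subject_id=f"S{i}") for i in range(4)]
        non = [make_feature_vector(subject_id=f"S{i}", roi_role="GTVnr") for i in range(4)]
        t = paired_differences(rec, non)
        assert (t.differences.to_numpy() == 0).all()
        assert t.n == 4

    def test_constant_offset_column(self, rng):
        base = {f: float(v) for f, v in zip(FEATURE_NAMES, rng.normal(size=47))}
        rec = [make_feature_vector({f: v + 2.5 for f, v in base.items()}, subject_id=f"S{i}")
               for i in range(3)]
        non = [make_feature_vector(base, subject_id=f"S{i}", roi_role="GTVnr") for i in range(3)]
        t = paired_differences(rec, non)
        np.testing.assert_allclose(t.differences.to_numpy(), 2.5, atol=1e-12)

    def test_column_means_match_bruteforce(self, rng):
        rec_vals = [dict(zip(FEATURE_NAMES, rng.normal(size=47))) for _ in range(6)]
        non_vals = [dict(zip(FEATURE_NAMES, rng.normal(size=47))) for _ in range(6)]
        rec = [make_feature_vector(v, subject_id=f"S{i}") for i, v in enumerate(rec_vals)]
        non = [make_feature_vector(v, subject_id=f"S{i}", roi_role="GTVnr")
               for i, v in enumerate(non_vals)]
        t = paired_differences(rec, non)
        for f in FEATURE_NAMES[:5]:
            expect = np.mean([rv[f] - nv[f] for rv, nv in zip(rec_vals, non_vals)])
            assert t.differences[f].mean() == pytest.approx(expect, rel=1e-12)

    def test_subject_mismatch_rejected(self):
        rec = [make_feature_vector(subject_id="A")]
        non = [make_feature_vector(subject_id="B", roi_role="GTVnr")]
        with pytest.raises(ValueError, match="do not match"):
            paired_differences(rec, non)


class TestTestFeature:
    def test_normal_data_mostly_uses_t(self):
        chose_t = 0
        for seed in range(100):
            d = np.random.default_rng(seed).normal(2.0, 1.0, 14)
            r = feature_test(d, 0.05, 1)
            chose_t += r.test_used == "paired_t"
        assert chose_t >= 90

    def test_skewed_data_often_uses_wilcoxon(self):
        chose_w = 0
        for seed in range(100):
            d = np.random.default_rng(seed).exponential(1.0, 14) - 0.1
            r = feature_test(d, 0.05, 1)
            chose_w += r.test_used == "wilcoxon_signed_rank"
        assert chose_w >= 50

    def test_branch_matches_shapiro(self, rng):
        for _ in range(50):
            d = rng.normal(size=14) + rng.exponential(1, 14) * rng.integers(0, 2)
            r = feature_test(d, 0.05, 47)
            if r.degenerate:
                continue
            if r.shapiro_p < 0.05:
                assert r.test_used == "wilcoxon_signed_rank"
            else:
                assert r.test_used == "paired_t"

    def test_t_p_matches_closed_form(self, rng):
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 14)
            r = feature_test(d, 0.05, 1)
            if r.test_used != "paired_t":
                continue
            t = r.mean_diff / (r.sd_diff / np.sqrt(14))
            p = 2 * sps.t.sf(abs(t), 13)
            assert r.p_value == pytest.approx(p, abs=1e-12)

    def test_zero_variance_degenerate(self):
        r = feature_test(np.full(10, 3.0), 0.05, 47)
        assert r.degenerate and not r.significant

    def test_type_one_error_calibrated(self):
        # full branched test at nominal 0.05, null N(0,1) differences
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            d = np.random.default_rng(seed + 10_000).normal(size=14)
            r = feature_test(d, 0.05, 1)
            rejections += r.significant
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07

    def test_minimum_n(self):
        with pytest.raises(ValueError, match="n >= 3"):
            feature_test(np.array([1.0, 2.0]), 0.05, 1)


class TestWilcoxonExact:
    def test_matches_full_sign_enumeration_n5(self, rng):
        for _ in range(20):
            d = rng.normal(size=5)
            while np.unique(np.abs(d)).size < 5 or np.any(d == 0):
                d = rng.normal(size=5)
            assert wilcoxon_signed_rank_p(d) == pytest.approx(
                wilcoxon_two_sided_exact(d), abs=1e-12
            )

    def test_zeros_dropped(self):
        d = np.array([0.0, 0.0, 1.0, -2.0, 3.0, 4.0, -5.0])
        assert wilcoxon_signed_rank_p(d) == pytest.approx(
            wilcoxon_two_sided_exact(d[d != 0]), abs=1e-12
        )


class TestCorrelationMatrix:
    def make_table(self, X, features):
        import pandas as pd

        from hetrad.stats import PairedStudyTable

        df = pd.DataFrame(X, columns=features)
        return PairedStudyTable(differences=df, subject_ids=[f"S{i}" for i in range(len(df))])

    def test_duplicated_feature_perfect_correlation(self, rng):
        x = rng.normal(size=14)
        t = self.make_table(np.column_stack([x, x]), ["a", "b"])
        r, p, mask = correlation_matrix(t, ["a", "b"])
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert mask.loc["a", "b"]
        assert (np.diag(r) == 1.0).all()

    def test_anticorrelated_columns(self, rng):
        x = rng.normal(size=10)
        t = self.make_table(np.column_stack([x, -x]), ["a", "b"])
        r, _, _ = correlation_matrix(t, ["a", "b"])
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_null_significance_rate_about_five_percent(self):
        hits = 0
        n_rep = 1000
        for seed in range(n_rep):
            g = np.random.default_rng(seed + 777)
            t = self.make_table(g.normal(size=(14, 2)), ["a", "b"])
            _, _, mask = correlation_matrix(t, ["a", "b"])
            hits += bool(mask.loc["a", "b"])
        assert 0.03 <= hits / n_rep <= 0.07

    def test_zero_variance_column_rejected(self):
        t = self.make_table(np.column_stack([np.ones(8), np.arange(8.0)]), ["a", "b"])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(t, ["a", "b"])

    def test_symmetry(self, rng):
        t = self.make_table(rng.normal(size=(12, 4)), list("abcd"))
        r, p, _ = correlation_matrix(t, list("abcd"))
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        np.testing.assert_allclose(p.to_numpy(), p.to_numpy().T)


class TestPcaRegions:
    def region_table(self, X, features):
        import pandas as pd

        df = pd.DataFrame(X, columns=features)
        df.insert(0, "region", ["recurrent"] * (len(df) // 2) + ["nonrecurrent"] * (len(df) - len(df) // 2))
        return df

    def test_perfectly_correlated_features_pc1_explains_all(self, rng):
        x = rng.normal(size=20)
        df = self.region_table(np.column_stack([x, 3 * x]), ["a", "b"])
        res = pca_regions(df, ["a", "b"])
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_normalized_and_ordered(self, rng):
        df = self.region_table(rng.normal(size=(28, 7)), list("abcdefg"))
        res = pca_regions(df, list("abcdefg"))
        evf = res.explained_variance_fraction
        assert evf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(evf) <= 1e-12)
        assert np.all((evf >= 0) & (evf <= 1))

    def test_scores_reconstruct_from_loadings(self, rng):
        df = self.region_table(rng.normal(size=(20, 5)), list("abcde"))
        feats = list("abcde")
        res = pca_regions(df, feats)
        Z = (df[feats].to_numpy() - res.feature_means) / res.feature_sds
        recon = Z @ res.loadings.to_numpy()
        comp_cols = [c for c in res.scores.columns if c != "region"]
        np.testing.assert_allclose(res.scores[comp_cols].to_numpy(), recon, atol=1e-9)
        # centered scores
        np.testing.assert_allclose(res.scores[comp_cols].mean(), 0.0, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        df = self.region_table(rng.normal(size=(15, 4)), list("abcd"))
        res = pca_regions(df, list("abcd"))
        L = res.loadings.to_numpy()
        for c in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, c])), c] > 0

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            pca_regions(self.region_table(X, ["a", "b"]), ["a", "b"])


class TestRunStatistics:
    def cohort(self, rng, n=8, effect=None):
        rec, non = [], []
        for i in range(n):
            base = dict(zip(FEATURE_NAMES, rng.normal(size=47)))
            shifted = dict(base)
            if effect:
                for f, e in effect.items():
                    shifted[f] = base[f] + e + rng.normal(0, 0.1)
            rec.append(make_feature_vector(shifted, subject_id=f"S{i:02d}"))
            non.append(make_feature_vector(base, subject_id=f"S{i:02d}", roi_role="GTVnr"))
        return rec, non

    def test_identical_cohort_all_degenerate(self):
        rec = [make_feature_vector(subject_id=f"S{i}") for i in range(5)]
        non = [make_feature_vector(subject_id=f"S{i}", roi_role="GTVnr") for i in range(5)]
        with pytest.warns(UserWarning, match="no feature survives"):
            res = run_statistics(rec, non)
        assert res.significant_features == []
        assert all(r.degenerate for r in res.tests)

    def test_injected_effect_detected(self, rng):
        rec, non = self.cohort(rng, n=14, effect={"NGTDM_Busyness": -3.0, "NGTDM_Coarseness": 3.0})
        res = run_statistics(rec, non)
        assert "NGTDM_Busyness" in res.significant_features
        assert "NGTDM_Coarseness" in res.significant_features
        # branch bookkeeping holds on every reported test
        for r in res.tests:
            if not r.degenerate:
                assert (r.test_used == "wilcoxon_signed_rank") == (r.shapiro_p < 0.05)

    def test_alpha_monotonicity(self, rng):
        rec, non = self.cohort(rng, n=14, effect={"GLSZM_GLV": 1.0, "NGTDM_Strength": 2.0})
        res1 = HabitatComparison(rec, non).fit(alpha=0.05)
        res2 = HabitatComparison(rec, non).fit(alpha=0.10)
        assert set(res1.significant_features) <= set(res2.significant_features)

    def test_summary_mentions_key_quantities(self, rng):
        rec, non = self.cohort(rng, n=10, effect={"NGTDM_Strength": 4.0})
        res = run_statistics(rec, non)
        s = res.summary()
        assert "Bonferroni" in s and "subjects: 10" in s and "0.001" in s
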