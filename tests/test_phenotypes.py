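import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from kinboost.phenotypes import (
    age_composition_test,
    broodstock_date_subset,
    freshwater_age_test,
    holm_bonferroni,
    ks_run_timing,
    size_at_age_fit,
)

# Age-composition reconstructions: proportions x N, rounded to integers
TABLE3 = {
    2011: ((3642, (0.013, 0.060, 0.327, 0.600)), (554, (0.0, 0.125, 0.581, 0.294)), 183.14, 3.0),
    2012: ((528, (0.009, 0.040, 0.653, 0.297)), (711, (0.001, 0.145, 0.782, 0.072)), 125.95, 0.5),
    2013: ((725, (0.010, 0.070, 0.487, 0.433)), (279, (0.0, 0.204, 0.667, 0.129)), 92.74, 0.5),
}


def _ages_from_proportions(n, props):
    ages = []
    for age, p in zip((3, 4, 5, 6), props):
        ages.extend([age] * int(round(p * n)))
    return ages


class TestRunTiming:
    def test_identical_samples(self):
        r = ks_run_timing([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_disjoint_supports(self):
        r = ks_run_timing([1, 2, 3], [4, 5, 6])
        assert r.statistic == 1.0

    def test_d_matches_exhaustive_sup(self):
        """D equals the brute-force sup over the pooled sample points."""
        rng = np.random.default_rng(0)
        h = rng.integers(150, 250, 5).astype(float)
        w = rng.integers(150, 250, 5).astype(float)
        r = ks_run_timing(h, w)
        grid = np.concatenate([h, w])
        sup = max(
            abs(np.mean(h <= x) - np.mean(w <= x)) for x in grid
        )
        assert r.statistic == pytest.approx(sup)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        h = rng.normal(190, 10, 40)
        w = rng.normal(195, 10, 60)
        d1 = ks_run_timing(h, w).statistic
        d2 = ks_run_timing(np.exp(h / 50), np.exp(w / 50)).statistic
        assert d1 == pytest.approx(d2)

    def test_delta_sign_convention(self):
        r = ks_run_timing([180, 181, 182], [190, 191, 192])
        assert r.extra["delta_days"] < 0  # hatchery earlier -> negative

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_run_timing([], [1, 2])


class TestAgeComposition:
    @pytest.mark.parametrize("brood", sorted(TABLE3))
    def test_reconstructed_chi2(self, brood):
        (nw, pw), (nh, ph), expected, tol = TABLE3[brood]
        w = _ages_from_proportions(nw, pw)
        h = _ages_from_proportions(nh, ph)
        r = age_composition_test(h, w)
        assert r.statistic == pytest.approx(expected, abs=tol)
        assert r.df == 2

    def test_identical_proportions(self):
        ages = [4] * 10 + [5] * 30 + [6] * 20
        r = age_composition_test(ages, ages)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_zero_class_errors(self):
        with pytest.raises(ValueError, match="age class"):
            age_composition_test([5] * 10, [5] * 10)  # no 3/4, no 6 anywhere

    def test_age_range_checked(self):
        with pytest.raises(ValueError, match="total age"):
            age_composition_test([7], [5])


class TestFreshwaterAge:
    def test_reconstructed_brood_2011(self):
        # wild 234 x (0.256, 0.744); hatchery 31 x (0.871, 0.129)
        w = [1] * 60 + [2] * 174
        h = [1] * 27 + [2] * 4
        r = freshwater_age_test(h, w)
        assert r.p_raw < 0.0001

    def test_identical_proportions(self):
        r = freshwater_age_test([1] * 5 + [2] * 5, [1] * 5 + [2] * 5)
        assert r.p_raw == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals full enumeration over fixed margins."""
        h = [1] * 6 + [2] * 4
        w = [1] * 2 + [2] * 8
        r = freshwater_age_test(h, w)
        a, b = 6, 4  # hatchery row
        c, d = 2, 8
        n = a + b + c + d
        row1, col1 = a + b, a + c
        p_obs = comb(row1, a) * comb(n - row1, col1 - a) / comb(n, col1)
        total = 0.0
        for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
            p_x = comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)
            if p_x <= p_obs * (1 + 1e-9):
                total += p_x
        assert r.p_raw == pytest.approx(total, abs=1e-10)

    def test_empty_margin(self):
        r = freshwater_age_test([1, 1], [1, 1, 1])
        assert r.p_raw == 1.0 and r.note == "empty margin"


def _size_frame(rng, n, beta_origin=10.0, beta_sex=20.0):
    origin = rng.choice(["hatchery", "wild"], n)
    sex = rng.choice(["F", "M"], n)
    scale_age = rng.choice(["1.2", "2.2", "1.3", "2.3"], n)
    age_effect = {"1.2": 0.0, "2.2": 5.0, "1.3": 40.0, "2.3": 45.0}
    mefl = (
        500.0
        + beta_origin * (origin == "hatchery")
        + beta_sex * (sex == "M")
        + np.array([age_effect[a] for a in scale_age])
        + rng.normal(0, 15, n)
    )
    return pd.DataFrame({"mefl_mm": mefl, "origin": origin, "sex": sex, "scale_age": scale_age})


class TestSizeAtAge:
    def test_origin_effect_recovery(self):
        rng = np.random.default_rng(0)
        df = _size_frame(rng, 200, beta_origin=10.0)
        m = size_at_age_fit(df, brood_year=2011)
        se = m.std_errors["origin[hatchery]"]
        assert m.coefficients["origin[hatchery]"] == pytest.approx(10.0, abs=3 * se)

    def test_null_calibration(self):
        """With no origin effect the origin p-value is ~uniform."""
        rng = np.random.default_rng(1)
        sig = 0
        reps = 300
        for _ in range(reps):
            df = _size_frame(rng, 80, beta_origin=0.0)
            sig += size_at_age_fit(df).origin_p < 0.05
        assert 0.02 <= sig / reps <= 0.08

    def test_constant_response(self):
        rng = np.random.default_rng(2)
        df = _size_frame(rng, 60)
        df["mefl_mm"] = 500.0
        m = size_at_age_fit(df)
        for name, val in m.coefficients.items():
            if name != "Intercept":
                assert val == pytest.approx(0.0, abs=1e-8)
        assert m.residual_sigma == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficiency_named(self):
        rng = np.random.default_rng(3)
        df = _size_frame(rng, 50)
        df["sex"] = "F"  # one sex only -> sex column constant 0 ... keep origin
        with pytest.raises(ValueError, match="sex"):
            size_at_age_fit(df)

    def test_needs_both_origins(self):
        rng = np.random.default_rng(4)
        df = _size_frame(rng, 30)
        df["origin"] = "wild"
        with pytest.raises(ValueError, match="both origins"):
            size_at_age_fit(df)


class TestHolm:
    def test_two_pvalues(self):
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_single_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.3]), [0.3])

    def test_capped_at_one(self):
        np.testing.assert_allclose(holm_bonferroni([0.5, 0.5, 0.5]), [1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            ours = holm_bonferroni(p)
            theirs = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(ours, theirs)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 15)
        adj = holm_bonferroni(p)
        assert (adj >= p).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestBroodstockDateSubset:
    def _setup(self):
        registry = pd.DataFrame(
            {
                "id": ["P1", "P2", "B1", "O1", "O2", "O3"],
                "return_year": [2012, 2012, 2012, 2016, 2016, 2016],
                "return_doy": [200, 215, 201, 205, 205, 205],
                "is_broodstock": [False, False, True, False, False, False],
            }
        )
        assignments = pd.DataFrame(
            {
                "offspring_id": ["O1", "O2", "O3"],
                "brood_year": [2012, 2012, 2012],
                "dam_id": ["P1", "P2", "B1"],
                "sire_id": [None, None, None],
            }
        )
        return registry, assignments

    def test_window_membership(self):
        registry, assignments = self._setup()
        # window covers P1 only; O3 is hatchery-born and excluded
        subset = broodstock_date_subset(assignments, registry, 2012, (200, 201))
        assert subset == ["O1"]

    def test_whole_season_window(self):
        registry, assignments = self._setup()
        subset = broodstock_date_subset(assignments, registry, 2012, (1, 366))
        assert set(subset) == {"O1", "O2"}

    def test_empty_window(self):
        registry, assignments = self._setup()
        assert broodstock_date_subset(assignments, registry, 2012, (10, 11)) == []
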