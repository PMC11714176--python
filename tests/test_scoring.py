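"""Percentile scoring, CLR density, ROC cutoff and tertile machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmescore.scoring import (
    _bracket,
    clr_categorize,
    clr_density,
    density_score,
    pdl1_tumor_categorize,
    percentile_rank,
    percentile_score,
    proximity_score,
    roc_optimal_cutoff,
    tertile_classify,
)


def midrank_percentiles_oracle(values):
    """Independent mid-rank percentile recomputation (count-based)."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    n = ok.sum()
    out = np.full(x.shape, np.nan)
    for i in np.flatnonzero(ok):
        less = np.sum(x[ok] < x[i])
        equal = np.sum(x[ok] == x[i])
        out[i] = 100.0 * (less + 0.5 * equal) / n
    return out


class TestPercentileRank:
    def test_midrank_formula_by_hand(self):
        assert percentile_rank([1, 2, 3, 4])[-1] == pytest.approx(87.5)

    def test_all_ties_give_fifty(self):
        assert np.allclose(percentile_rank([3.0] * 7), 50.0)

    def test_matches_counting_oracle_and_mean_is_fifty(self, rng):
        x = rng.normal(size=171)
        pct = percentile_rank(x)
        np.testing.assert_allclose(pct, midrank_percentiles_oracle(x))
        assert np.argsort(pct).tolist() == np.argsort(x).tolist()
        assert pct.mean() == pytest.approx(50.0)

    def test_missing_values_excluded_from_n(self):
        pct = percentile_rank([1.0, np.nan, 2.0])
        assert np.isnan(pct[1]) and pct[0] == 25.0 and pct[2] == 75.0

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            percentile_rank([np.nan, np.nan])


class TestDensityScore:
    def test_bracket_boundaries(self):
        # low is closed at 25, intermediate closed at 70
        got = _bracket(np.array([25.0, 25.0001, 70.0, 70.0001]), (25.0, 70.0))
        assert got.tolist() == ["low", "intermediate", "intermediate", "high"]

    def test_cohort_maximum_in_all_components_is_high(self, rng):
        x = rng.uniform(size=12)
        x[3] = 2.0  # cohort max
        out = density_score(x, x, x, x)
        assert out["score"].iloc[3] == "high"

    def test_category_proportions_for_comonotone_continuous_data(self, rng):
        # four strictly monotone transforms of one continuous variable: the
        # mean percentile equals the common percentile, so the brackets give
        # 25% low, 45% intermediate, 30% high exactly at n = 100
        u = rng.uniform(1, 2, size=100)
        out = density_score(u, u**2, np.log(u), 10 * u - 3)
        counts = out["score"].value_counts()
        assert counts["low"] == 25
        assert counts["intermediate"] == 45
        assert counts["high"] == 30

    def test_partial_components_use_available_mean(self):
        cd3_ct = np.array([1.0, 2.0, 3.0, 4.0])
        cd3_im = np.array([4.0, np.nan, 2.0, 1.0])
        cd8_ct = np.array([2.0, np.nan, 4.0, 3.0])
        cd8_im = np.array([3.0, np.nan, 1.0, 2.0])
        out = density_score(cd3_ct, cd3_im, cd8_ct, cd8_im)
        pcts = [percentile_rank(c) for c in (cd3_ct, cd3_im, cd8_ct, cd8_im)]
        stacked = np.vstack(pcts)
        expected = np.nanmean(stacked, axis=0)
        np.testing.assert_allclose(out["mean_percentile"], expected)
        # tumor 1 has only its cd3_ct percentile available
        assert out["mean_percentile"].iloc[1] == pytest.approx(pcts[0][1])

    def test_all_components_missing_gives_missing_score(self):
        out = density_score([1, 2, np.nan], [1, 2, np.nan], [1, 2, np.nan],
                            [1, 2, np.nan])
        assert out["score"].iloc[2] is None
        assert out["score"].notna().sum() == 2

    def test_proximity_score_shares_machinery(self, rng):
        a, b, c, d = (rng.uniform(size=30) for _ in range(4))
        dens = density_score(a, b, c, d)
        prox = proximity_score(a, b, c, d)
        assert dens["score"].tolist() == prox["score"].tolist()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        r = np.random.default_rng(seed)
        cols = [r.normal(size=20) for _ in range(4)]
        base = density_score(*cols)["score"].tolist()
        transformed = density_score(*(np.exp(3 * c) for c in cols))["score"].tolist()
        assert base == transformed

    def test_permutation_equivariance(self, rng):
        cols = [rng.normal(size=25) for _ in range(4)]
        base = density_score(*cols)["score"].to_numpy()
        perm = rng.permutation(25)
        permuted = density_score(*(c[perm] for c in cols))["score"].to_numpy()
        assert (base[perm] == permuted).all()


class TestClr:
    def test_cutoff_arithmetic(self):
        assert clr_density(21, 50.0) == pytest.approx(0.42)
        assert clr_density(0, 50.0) == 0.0

    def test_vectorized_equals_scalar_recomputation(self, rng):
        counts = rng.integers(0, 40, size=50)
        lengths = rng.uniform(10, 90, size=50)
        d = clr_density(counts, lengths)
        np.testing.assert_allclose(d, [c / l for c, l in zip(counts, lengths)])

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(ValueError):
            clr_density(5, 0.0)

    def test_cutoff_is_inclusive_into_high(self):
        assert clr_categorize([0.42, 0.419, np.nan]).tolist() == ["high", "low", None]


class TestRocCutoff:
    def test_perfect_separation(self):
        res = roc_optimal_cutoff([1, 2, 3, 4], [False, False, True, True])
        assert res.cutoff == pytest.approx(2.5)
        assert res.youden_j == pytest.approx(1.0)

    def test_null_labels_give_small_j(self, rng):
        x = rng.normal(size=200)
        js = []
        for _ in range(30):
            y = rng.permutation(np.arange(200) < 100)
            js.append(roc_optimal_cutoff(x, y).youden_j)
        # max-J over thresholds is positively biased under the null but small
        assert 0 <= np.mean(js) < 0.25

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_optimal_cutoff([1, 2, 3], [True, True, True])

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            res = roc_optimal_cutoff(x, y)
            # independent exhaustive scan
            uniq = np.unique(x)
            cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
            best_j, best_t = -np.inf, None
            for t in cands:
                pred = x >= t
                sens = (pred & y).sum() / y.sum()
                spec = (~pred & ~y).sum() / (~y).sum()
                if sens + spec - 1 > best_j + 1e-12:
                    best_j, best_t = sens + spec - 1, t
            assert res.cutoff == pytest.approx(best_t)
            assert res.youden_j == pytest.approx(best_j)


class TestTertiles:
    def test_one_to_nine_splits_evenly(self):
        got = tertile_classify(np.arange(1, 10))
        assert got.tolist() == ["low"] * 3 + ["moderate"] * 3 + ["high"] * 3

    def test_heavy_ties_absorbed_into_one_group(self):
        got = tertile_classify([1, 2, 5, 5, 5, 5, 5, 8, 9])
        assert got[2:7].tolist() == ["moderate"] * 5

    def test_group_sizes_near_equal_for_continuous(self, rng):
        got = tertile_classify(rng.normal(size=100))
        sizes = pd.Series(got).value_counts()
        assert all(abs(sizes[g] - 100 / 3) <= 1 for g in ("low", "moderate", "high"))

    def test_missing_stays_missing(self):
        got = tertile_classify([1.0, np.nan, 2.0, 3.0])
        assert got[1] is None


class TestPdl1Brackets:
    @pytest.mark.parametrize(
        "histoscore,expected",
        [(0.9, "negative"), (1.0, "1-<5"), (4.999, "1-<5"), (5.0, ">=5"), (0.0, "negative")],
    )
    def test_printed_brackets(self, histoscore, expected):
        assert pdl1_tumor_categorize([histoscore])[0] == expected

    def test_labels_only_from_declared_set(self, rng):
        got = pdl1_tumor_categorize(rng.uniform(0, 100, size=200))
        assert set(got) <= {"negative", "1-<5", ">=5"}
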