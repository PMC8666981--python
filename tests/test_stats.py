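import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from somacohort.stats import (ContingencyTable, SurvivalRecord,
                              fisher_exact_two_sided, format_p,
                              km_survival_at, log_rank, mann_whitney_u,
                              median_mad, run_contrast_grid)


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of all margin-preserving 2x2 tables."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                        math.comb(n, c1))

    p_obs = prob(a)
    total = sum(prob(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                if prob(k) <= p_obs)
    return float(total)


def mw_oracle(a, b):
    """Full enumeration of group labelings for the two-sided U test."""
    pooled = list(a) + list(b)
    nA = len(a)

    def u_stat(idx):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum((x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b)

    mid = nA * len(b) / 2
    obs = abs(u_stat(range(nA)) - mid)
    labelings = list(itertools.combinations(range(len(pooled)), nA))
    hits = sum(1 for idx in labelings if abs(u_stat(idx) - mid) >= obs - 1e-12)
    return hits / len(labelings)


class TestFisher:
    def test_equal_proportions_give_one(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_gives_one_with_warning(self):
        with pytest.warns(UserWarning, match="empty margin"):
            assert fisher_exact_two_sided([[0, 5], [0, 7]]) == 1.0

    def test_row_and_column_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            p = fisher_exact_two_sided([[a, b], [c, d]])
            assert fisher_exact_two_sided([[c, d], [a, b]]) == pytest.approx(p)
            assert fisher_exact_two_sided([[b, a], [d, c]]) == pytest.approx(p)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            p = fisher_exact_two_sided([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = fisher_exact_two_sided([[a, b], [c, d]])
            assert 0 < p <= 1


class TestMannWhitney:
    def test_two_two_exact(self):
        # U=0; all C(4,2)=6 labelings, 2 as extreme -> p = 1/3
        assert mann_whitney_u([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_give_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            nA, nB = rng.integers(2, 8, size=2)
            pooled = rng.permutation(np.arange(1.0, nA + nB + 1))  # no ties
            a, b = pooled[:nA], pooled[nA:]
            assert mann_whitney_u(a, b) == pytest.approx(mw_oracle(a, b),
                                                         rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestMedianMad:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4, 100], (3, 1)),
        ([5], (5, 0)),
        ([1, 2, 3, 4], (2.5, 1.0)),
    ])
    def test_examples(self, values, expected):
        assert median_mad(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_mad([])


def _recs(times_events, group=""):
    return [SurvivalRecord(f"s{i}", t, bool(e), group)
            for i, (t, e) in enumerate(times_events)]


class TestKaplanMeier:
    def test_no_events_is_one(self):
        recs = _recs([(30, 0), (40, 0), (50, 0)])
        assert km_survival_at(recs, 24) == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survival(self):
        recs = _recs([(t, 1) for t in range(10, 20)] +
                     [(t, 1) for t in range(30, 35)])
        # 10 of 15 events before t=24
        assert km_survival_at(recs, 24) == pytest.approx(5 / 15)

    def test_staggered_product_limit_by_hand(self):
        # events at 5 (n=5) and 15 (n=3 after the censor at 10):
        # S(24) = (4/5) * (2/3) = 8/15
        recs = _recs([(5, 1), (10, 0), (15, 1), (20, 0), (25, 1)])
        assert km_survival_at(recs, 24) == pytest.approx(8 / 15, abs=1e-9)


def logrank_oracle(a, b):
    """Hand computation of the one-df log-rank chi-square p-value."""
    events = sorted({r.time for r in a + b if r.event})
    O_minus_E = 0.0
    var = 0.0
    for t in events:
        n1 = sum(1 for r in a if r.time >= t)
        n2 = sum(1 for r in b if r.time >= t)
        d1 = sum(1 for r in a if r.event and r.time == t)
        d2 = sum(1 for r in b if r.event and r.time == t)
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = O_minus_E ** 2 / var
    return float(chi2.sf(stat, 1))


class TestLogRank:
    def test_identical_groups_give_one(self):
        recs = _recs([(5, 1), (10, 1), (15, 0)])
        assert log_rank(recs, list(recs)) == pytest.approx(1.0)

    def test_extreme_separation(self):
        a = _recs([(60, 0)] * 8, "a")
        b = _recs([(1, 1)] * 8, "b")
        assert log_rank(a, b) < 0.01

    def test_matches_hand_computed_observed_expected(self):
        a = _recs([(3, 1), (6, 0), (9, 1), (14, 0), (20, 1)], "a")
        b = _recs([(2, 1), (4, 1), (7, 1), (11, 0), (16, 1)], "b")
        assert log_rank(a, b) == pytest.approx(logrank_oracle(a, b), abs=1e-6)

    def test_no_events_warns_and_returns_one(self):
        a = _recs([(5, 0)])
        b = _recs([(7, 0)])
        with pytest.warns(UserWarning, match="no events"):
            assert log_rank(a, b) == 1.0


class TestContrastGrid:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(4)
        n = 30
        return pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "age_group": ["<50"] * 20 + [">=50"] * 10,
            "sex": rng.choice(["male", "female"], n).tolist(),
            "smoking": ["ever"] * 10 + ["never"] * 10 + ["unknown"] * 10,
            "flag": [True] * 15 + [False] * 15,
            "allfalse": [False] * n,
            "tmb": rng.lognormal(1.2, 0.5, n).tolist(),
        })

    def test_binary_feature_uses_fisher(self, table):
        res = run_contrast_grid(table, [{"feature": "flag", "grouping": "age"}])
        assert res[0].test == "fisher_exact"
        assert 0 < res[0].p_value <= 1
        assert res[0].n_per_group == (20, 10)

    def test_numeric_feature_uses_mann_whitney(self, table):
        res = run_contrast_grid(table, [{"feature": "tmb", "grouping": "age"}])
        assert res[0].test == "mann_whitney_u"
        med, mad = res[0].estimate_per_group[0]
        assert med > 0 and mad >= 0

    def test_unknown_smoking_excluded(self, table):
        res = run_contrast_grid(table,
                                [{"feature": "flag", "grouping": "smoking"}])
        assert sum(res[0].n_per_group) == 20  # 10 unknown dropped

    def test_constant_feature_warns_p_one(self, table):
        with pytest.warns(UserWarning, match="constant"):
            res = run_contrast_grid(
                table, [{"feature": "allfalse", "grouping": "age"}])
        assert res[0].p_value == 1.0

    def test_missing_feature_lists_columns(self, table):
        with pytest.raises(KeyError, match="available"):
            run_contrast_grid(table, [{"feature": "nope", "grouping": "age"}])


class TestPrintedP:
    @pytest.mark.parametrize("p,printed", [
        (0.0158, "0.02"), (0.0043, "0.004"), (0.0797, "0.08"),
        (0.3897, "0.39"), (1.0, "1"), (0.0005, "<0.001"), (0.54, "0.54"),
    ])
    def test_display_rounding(self, p, printed):
        assert format_p(p) == printed
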