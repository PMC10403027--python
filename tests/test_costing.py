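"""Expenditure decomposition: service tables, windows, deciles, clusters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eolpathways import (
    cluster_cost_share,
    cluster_cost_summary,
    patient_totals,
    service_cost_table,
    top_decile_summary,
    window_share,
)
from eolpathways.costing import CATEGORY_CODES

from _oracles import summary_stats


def claims_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "days_before_death",
                                       "category", "cost"])


def random_claims(rng, ids, n_claims):
    return claims_frame(
        {
            "patient_id": rng.choice(ids, n_claims),
            "days_before_death": rng.integers(0, 365, n_claims),
            "category": rng.choice(CATEGORY_CODES, n_claims),
            "cost": rng.gamma(2.0, 500.0, n_claims),
        }
    )


class TestServiceCostTable:
    def test_no_claims_all_zero(self):
        table = service_cost_table(claims_frame([]), ["a", "b"]).table
        assert (table["mean"] == 0).all()
        assert (table["median"] == 0).all()
        assert (table["pct_users"] == 0).all()

    def test_three_patient_hand_fixture(self):
        # p1: 1000 acute + 200 pharmacy; p2: 100 pharmacy; p3: no claims.
        claims = claims_frame(
            [
                ("p1", 10, "acute_hospital", 1000.0),
                ("p1", 5, "pharmacy", 200.0),
                ("p2", 300, "pharmacy", 100.0),
            ]
        )
        tab = service_cost_table(claims, ["p1", "p2", "p3"])
        acute = tab.table.loc["acute_hospital"]
        assert acute["mean"] == 1000.0 / 3
        assert acute["pct_users"] == pytest.approx(100 / 3)
        assert acute["median"] == 0.0
        pharmacy = tab.table.loc["pharmacy"]
        assert pharmacy["mean"] == 100.0
        assert pharmacy["pct_users"] == pytest.approx(200 / 3)
        assert pharmacy["median"] == 100.0  # zero-claim patient pulls it down
        total = tab.table.loc["total"]
        assert total["mean"] == pytest.approx(1300.0 / 3)
        assert total["median"] == 100.0
        assert total["pct_users"] == pytest.approx(200 / 3)

    def test_matches_naive_oracle_on_random_fixture(self, rng):
        ids = [f"p{i}" for i in range(15)]
        claims = random_claims(rng, ids, 200)
        tab = service_cost_table(claims, ids).table
        per_pat = claims.groupby(["patient_id", "category"])["cost"].sum()
        for cat in CATEGORY_CODES:
            values = [per_pat.get((p, cat), 0.0) for p in ids]
            expected = summary_stats(values)
            for key in ("mean", "sd", "median", "iqr"):
                assert tab.loc[cat, key] == pytest.approx(expected[key])

    def test_window_restricts_claims(self):
        claims = claims_frame(
            [("p1", 10, "pharmacy", 100.0), ("p1", 200, "pharmacy", 900.0)]
        )
        tab90 = service_cost_table(claims, ["p1"], window_days=90)
        assert tab90.table.loc["pharmacy", "mean"] == 100.0

    def test_category_means_sum_to_total_mean(self, rng):
        ids = [f"p{i}" for i in range(30)]
        claims = random_claims(rng, ids, 500)
        tab = service_cost_table(claims, ids).table
        assert tab.loc[CATEGORY_CODES, "mean"].sum() == pytest.approx(
            tab.loc["total", "mean"], rel=1e-9
        )
        assert tab.loc[CATEGORY_CODES, "pct_of_total"].sum() == pytest.approx(100.0)

    def test_unknown_patient_rejected(self):
        claims = claims_frame([("ghost", 0, "pharmacy", 1.0)])
        with pytest.raises(ValueError):
            service_cost_table(claims, ["p1"])

    def test_invalid_day_offset_rejected(self):
        claims = claims_frame([("p1", 400, "pharmacy", 1.0)])
        with pytest.raises(ValueError):
            service_cost_table(claims, ["p1"])


class TestWindowShare:
    def test_all_spending_in_last_90_days(self):
        claims = claims_frame([("p1", 10, "pharmacy", 50.0),
                               ("p2", 89, "pharmacy", 10.0)])
        assert window_share(claims) == 1.0

    def test_constant_daily_spend_is_analytic_ratio(self):
        claims = claims_frame(
            [("p1", d, "pharmacy", 1.0) for d in range(365)]
        )
        assert window_share(claims) == pytest.approx(90 / 365)

    def test_no_spending_returns_zero(self):
        assert window_share(claims_frame([])) == 0.0

    def test_monotone_in_window_and_one_at_365(self, rng):
        claims = random_claims(rng, [f"p{i}" for i in range(5)], 100)
        shares = [window_share(claims, short_window=w) for w in (30, 90, 180, 365)]
        assert all(a <= b + 1e-12 for a, b in zip(shares, shares[1:]))
        assert shares[-1] == 1.0


class TestTopDecile:
    def test_twenty_patients_arithmetic(self):
        totals = pd.Series(np.arange(1.0, 21.0), index=[f"p{i:02d}" for i in range(20)])
        dec = top_decile_summary(totals)
        assert dec.count == 2
        assert dec.threshold == 19.0
        assert dec.share == pytest.approx((19 + 20) / 210)

    def test_equal_totals_count_one_share_tenth(self):
        totals = pd.Series([5.0] * 10, index=[f"p{i}" for i in range(10)])
        dec = top_decile_summary(totals)
        assert dec.count == 1
        assert dec.share == pytest.approx(0.1)

    def test_ties_resolved_stably_by_patient_id(self):
        totals = pd.Series([1.0, 5.0, 5.0, 5.0], index=["d", "c", "b", "a"])
        dec = top_decile_summary(totals)  # count = 4 - 3 = 1
        assert dec.count == 1 and dec.threshold == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_decile_summary(pd.Series(dtype=float))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=10_000))
    def test_count_convention_for_all_n(self, n):
        totals = pd.Series(np.ones(n), index=range(n))
        assert top_decile_summary(totals).count == n - int(np.floor(0.9 * n))


class TestClusterCosts:
    def test_singleton_clusters(self):
        labels = pd.Series([1, 2], index=["a", "b"])
        totals = pd.Series([100.0, 300.0], index=["a", "b"])
        tab = cluster_cost_summary(labels, totals)
        assert tab.loc[1, "mean"] == 100.0 and tab.loc[1, "sd"] == 0.0

    def test_equal_totals_zero_spread(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        totals = pd.Series([50.0] * 4, index=list("abcd"))
        tab = cluster_cost_summary(labels, totals)
        assert (tab["sd"] == 0.0).all() and (tab["iqr"] == 0.0).all()

    def test_nine_patient_hand_fixture(self):
        labels = pd.Series([1] * 3 + [2] * 3 + [3] * 3,
                           index=[f"p{i}" for i in range(9)])
        totals = pd.Series([10.0, 20.0, 30.0, 100.0, 100.0, 130.0, 0.0, 0.0, 900.0],
                           index=[f"p{i}" for i in range(9)])
        tab = cluster_cost_summary(labels, totals)
        assert tab.loc[1, "mean"] == 20.0 and tab.loc[1, "sd"] == 10.0
        assert tab.loc[1, "median"] == 20.0 and tab.loc[1, "iqr"] == 10.0
        assert tab.loc[2, "mean"] == 110.0
        assert tab.loc[2, "sd"] == pytest.approx(np.std([100, 100, 130], ddof=1))
        assert tab.loc[3, "median"] == 0.0 and tab.loc[3, "mean"] == 300.0

    def test_unlabelled_patient_rejected(self):
        labels = pd.Series([1], index=["a"])
        totals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            cluster_cost_summary(labels, totals)


class TestClusterCostShare:
    def test_equal_clusters_equal_shares(self):
        shares = cluster_cost_share([10, 10, 10], [5.0, 5.0, 5.0])
        np.testing.assert_allclose(shares, 1 / 3)

    def test_shares_sum_to_one(self, rng):
        for _ in range(20):
            sizes = rng.integers(1, 100, 4)
            means = rng.gamma(2, 100, 4)
            assert cluster_cost_share(sizes, means).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cluster_cost_share([1, 2], [0.0, 0.0])


def test_patient_totals_includes_zero_patients(rng):
    ids = [f"p{i}" for i in range(8)]
    claims = random_claims(rng, ids[:5], 50)
    totals = patient_totals(claims, ids)
    assert len(totals) == 8
    assert (totals.loc[ids[5:]] == 0).all()
    assert totals.sum() == pytest.approx(claims["cost"].sum())
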