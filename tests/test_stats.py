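import math

import numpy as np
import pandas as pd
import pytest

from pindex.io import ZipGazetteer
from pindex.stats import (binomial_sex_test, cluster_geopoints,
                          geocode_participants, normalize_zip,
                          pindex_distribution, prevalence_table,
                          stratify_by_field, wilcoxon_rank_sum)
from helpers import exact_mann_whitney_two_sided, make_cohort


def ptable_of(values, ids=None):
    ids = ids or [f"P{i}" for i in range(len(values))]
    return pd.DataFrame({"participant_id": ids,
                         "raw_sum": [0] * len(values),
                         "p_index": values})


class TestPrevalence:
    def test_direct_ratio(self):
        c = make_cohort({"A": {"d": "yes"}, "B": {"d": "no"},
                         "C": {"d": "no"}, "D": {"d": "no"}})
        row = prevalence_table(c, ["d"]).iloc[0]
        assert row["n_yes"] == 1 and row["n_no"] == 3
        assert row["prevalence_percent"] == pytest.approx(25.0)

    def test_zero_yes(self):
        c = make_cohort({f"P{i}": {"d": "no"} for i in range(10)})
        assert prevalence_table(c, ["d"]).iloc[0]["prevalence_percent"] == 0.0

    def test_no_respondents_flagged_nan(self):
        c = make_cohort({"A": {"d": "unsure"}})
        assert math.isnan(prevalence_table(c, ["d"]).iloc[0]["prevalence_percent"])

    def test_sorted_descending_and_bounded(self):
        c = make_cohort({"A": {"x": "yes", "y": "no"},
                         "B": {"x": "yes", "y": "yes"}})
        df = prevalence_table(c, ["x", "y"])
        assert list(df["phenotype"]) == ["x", "y"]
        assert ((df["n_yes"] + df["n_no"]) <= 2).all()


class TestPIndexDistribution:
    def test_hand_computation(self):
        d = pindex_distribution(ptable_of([0.0, 0.0, 95.0]))
        assert (d.n_above_hi, d.n_below_lo, d.n_zero) == (1, 2, 2)
        assert d.median_all == 0.0
        assert d.median_nonzero == 95.0

    def test_all_hundred(self):
        d = pindex_distribution(ptable_of([100.0] * 4))
        assert d.n_above_hi == 4 and d.n_below_lo == 0

    def test_midpoint_median(self):
        d = pindex_distribution(ptable_of([5.0, 15.0]))
        assert d.median_all == 10.0
        assert d.n_above_hi == 0 and d.n_below_lo == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pindex_distribution(ptable_of([]))


class TestBinomialSexTest:
    def test_symmetric_center(self):
        assert binomial_sex_test(5, 5) == pytest.approx(1.0)

    def test_one_sided_exact_tail(self):
        assert binomial_sex_test(8, 2, sided="one") == pytest.approx(56 / 1024)

    def test_two_sided_symmetric_in_arguments(self):
        assert binomial_sex_test(1793, 1271) == \
            pytest.approx(binomial_sex_test(1271, 1793))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_sex_test(-1, 5)


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_two_vs_two_exact(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_three_vs_three_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(7)
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                for _ in range(3):
                    pooled = rng.choice(1000, size=n_a + n_b, replace=False)
                    a, b = pooled[:n_a].tolist(), pooled[n_a:].tolist()
                    assert wilcoxon_rank_sum(a, b) == pytest.approx(
                        exact_mann_whitney_two_sided(a, b)), (a, b)


class TestStratify:
    def test_hand_medians(self):
        c = make_cohort({"A": {"State": "MA"}, "B": {"State": "MA"},
                         "C": {"State": "MO"}, "D": {"State": "MO"},
                         "E": {"State": "MO"}})
        pt = ptable_of([10, 20, 30, 40, 50], ids=list("ABCDE"))
        df = stratify_by_field(pt, c, "State", min_group=1)
        med = dict(zip(df["label"], df["median_p_index"]))
        assert med == {"MA": 15.0, "MO": 40.0}

    def test_small_group_dropped(self):
        c = make_cohort({f"P{i}": {"State": "UT"} for i in range(29)})
        pt = ptable_of([50.0] * 29, ids=[f"P{i}" for i in range(29)])
        assert len(stratify_by_field(pt, c, "State", min_group=30)) == 0

    def test_pct_above_90(self):
        ids = [f"P{i}" for i in range(31)]
        c = make_cohort({i: {"State": "SC"} for i in ids})
        pt = ptable_of([95.0] * 9 + [50.0] * 22, ids=ids)
        row = stratify_by_field(pt, c, "State", min_group=30).iloc[0]
        assert row["n"] == 31
        assert round(row["pct_above_90"]) == 29

    def test_dual_listed_values_form_own_stratum(self):
        c = make_cohort({"A": {"Sex/Gender": ["Male", "Female"]},
                         "B": {"Sex/Gender": "Male"}})
        df = stratify_by_field(ptable_of([50, 60], ids=["A", "B"]), c,
                               "Sex/Gender", min_group=1)
        assert set(df["label"]) == {"Female / Male", "Male"}

    def test_missing_or_invalid_field_excluded_and_partition(self):
        c = make_cohort({"A": {"State": "MA"}, "B": {"State": "unsure"},
                         "C": {"Height": "170"}})
        df = stratify_by_field(ptable_of([1, 2, 3], ids=["A", "B", "C"]),
                               c, "State", min_group=1)
        assert df["n"].sum() == 1


class TestGeocode:
    gaz = ZipGazetteer([("02144", 42.40, -71.12)])

    def _cohort(self, zips):
        return make_cohort({f"P{i}": {"Zip code": z} for i, z in enumerate(zips)})

    def test_exact_match(self):
        df = geocode_participants(self._cohort(["02144"]), self.gaz)
        assert len(df) == 1 and df.iloc[0]["lat"] == 42.40

    def test_zero_padding(self):
        assert normalize_zip("2144") == "02144"
        df = geocode_participants(self._cohort(["2144"]), self.gaz)
        assert len(df) == 1

    def test_zip_plus_four(self):
        assert normalize_zip("02144-1234") == "02144"

    def test_garbage_dropped_and_reported(self):
        df = geocode_participants(self._cohort(["ABCDE", "02144"]), self.gaz)
        assert len(df) == 1
        assert df.attrs["n_unmatched"] == 1


class TestClusterGeopoints:
    def test_floor_lat_ceil_lon_on_negative_longitude(self):
        pts = pd.DataFrame({"participant_id": ["A"], "zip": ["x"],
                            "lat": [42.36], "lon": [-71.06]})
        df = cluster_geopoints(pts, ptable_of([50.0], ids=["A"]))
        assert (df.iloc[0]["cell_lat"], df.iloc[0]["cell_lon"]) == (42, -71)

    def test_median_unrounded_plot_coordinates(self):
        pts = pd.DataFrame({"participant_id": ["A", "B"], "zip": ["x", "y"],
                            "lat": [42.3, 42.7], "lon": [-71.1, -71.9]})
        df = cluster_geopoints(pts, ptable_of([10.0, 20.0], ids=["A", "B"]))
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["cell_lat"], row["cell_lon"]) == (42, -71)
        assert row["plot_lat"] == pytest.approx(42.5)
        assert row["plot_lon"] == pytest.approx(-71.5)
        assert row["median_p_index"] == pytest.approx(15.0)

    def test_integer_boundary_convention(self):
        pts = pd.DataFrame({"participant_id": ["A"], "zip": ["x"],
                            "lat": [42.0], "lon": [-71.0]})
        df = cluster_geopoints(pts, ptable_of([1.0], ids=["A"]))
        assert (df.iloc[0]["cell_lat"], df.iloc[0]["cell_lon"]) == (42, -71)

    def test_partition(self):
        rng = np.random.default_rng(1)
        n = 200
        pts = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "zip": ["x"] * n,
            "lat": rng.uniform(25, 48, n),
            "lon": rng.uniform(-120, -70, n)})
        df = cluster_geopoints(pts, ptable_of(rng.uniform(0, 100, n).tolist(),
                                              ids=list(pts["participant_id"])))
        assert df["n"].sum() == n
        for _, row in df.iterrows():
            for pid in row["member_ids"]:
                lat = float(pts.loc[pts.participant_id == pid, "lat"].iloc[0])
                lon = float(pts.loc[pts.participant_id == pid, "lon"].iloc[0])
                assert math.floor(lat) == row["cell_lat"]
                assert math.ceil(lon) == row["cell_lon"]
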