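"""Range-change arithmetic, threat classes, elevation shifts, archipelago
tests and protected-area coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from shapely.geometry import box as shapely_box

from bryoclim.change import (
    RangeChangeReport,
    Status,
    classify_status,
    compare_archipelagos,
    elevation_shift,
    pa_coverage,
    pct_remaining,
    protected_cell_mask,
    summarize_pixel_table,
    tabulate,
)
from bryoclim.geo import GridTransform, RegionMask
from bryoclim.project import BinaryRange

from conftest import single_region_mask


class TestPctRemaining:
    @pytest.mark.parametrize(
        "pres,fut,expected",
        [(2698, 1473, 54.6), (1768, 2644, 149.5), (64, 555, 867.2), (5073, 890, 17.5)],
    )
    def test_published_worked_examples(self, pres, fut, expected):
        assert pct_remaining(pres, fut) == expected

    def test_trivial_endpoints(self):
        assert pct_remaining(123, 123) == 100.0
        assert pct_remaining(123, 0) == 0.0

    def test_zero_present_is_not_applicable(self):
        assert pct_remaining(0, 10) is None

    @given(st.integers(1, 10000), st.integers(0, 10000), st.integers(1, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, pres, fut, k):
        assert pct_remaining(pres, fut) == pct_remaining(k * pres, k * fut)

    def test_half_up_rounding(self):
        # 100 * 1 / 16 = 6.25 -> 6.3 under half-up (banker's would give 6.2)
        assert pct_remaining(16, 1) == 6.3


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (0.0, Status.EXTINCT),
            (0.8, Status.NEAR_EXTINCT),
            (1.0, Status.SUB5),
            (4.9, Status.SUB5),
            (5.0, Status.ENDANGERED),
            (50.0, Status.ENDANGERED),
            (54.6, Status.VULNERABLE),
            (70.0, Status.VULNERABLE),
            (70.1, Status.BELOW_VU),
            (100.0, Status.BELOW_VU),
            (149.5, Status.EXPANDING),
        ],
    )
    def test_class_boundaries(self, pct, expected):
        assert classify_status(pct) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_status(-1.0)

    @given(st.floats(0, 200, allow_nan=False), st.floats(0, 200, allow_nan=False))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_step_function(self, a, b):
        """Lower remaining area never maps to a less severe class."""
        severity = [
            Status.EXPANDING, Status.BELOW_VU, Status.VULNERABLE,
            Status.ENDANGERED, Status.SUB5, Status.NEAR_EXTINCT, Status.EXTINCT,
        ]
        lo, hi = min(a, b), max(a, b)
        assert severity.index(classify_status(lo)) >= severity.index(classify_status(hi))


def _range(grid):
    return BinaryRange(grid=np.asarray(grid, dtype=bool), threshold=0.5)


class TestElevationShift:
    def test_identical_ranges_give_zero_t_and_unit_p(self):
        mask = single_region_mask((10, 10), archipelagos=2)
        rng = np.random.default_rng(0)
        elev = rng.uniform(0, 100, (10, 10))
        g = rng.random((10, 10)) > 0.5
        res = elevation_shift(_range(g), _range(g), elev, mask)
        assert res.t_stat == 0.0
        assert res.p_value == 1.0

    def test_constructed_uphill_shift_raises_every_island_mean(self):
        """Future range = present range shifted to strictly higher cells on a
        synthetic two-island elevation ramp."""
        mask = single_region_mask((10, 10), archipelagos=2)
        elev = np.tile(np.arange(10.0)[:, None] * 100, (1, 10))  # rises with row
        pres = np.zeros((10, 10), dtype=bool)
        fut = np.zeros((10, 10), dtype=bool)
        pres[1, :] = pres[6, :] = True     # low rows of each island band
        fut[3, :] = fut[9, :] = True       # higher rows (unequal per-island shifts)
        res = elevation_shift(_range(pres), _range(fut), elev, mask)
        assert (res.mean_future > res.mean_present).all()
        assert res.t_stat > 0

    def test_matches_closed_form_paired_t_on_hand_means(self):
        mask = single_region_mask((10, 10), archipelagos=5)
        elev = np.zeros((10, 10))
        pres = np.zeros((10, 10), dtype=bool)
        fut = np.zeros((10, 10), dtype=bool)
        pre_means = [100.0, 220.0, 150.0, 300.0, 80.0]
        fut_means = [180.0, 260.0, 270.0, 310.0, 200.0]
        for b in range(5):
            rows = slice(2 * b, 2 * b + 2)
            elev[2 * b, 0] = pre_means[b]
            pres[2 * b, 0] = True
            elev[2 * b, 1] = fut_means[b]
            fut[2 * b, 1] = True
        res = elevation_shift(_range(pres), _range(fut), elev, mask)
        d = np.array(fut_means) - np.array(pre_means)
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=len(d) - 1)
        assert res.t_stat == pytest.approx(t_expected, abs=1e-10)
        assert res.p_value == pytest.approx(p_expected, abs=1e-10)

    def test_islands_lost_from_future_are_dropped_from_pairing(self):
        mask = single_region_mask((10, 10), archipelagos=2)
        elev = np.full((10, 10), 50.0)
        pres = np.ones((10, 10), dtype=bool)
        fut = np.zeros((10, 10), dtype=bool)
        fut[0, 0] = True  # species survives only on island 1
        res = elevation_shift(_range(pres), _range(fut), elev, mask)
        assert res.t_stat is None and res.p_value is None
        assert res.n_dropped == 1


class TestArchipelagoComparison:
    def test_all_equal_values_give_null_result(self):
        res = compare_archipelagos({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0]})
        assert res.h_stat == 0.0
        assert res.p_value == 1.0

    def test_fully_separated_groups_match_rank_sum_oracle(self):
        groups = {"a": [1.0, 2, 3, 4, 5], "b": [6.0, 7, 8, 9, 10], "c": [11.0, 12, 13, 14, 15]}
        res = compare_archipelagos(groups)
        # brute-force H from the rank-sum formula (no ties here)
        n = 15
        rank_sums = {"a": 15, "b": 40, "c": 65}
        h = 12 / (n * (n + 1)) * sum(rs**2 / 5 for rs in rank_sums.values()) - 3 * (n + 1)
        assert res.h_stat == pytest.approx(h, abs=1e-10)

    def test_matches_brute_force_tie_corrected_h_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = {
                f"g{i}": np.round(rng.random(rng.integers(2, 8)), 1) for i in range(k)
            }
            pooled = np.concatenate(list(groups.values()))
            if np.all(pooled == pooled[0]):
                continue
            ranks = stats.rankdata(pooled)
            n = pooled.size
            h = 0.0
            start = 0
            for v in groups.values():
                rs = ranks[start : start + len(v)].sum()
                h += rs**2 / len(v)
                start += len(v)
            h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
            _, counts = np.unique(pooled, return_counts=True)
            h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
            res = compare_archipelagos({g: list(v) for g, v in groups.items()})
            assert res.h_stat == pytest.approx(h, abs=1e-10)

    def test_duplicated_identical_groups_have_null_pairwise_pvalues(self):
        vals = [12.0, 30.0, 55.0, 70.0]
        res = compare_archipelagos({"a": vals, "b": list(vals)})
        assert res.pairwise_p("a", "b") > 0.9

    def test_separated_groups_have_small_pairwise_pvalues(self):
        groups = {"a": [1.0, 2, 3, 4, 5, 6], "b": [20.0, 21, 22, 23, 24, 25]}
        res = compare_archipelagos(groups)
        assert res.pairwise_p("a", "b") < 0.05

    def test_empty_or_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            compare_archipelagos({"a": [1.0, 2.0], "b": []})
        with pytest.raises(ValueError):
            compare_archipelagos({"a": [1.0, 2.0], "b": [3.0]})


class TestPaCoverage:
    T = GridTransform(west=0.0, north=1.0, cell_size=0.1)

    def test_full_cover_gives_100(self):
        grid = np.ones((10, 10), dtype=bool)
        polys = [shapely_box(-1, -1, 2, 2)]
        assert pa_coverage(_range(grid), polys, self.T) == pytest.approx(100.0)

    def test_no_polygons_gives_zero(self):
        grid = np.ones((5, 5), dtype=bool)
        assert pa_coverage(_range(grid), [], self.T) == pytest.approx(0.0)

    def test_empty_range_not_applicable(self):
        assert pa_coverage(_range(np.zeros((5, 5))), [shapely_box(0, 0, 1, 1)], self.T) is None

    def test_five_percent_rule_matches_fine_rasterization_oracle(self):
        rng = np.random.default_rng(2)
        polys = [
            shapely_box(x, y, x + rng.uniform(0.05, 0.3), y + rng.uniform(0.05, 0.3))
            for x, y in rng.uniform(0, 0.8, size=(6, 2))
        ]
        grid = np.ones((10, 10), dtype=bool)
        got = protected_cell_mask(polys, self.T, (10, 10), overlap=0.05)
        from shapely.ops import unary_union
        from shapely.geometry import Point

        union = unary_union(polys)
        sub = 40
        for r in range(10):
            for c in range(10):
                w, s, e, n = self.T.cell_box(r, c)
                step = (e - w) / sub
                inside = sum(
                    union.contains(Point(w + (i + 0.5) * step, s + (j + 0.5) * step))
                    for i in range(sub)
                    for j in range(sub)
                )
                frac = inside / sub**2
                if abs(frac - 0.05) > 0.01:  # skip knife-edge cells
                    assert got[r, c] == (frac >= 0.05), (r, c, frac)

    def test_adding_polygons_never_decreases_coverage(self):
        rng = np.random.default_rng(3)
        grid = rng.random((10, 10)) > 0.4
        polys = [
            shapely_box(x, y, x + 0.15, y + 0.15) for x, y in rng.uniform(0, 0.8, size=(5, 2))
        ]
        prev = 0.0
        for k in range(1, 6):
            cov = pa_coverage(_range(grid), polys[:k], self.T)
            assert cov >= prev - 1e-12
            prev = cov


class TestTabulate:
    def make_reports(self):
        return [
            RangeChangeReport("sp1", "islands", "rcp85", 100, 0),
            RangeChangeReport("sp2", "islands", "rcp85", 200, 3),
            RangeChangeReport("sp3", "islands", "rcp85", 100, 60),
            RangeChangeReport("sp1", "continent", "rcp85", 40, 10),
            RangeChangeReport("sp2", "continent", "rcp85", 0, 0),
        ]

    def test_summary_counts_zero_future_rows(self):
        df, summary = tabulate(self.make_reports())
        assert summary["rcp85"]["n_extinct"] == 1
        assert summary["rcp85"]["n_below_5pct"] == 1
        assert summary["n_with_continental_present"] == 1

    def test_csv_round_trip(self, tmp_path):
        df, _ = tabulate(self.make_reports())
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back[["species", "n_present", "n_future", "pct_remaining"]],
            df[["species", "n_present", "n_future", "pct_remaining"]],
        )

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError):
            tabulate([])


def test_summarize_pixel_table_counts():
    table = pd.DataFrame(
        {
            "species": ["a", "b", "c", "d"],
            "n_mac_present": [100, 100, 100, 100],
            "n_cont_present": [10, 0, 5, 0],
            "n_mac_rcp45": [50, 60, 70, 80],
            "n_cont_rcp45": [0, 0, 3, 0],
            "n_mac_rcp85": [0, 4, 20, 0],
            "n_cont_rcp85": [0, 0, 0, 0],
        }
    )
    s = summarize_pixel_table(table)
    assert s["n_extinct_mac_rcp85"] == 2
    assert s["n_below_5pct_mac_rcp85"] == 1
    assert s["n_with_continental_present"] == 2
    assert s["n_losing_continental_rcp45"] == 1
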