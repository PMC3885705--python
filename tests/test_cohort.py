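"""Sample summaries, group comparisons, shrinkage and rejection accounting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ctcmorph.cohort import (RejectionReport, average_median, compare_groups,
                             compare_groups_both, rank_correlation,
                             rejection_report, shrinkage_analysis,
                             summarize_all, summarize_sample)
from ctcmorph.errors import CtcMorphError


def _frame(diameters, sample_id="S1", group="ctc", status=None, reasons=None,
           nuc=None, timepoint=None):
    n = len(diameters)
    return pd.DataFrame({
        "tile_id": [f"{sample_id}_{i}" for i in range(n)],
        "sample_id": sample_id, "group": group,
        "a_cell_px": 300, "a_nuc_px": 150,
        "diameter_um": diameters,
        "nuc_diameter_um": nuc if nuc is not None else [d * 0.7 for d in diameters],
        "nc_ratio": 1.0, "ef": 1.2,
        "qc_status": status if status is not None else ["accepted"] * n,
        "qc_reason": reasons if reasons is not None else ["none"] * n,
        "timepoint_h": timepoint,
    })


class TestSummaries:
    def test_type7_quartiles(self):
        s = summarize_sample(_frame([6, 7, 8, 9, 10]))
        d = s.stats["diameter_um"]
        assert d["median"] == pytest.approx(8.0)
        # linear interpolation between order statistics (numpy default)
        assert d["q1"] == pytest.approx(7.0)
        assert d["q3"] == pytest.approx(9.0)

    def test_single_record_degenerate(self):
        s = summarize_sample(_frame([7.5]))
        d = s.stats["diameter_um"]
        assert d["median"] == d["q1"] == d["q3"] == pytest.approx(7.5)
        assert s.n_cells == 1

    def test_rejected_cells_excluded(self):
        df = _frame([6, 7, 8, 9, 100],
                    status=["accepted"] * 4 + ["rejected"],
                    reasons=["none"] * 4 + ["border_touch"])
        s = summarize_sample(df)
        assert s.n_cells == 4
        assert s.stats["diameter_um"]["median"] == pytest.approx(7.5)

    def test_all_rejected_sample_omitted_with_warning(self):
        df = _frame([6, 7], status=["rejected"] * 2,
                    reasons=["empty"] * 2)
        with pytest.warns(UserWarning, match="no accepted"):
            assert summarize_sample(df) is None

    def test_permutation_invariance(self, rng):
        vals = rng.normal(8, 2, 31)
        df = _frame(vals)
        shuffled = df.sample(frac=1.0, random_state=4)
        a = summarize_sample(df).stats["diameter_um"]
        b = summarize_sample(shuffled).stats["diameter_um"]
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12)

    def test_summarize_all_groups_by_sample(self):
        df = pd.concat([_frame([6, 7, 8], "S1"), _frame([10, 11], "S2")])
        out = summarize_all(df)
        assert len(out) == 2
        assert set(out["sample_id"]) == {"S1", "S2"}

    def test_average_median_unweighted(self):
        df = pd.concat([_frame([1, 1, 1], "S1"), _frame([3], "S2")])
        # per-sample medians 1 and 3, unweighted mean 2 (not the pooled 1)
        assert average_median(df, "diameter_um") == pytest.approx(2.0)


class TestCompareGroups:
    def test_identical_samples_rank_sum_p_is_one(self):
        gc = compare_groups([1, 2, 3], [1, 2, 3], "ef", "mann_whitney")
        assert gc.p_value == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        gc = compare_groups([1, 2, 3], [4, 5, 6], "ef", "mann_whitney")
        assert gc.statistic == pytest.approx(0.0)  # U = 0
        # oracle: 2 of C(6,3)=20 equally likely rank assignments are as extreme
        assert gc.p_value == pytest.approx(0.1)

    def test_welch_on_study_group_parameters(self):
        g = np.random.default_rng(42)
        a = g.normal(7.97, 1.81, 100)
        b = g.normal(13.38, 2.54, 100)
        gc = compare_groups(a, b, "diameter_um", "welch_t")
        assert gc.p_value < 1e-3
        # independent reference implementation
        from statsmodels.stats.weightstats import ttest_ind
        _, p_ref, _ = ttest_ind(a, b, usevar="unequal")
        assert gc.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_rank_sum_matches_exact_permutation_oracle_small_n(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 6)
        gc = compare_groups(a, b, "ef", "mann_whitney")
        # oracle: enumerate all C(11,5) assignments of pooled values
        pooled = np.concatenate([a, b])
        n_a = len(a)

        def u_stat(idx_a):
            av = pooled[list(idx_a)]
            bv = pooled[[i for i in range(len(pooled)) if i not in idx_a]]
            return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

        observed = u_stat(tuple(range(n_a)))
        total, extreme = 0, 0
        m = n_a * (len(pooled) - n_a)
        for comb in itertools.combinations(range(len(pooled)), n_a):
            u = u_stat(comb)
            total += 1
            if abs(u - m / 2) >= abs(observed - m / 2) - 1e-12:
                extreme += 1
        assert gc.p_value == pytest.approx(extreme / total, abs=1e-9)

    def test_both_methods_reported(self):
        rows = compare_groups_both([1.0, 2, 3, 4], [2.0, 3, 4, 5], "nc_ratio")
        assert [r.method for r in rows] == ["welch_t", "mann_whitney"]

    def test_small_groups_rejected(self):
        with pytest.raises(CtcMorphError):
            compare_groups([1.0], [2.0, 3.0], "ef")


class TestShrinkage:
    def test_six_percent_decrease(self):
        t0 = _frame([100.0] * 4, timepoint=0.0)
        t48 = _frame([94.0] * 4, timepoint=48.0)
        pct = shrinkage_analysis(t0, t48)
        assert pct["cell_diameter_pct"] == pytest.approx(-6.0)

    def test_no_change_is_zero(self):
        t0 = _frame([10.0, 12.0])
        pct = shrinkage_analysis(t0, t0)
        assert pct["cell_diameter_pct"] == pytest.approx(0.0)
        assert pct["nuclear_diameter_pct"] == pytest.approx(0.0)

    def test_ten_percent_nuclear_decrease(self):
        t0 = _frame([12.0] * 3, nuc=[10.0] * 3)
        t48 = _frame([12.0] * 3, nuc=[9.0] * 3)
        assert shrinkage_analysis(t0, t48)["nuclear_diameter_pct"] == \
            pytest.approx(-10.0)

    def test_empty_group_errors(self):
        t0 = _frame([10.0, 11.0])
        empty = _frame([5.0], status=["rejected"], reasons=["empty"])
        with pytest.raises(CtcMorphError):
            shrinkage_analysis(t0, empty)


class TestRejectionReport:
    def test_study_scale_accounting(self):
        n_rej = 209
        statuses = ["rejected"] * n_rej + ["accepted"] * (732 - n_rej)
        reasons = (["border_touch"] * 100 + ["multi_particle"] * 60
                   + ["empty"] * 40 + ["nuclear_gt_95pct"] * 9
                   + ["none"] * (732 - n_rej))
        df = _frame([8.0] * 732, status=statuses, reasons=reasons)
        rep = rejection_report(df)
        assert rep.n_total == 732 and rep.n_rejected == 209
        assert rep.fraction_rejected == pytest.approx(209 / 732)
        # exact fraction 0.28552 displays as 28.6% at one decimal
        assert rep.display_percent() == "28.6%"
        assert sum(rep.counts_per_reason.values()) == 209

    def test_none_rejected(self):
        rep = rejection_report(_frame([8.0] * 10))
        assert rep.n_rejected == 0
        assert rep.display_percent() == "0.0%"

    def test_all_rejected_counts_sum(self):
        df = _frame([8.0] * 6, status=["rejected"] * 6,
                    reasons=["empty", "empty", "border_touch", "multi_particle",
                             "multi_particle", "nuclear_gt_95pct"])
        rep = rejection_report(df)
        assert rep.fraction_rejected == pytest.approx(1.0)
        assert rep.counts_per_reason["multi_particle"] == 2
        assert sum(rep.counts_per_reason.values()) == rep.n_rejected

    def test_json_roundtrip(self, tmp_path):
        import json
        rep = RejectionReport(n_total=10, n_rejected=3,
                              counts_per_reason={"empty": 3})
        payload = json.loads(rep.to_json(tmp_path / "r.json"))
        assert payload["fraction_rejected"] == pytest.approx(0.3)


def test_rank_correlation_utility():
    rho, p = rank_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert rho == pytest.approx(1.0)


def test_quartile_and_box_plots_render(tmp_path):
    import pandas as pd
    from ctcmorph.plots import group_boxplot, per_sample_quartile_plot
    df = pd.concat([_frame([6.0, 7, 8, 9], "S1", "ctc"),
                    _frame([11.0, 12, 13], "S2", "cultured")])
    p1 = per_sample_quartile_plot(df, "diameter_um", tmp_path / "q.png")
    p2 = group_boxplot(df, "ef", tmp_path / "b.png")
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
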