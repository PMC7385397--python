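import numpy as np
import pandas as pd
import pytest

from droughtsel import selection as sel


def plot_rows(entries):
    """entries: (genotype, trial, treatment, tuber_number)"""
    return pd.DataFrame(entries, columns=["genotype_id", "trial_id",
                                          "treatment", "tuber_number"])


class TestFilterEligibility:
    def test_threshold_is_strict_below_five(self):
        plots = plot_rows([
            ("g1", "T1", "control", 4.9), ("g2", "T1", "control", 5.0),
        ])
        out = sel.filter_eligibility(plots, ["T1"]).set_index("genotype_id")
        assert not out.loc["g1", "eligible"]
        assert out.loc["g1", "exclusion_reason"] == "low tuber production"
        assert out.loc["g2", "eligible"]

    def test_no_control_records_excluded_with_distinct_reason(self):
        plots = plot_rows([("g1", "T1", "stress", 8)])
        out = sel.filter_eligibility(plots, ["T1"]).set_index("genotype_id")
        assert out.loc["g1", "exclusion_reason"] == "no control records"

    def test_delayed_emergence_flag(self):
        plots = plot_rows([("g1", "T1", "control", 10)])
        out = sel.filter_eligibility(plots, ["T1"],
                                     delayed_emergence={"g1"})
        assert out["exclusion_reason"].iloc[0] == "delayed emergence"

    def test_low_count_in_any_scoring_trial_excludes(self):
        plots = plot_rows([("g1", "T1", "control", 10),
                           ("g1", "T2", "control", 3)])
        out = sel.filter_eligibility(plots, ["T1", "T2"])
        assert not out["eligible"].iloc[0]


class TestFlagYieldOutliers:
    def _norm(self, values):
        return pd.DataFrame({"trial_id": "T1", "treatment": "control",
                             "sy_norm": values})

    def test_constant_stratum_has_no_flags(self):
        flags = sel.flag_yield_outliers(self._norm([5.0] * 10))
        assert not flags.any()

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        values = list(rng.normal(0, 1, 100)) + [10.0]
        flags = sel.flag_yield_outliers(self._norm(values))
        assert flags.iloc[-1]
        assert flags.sum() == 1

    def test_boundary_value_not_flagged(self):
        # 17 zeros plus +/-a: mean 0, sd = a/3, so +/-a sit exactly at
        # mean +/- 3 sd -- strictly outside is required, so no flags
        values = [0.0] * 17 + [3.0, -3.0]
        flags = sel.flag_yield_outliers(self._norm(values))
        assert not flags.any()

    def test_small_stratum_gets_no_flags(self):
        flags = sel.flag_yield_outliers(self._norm([1.0, 100.0]))
        assert not flags.any()


def _norm_for_selection(drym_by_trial, n_reps=2):
    """Build normalized records whose genotype-level relSY per trial equals
    0.5 + the requested DRYM offsets (control mean 100)."""
    rows = []
    for trial, mapping in drym_by_trial.items():
        for gid, rel in mapping.items():
            for r in range(n_reps):
                rows.append((gid, trial, "control", r + 1, 100.0))
                rows.append((gid, trial, "stress", r + 1, 100.0 * rel))
    return pd.DataFrame(rows, columns=["genotype_id", "trial_id", "treatment",
                                       "replicate", "sy_norm"])


class TestPhenotypicSelect:
    def test_shortlist_requires_top_depth_in_min_trials(self):
        genos = {f"g{i}": 0.9 - 0.01 * i for i in range(10)}
        # g9 is best in T1 only; g0..g8 consistent across both trials
        t2 = dict(genos)
        t2["g9"] = 0.05
        t1 = dict(genos)
        t1["g9"] = 2.0
        norm = _norm_for_selection({"T1": t1, "T2": t2})
        ppt, detail = sel.phenotypic_select(norm, genos.keys(),
                                            shortlist_depth=5, min_trials=2,
                                            k=3)
        assert "g9" not in ppt
        assert ppt == ["g0", "g1", "g2"]

    def test_single_trial_rank_insufficient(self):
        t1 = {f"g{i}": 0.5 for i in range(6)}
        t1["gX"] = 0.9
        t2 = {f"g{i}": 0.5 for i in range(6)}
        t2["gX"] = 0.1  # bottom in second trial
        norm = _norm_for_selection({"T1": t1, "T2": t2})
        ppt, _ = sel.phenotypic_select(norm, t1.keys(), shortlist_depth=1,
                                       min_trials=2, k=2)
        assert "gX" not in ppt

    def test_outlier_driven_qualification_removed(self):
        """A genotype whose top rank rests on one aberrantly low control
        replicate is dropped when ranks are recomputed without it."""
        base = {f"g{i}": 0.50 + 0.002 * i for i in range(30)}
        norm = _norm_for_selection({"T1": base, "T2": base}, n_reps=3)
        # gX: ordinary yields except one control replicate near zero,
        # inflating relSY in both trials
        rows = []
        for trial in ("T1", "T2"):
            rows += [("gX", trial, "control", 1, 1.0),
                     ("gX", trial, "control", 2, 100.0),
                     ("gX", trial, "control", 3, 100.0),
                     ("gX", trial, "stress", 1, 55.0),
                     ("gX", trial, "stress", 2, 55.0),
                     ("gX", trial, "stress", 3, 55.0)]
        extra = pd.DataFrame(rows, columns=norm.columns)
        norm = pd.concat([norm, extra], ignore_index=True)
        flags = pd.Series(False, index=norm.index)
        low_control = ((norm["genotype_id"] == "gX")
                       & (norm["treatment"] == "control")
                       & (norm["sy_norm"] == 1.0))
        flags[low_control] = True
        eligible = set(base) | {"gX"}
        ppt, detail = sel.phenotypic_select(norm, eligible, shortlist_depth=5,
                                            min_trials=2, k=5,
                                            outlier_flags=flags)
        assert "gX" not in ppt
        assert detail.loc[detail["genotype_id"] == "gX",
                          "outlier_removed"].iloc[0]

    def test_shortlist_monotone_in_depth(self):
        rng = np.random.default_rng(1)
        genos = {f"g{i}": float(0.4 + 0.4 * rng.random()) for i in range(40)}
        norm = _norm_for_selection({"T1": genos, "T2": genos})
        sizes = []
        for depth in (5, 10, 20):
            _, detail = sel.phenotypic_select(norm, genos.keys(),
                                              shortlist_depth=depth, k=5)
            sizes.append(int(detail["shortlisted"].sum()))
        assert sizes == sorted(sizes)


class TestMarkerSelect:
    def _combined(self, scores, preds=None):
        genos = list(scores.keys())
        return pd.DataFrame({
            "genotype_id": genos,
            "combined_score": [scores[g] for g in genos],
            "mean_predicted_drym": [preds[g] for g in genos] if preds
            else [-scores[g] for g in genos]})

    def test_best_and_worst_selected_disjoint(self):
        mpt, mps = sel.marker_select(
            self._combined({"a": 1, "b": 2, "c": 3, "d": 4}),
            k_tolerant=1, k_sensitive=1)
        assert mpt == ["a"]
        assert mps == ["d"]

    def test_oversized_selection_rejected(self):
        with pytest.raises(sel.SelectionError):
            sel.marker_select(self._combined({"a": 1, "b": 2}),
                              k_tolerant=2, k_sensitive=1)

    def test_all_tied_scores_resolved_deterministically(self):
        combined = self._combined({g: 1.0 for g in "abcdef"},
                                  preds={g: 0.0 for g in "abcdef"})
        mpt1, mps1 = sel.marker_select(combined, 2, 2)
        mpt2, mps2 = sel.marker_select(combined.sample(frac=1, random_state=3),
                                       2, 2)
        assert mpt1 == mpt2 == ["a", "b"]
        assert mps1 == mps2 == ["f", "e"]
        assert not set(mpt1) & set(mps1)


class TestVennSummary:
    def test_reported_bookkeeping(self):
        ppt = [f"p{i}" for i in range(15)] + [f"t{i}" for i in range(6)] \
            + [f"s{i}" for i in range(3)]
        mpt = [f"t{i}" for i in range(6)] + [f"mt{i}" for i in range(18)]
        mps = [f"s{i}" for i in range(3)] + [f"ms{i}" for i in range(19)]
        out = sel.venn_summary(ppt, mpt, mps)
        assert out["ppt_total"] == 24
        assert out["ppt_only"] == 15
        assert out["ppt_and_mpt"] == 6
        assert out["ppt_and_mps"] == 3
        assert out["mpt_and_mps"] == 0

    def test_overlapping_marker_populations_rejected_in_result(self):
        elig = pd.DataFrame({"genotype_id": list("abc"),
                             "eligible": True, "exclusion_reason": "none"})
        with pytest.raises(sel.SelectionError):
            sel.build_selection_result(["a"], ["b"], ["b"], elig)
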