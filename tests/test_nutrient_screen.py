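import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhckit import bjsq, mhc, nutrient_screen as ns
from mhckit.synthetic_data import (
    GeneratorConfig, generate_cohort, default_nutrient_effects,
    DEFAULT_PLANTED_NUTRIENTS,
)


def _exact_mw_p_oracle(a, b):
    """Brute-force two-sided p over all C(n+m, n) group labelings."""
    pooled = list(a) + list(b)
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y)
    m = len(b)
    mean_u = n * m / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples(self):
        a = [1, 2, 3, 4, 5]
        u, p = ns.mann_whitney(a, a)
        assert u == len(a) ** 2 / 2
        assert p > 0.9

    def test_complete_separation_exact(self):
        u, p = ns.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 labelings as extreme

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_agrees_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 7))
        b = rng.normal(1.0, size=rng.integers(3, 7))
        _, p = ns.mann_whitney(a, b)
        assert p == pytest.approx(_exact_mw_p_oracle(list(a), list(b)), abs=1e-10)

    def test_large_n_power(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            a = rng.normal(0.0, 1.0, 397)
            b = rng.normal(0.5, 1.0, 397)
            if ns.mann_whitney(a, b)[1] < 0.05:
                hits += 1
        assert hits >= 99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ns.mann_whitney([], [1.0])


@pytest.fixture(scope="module")
def ref_cells():
    return ns.reference_cells()


class TestFeasibleInterval:
    def test_potassium_reference(self, ref_cells):
        lo, hi, worse, better = ns.feasible_interval(ref_cells, "K_mg")
        assert (lo, hi) == (2441.6, 2507.0)

    def test_magnesium_reference(self, ref_cells):
        lo, hi, *_ = ns.feasible_interval(ref_cells, "Mg_mg")
        assert (lo, hi) == (265.8, 274.4)

    def test_vitamin_a_empty_interval(self, ref_cells):
        lo, hi, worse, better = ns.feasible_interval(ref_cells, "VA_ugRE")
        assert lo >= hi  # empty interval is a reportable state, not an error
        assert better["lack_of_vigor"] == 564.1
        assert worse["lack_of_vigor"] == 574.0

    def test_item_permutation_invariance_and_minmax_oracle(self, ref_cells):
        for nut in ("K_mg", "Fe_mg", "TDF_g"):
            shuffled = ref_cells.sample(frac=1.0, random_state=1)
            lo1, hi1, worse, better = ns.feasible_interval(ref_cells, nut)
            lo2, hi2, *_ = ns.feasible_interval(shuffled, nut)
            assert (lo1, hi1) == (lo2, hi2)
            assert lo1 == max(worse.values()) and hi1 == min(better.values())

    def test_missing_item_rejected(self, ref_cells):
        partial = ref_cells[ref_cells["mhc_item"] != "fatigue"]
        with pytest.raises(bjsq.ValidationError):
            ns.feasible_interval(partial, "K_mg")


class TestDeriveCutoff:
    def test_potassium_default_rule(self):
        assert ns.derive_cutoff(2441.6, 2507.0) == 2500.0

    def test_fiber_default_rule(self):
        assert ns.derive_cutoff(18.06, 18.69) == 18.0

    def test_folic_acid_default_rule(self, ref_cells):
        lo, hi, *_ = ns.feasible_interval(ref_cells, "FA_ug")
        assert ns.derive_cutoff(lo, hi) == 300.0

    def test_midpoint_inside_degenerate_interval(self):
        lo, hi = 5.000, 5.004
        mid = (lo + hi) / 2
        assert lo < mid < hi
        assert ns.derive_cutoff(lo, hi, rule=lambda a, b: (a + b) / 2) == mid

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="override"):
            ns.derive_cutoff(10.0, 9.0)

    def test_round_2sf(self):
        assert ns.round_2sf(2474.3) == 2500.0
        assert ns.round_2sf(18.375) == 18.0
        assert ns.round_2sf(303.15) == 300.0
        assert ns.round_2sf(0.0) == 0.0


class TestValidateCutoff:
    def test_potassium_no_violations(self, ref_cells):
        _, _, worse, better = ns.feasible_interval(ref_cells, "K_mg")
        assert ns.validate_cutoff(2500.0, worse, better) == []

    def test_iron_printed_cutoff_inconsistent(self, ref_cells):
        # Fe printed cut-off 8.1 fails: somatic worse-status mean is 8.16
        _, _, worse, better = ns.feasible_interval(ref_cells, "Fe_mg")
        violations = ns.validate_cutoff(8.1, worse, better)
        assert ("somatic", "worse_mean_at_or_above_cutoff") in violations

    def test_cutoff_below_all_means(self, ref_cells):
        _, _, worse, better = ns.feasible_interval(ref_cells, "K_mg")
        violations = ns.validate_cutoff(1000.0, worse, better)
        lower = [v for v in violations if v[1] == "worse_mean_at_or_above_cutoff"]
        upper = [v for v in violations if v[1] == "better_mean_at_or_below_cutoff"]
        assert len(lower) == 4 and len(upper) == 0


class TestScreen:
    def test_default_cohort_selects_planted_17(self, analyzed):
        res = ns.screen(analyzed["intakes"], analyzed["split"].labels)
        assert sorted(res.selected) == sorted(DEFAULT_PLANTED_NUTRIENTS)
        assert len(res.selected) == 17
        assert res.n_tests == 156

    def test_null_effects_select_nothing_usually(self):
        selected_counts = []
        for seed in range(20):
            cohort = generate_cohort(GeneratorConfig(
                n_subjects=400, seed=seed, n_non_worker=0, n_high_stress=0,
                nutrient_effects=default_nutrient_effects(0.0)))
            split = mhc.median_split(mhc.score_mhc(cohort.responses))
            res = ns.screen(cohort.intakes, split.labels)
            selected_counts.append(len(res.selected))
        assert sum(1 for c in selected_counts if c == 0) >= 0.7 * len(selected_counts)
        assert np.mean(selected_counts) < 1.0

    def test_alpha_one_selects_everything(self, analyzed):
        res = ns.screen(analyzed["intakes"], analyzed["split"].labels, alpha=1.0)
        assert len(res.selected) == 39

    def test_selection_monotone_in_alpha(self, analyzed):
        prev = set()
        for alpha in (0.01, 0.05, 0.2, 1.0):
            res = ns.screen(analyzed["intakes"], analyzed["split"].labels, alpha=alpha)
            assert prev <= set(res.selected)
            prev = set(res.selected)

    def test_energy_reported_but_never_selected(self, analyzed):
        intakes = analyzed["intakes"].copy()
        # energy proportional to a planted nutrient: clearly significant
        intakes[ns.ENERGY_COLUMN] = intakes["K_mg"] * 0.8
        res = ns.screen(intakes, analyzed["split"].labels)
        cells = res.cells[res.cells["nutrient"] == ns.ENERGY_COLUMN]
        assert len(cells) == 4
        assert cells["significant"].sum() >= 3
        assert ns.ENERGY_COLUMN not in res.selected

    def test_missing_nutrient_column(self, analyzed):
        with pytest.raises(bjsq.ValidationError, match="K_mg"):
            ns.screen(analyzed["intakes"].drop(columns=["K_mg"]),
                      analyzed["split"].labels)

    def test_type_one_calibration_under_null(self):
        # cell-level rejection rate across null nutrients is ~5%
        rejections = []
        for seed in range(10):
            cohort = generate_cohort(GeneratorConfig(
                n_subjects=500, seed=100 + seed, n_non_worker=0,
                n_high_stress=0, nutrient_effects=default_nutrient_effects(0.0)))
            split = mhc.median_split(mhc.score_mhc(cohort.responses))
            res = ns.screen(cohort.intakes, split.labels)
            rejections.append(res.cells["significant"].mean())
        rate = float(np.mean(rejections))
        assert 0.02 <= rate <= 0.08


class TestCountGroups:
    def test_bins_exact(self):
        expected = {0: "0N", 1: "1-4N", 4: "1-4N", 5: "5-8N", 8: "5-8N",
                    9: "9-12N", 12: "9-12N", 13: "13-17N", 17: "13-17N"}
        for count, label in expected.items():
            assert ns.count_group_label(count) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ns.count_group_label(18)

    @given(st.integers(0, 17))
    @settings(max_examples=18, deadline=None)
    def test_label_pure_function_of_count(self, count):
        assert ns.count_group_label(count) == ns.count_group_label(count)


def _cutoff_entry(nutrient, cutoff):
    return ns.CutoffEntry(nutrient=nutrient, worse_means={}, better_means={},
                          lo=0.0, hi=1.0, cutoff=cutoff)


class TestStratifyAndCompare:
    def _tiny(self):
        intakes = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "K_mg": [2500.0, 2400.0, 2600.0],
            "Mg_mg": [270.0, 100.0, 400.0],
        })
        scores = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "lack_of_vigor": [6, 7, 8], "irritability": [6, 7, 8],
            "fatigue": [6, 7, 8], "somatic": [15, 16, 17],
        })
        return intakes, scores

    def test_at_cutoff_counts_as_above(self):
        intakes, scores = self._tiny()
        cutoffs = [_cutoff_entry("K_mg", 2500.0), _cutoff_entry("Mg_mg", 270.0)]
        groups, _, _ = ns.stratify_and_compare(intakes, cutoffs, scores)
        counts = dict(zip(groups["subject_id"], groups["count"]))
        assert counts == {"a": 2, "b": 0, "c": 2}  # exact-cutoff subject counted

    def test_all_below_cutoffs_single_0n_group(self):
        intakes, scores = self._tiny()
        cutoffs = [_cutoff_entry("K_mg", 99999.0)]
        groups, summary, warnings = ns.stratify_and_compare(intakes, cutoffs, scores)
        assert (groups["group"] == "0N").all()
        assert summary.loc[summary["group"] != "0N", "n"].sum() == 0

    def test_count_is_indicator_sum(self, analyzed):
        res = ns.screen(analyzed["intakes"], analyzed["split"].labels)
        entries = ns.derive_cutoffs(res)
        groups, _, _ = ns.stratify_and_compare(
            analyzed["intakes"], entries, analyzed["scores"])
        expected = np.zeros(len(analyzed["intakes"]), dtype=int)
        for e in entries:
            if e.cutoff is not None:
                expected += (
                    analyzed["intakes"][e.nutrient].to_numpy() >= e.cutoff
                ).astype(int)
        assert (groups["count"].to_numpy() == expected).all()
        assert [ns.count_group_label(c) for c in groups["count"]] == list(groups["group"])

    def test_monotone_planted_coupling_reproduces_group_trend(self):
        # vigor score mean non-decreasing across groups and the three
        # higher-count contrasts significant on a planted-coupling cohort
        cohort = generate_cohort(GeneratorConfig(seed=3))
        included, _ = bjsq.filter_population(cohort.subjects)
        responses = cohort.responses[
            cohort.responses["subject_id"].isin(included)].reset_index(drop=True)
        intakes = cohort.intakes[
            cohort.intakes["subject_id"].isin(included)].reset_index(drop=True)
        scores = mhc.score_mhc(responses)
        split = mhc.median_split(scores)
        res = ns.screen(intakes, split.labels)
        entries = ns.derive_cutoffs(res)
        _, summary, _ = ns.stratify_and_compare(intakes, entries, scores)
        vigor = summary[summary["mhc_item"] == "lack_of_vigor"].set_index("group")
        order = ["0N", "1-4N", "5-8N", "9-12N", "13-17N"]
        means = vigor.loc[order, "mean"].to_numpy()
        assert (np.diff(means) >= 0).all()
        for g in ("5-8N", "9-12N", "13-17N"):
            assert vigor.loc[g, "p_vs_0N"] < 0.05


class TestDeriveCutoffs:
    def test_reference_pipeline_with_overrides(self, ref_cells):
        screen_like = ns.ScreenResult(
            cells=ref_cells, selected=["K_mg", "Fe_mg", "VA_ugRE"],
            alpha=0.05, n_tests=68)
        entries = ns.derive_cutoffs(screen_like, overrides={"VA_ugRE": 570.0})
        by_name = {e.nutrient: e for e in entries}
        assert by_name["K_mg"].cutoff == 2500.0
        assert by_name["K_mg"].source == "derived"
        assert by_name["K_mg"].violations == []
        assert by_name["VA_ugRE"].source == "override"
        assert by_name["VA_ugRE"].violations  # override cannot fix the means
        assert not by_name["VA_ugRE"].feasible
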