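"""Calibration sets, subset combinatorics, RMSE pooling and the
within-subject ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trunkmoment.study import (CalibrationSet, CalibrationStudy, EvalOptions,
                               StudyConfig, StudyInputError, enumerate_subsets,
                               evaluate_calibration_set, full_set, is_selected,
                               quasi_static_set, rm_anova, selected_family,
                               task_group_rmse, worst_selected, bonferroni)
from trunkmoment.synthetic_data import calibration_conditions
from trunkmoment.trial_model import VELOCITY_ORDER, TrialCondition

CONDITIONS = calibration_conditions()


class TestSubsets:
    @pytest.mark.parametrize("n,count", [(1, 14), (2, 91), (3, 364), (14, 1)])
    def test_counts_match_binomial_coefficients(self, n, count):
        subsets = enumerate_subsets(CONDITIONS, n)
        assert len(subsets) == count == math.comb(14, n)
        assert len(set(subsets)) == count  # distinct, deterministic order

    def test_full_subset_equals_full_set(self):
        (only,) = enumerate_subsets(CONDITIONS, 14)
        assert {c.label for c in only} == set(full_set().conditions)

    @pytest.mark.parametrize("n", [0, 15])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(StudyInputError):
            enumerate_subsets(CONDITIONS, n)


class TestSelectedFamily:
    def test_member_and_non_member_examples(self):
        by_label = {c.label: c for c in CONDITIONS}
        member = [by_label["stoop-15-slow"], by_label["squat-7.5-slow"],
                  by_label["free-7.5-fast"]]
        assert is_selected(member, CONDITIONS)
        non_member = [by_label["stoop-15-normal"], by_label["squat-7.5-normal"],
                      by_label["free-7.5-normal"]]
        assert not is_selected(non_member, CONDITIONS)

    def test_family_equals_brute_force_filter(self):
        """Independent re-statement of the coverage rule applied to all 364
        subsets must reproduce the family exactly."""
        def brute_force_ok(subset):
            masses = sorted({c.mass_kg for c in subset})
            techs = {c.technique for c in subset}
            vels = [VELOCITY_ORDER[c.velocity] for c in subset]
            return (masses == [7.5, 15.0]
                    and "stoop" in techs and "squat" in techs
                    and min(vels) <= VELOCITY_ORDER["slow"]
                    and max(vels) == VELOCITY_ORDER["fast"])

        brute = {frozenset(c.label for c in s)
                 for s in itertools.combinations(CONDITIONS, 3)
                 if brute_force_ok(s)}
        family = selected_family(CONDITIONS)
        assert {frozenset(m.conditions) for m in family} == brute
        assert all(m.n == 3 for m in family)

    def test_quasi_static_set_is_the_two_very_slow_free_lifts(self):
        qs = quasi_static_set(CONDITIONS)
        assert qs.n == 2
        for label in qs.conditions:
            technique, _, velocity = label.split("-")
            assert technique == "free"
            assert velocity == "very_slow"


class TestWorstSelected:
    def _results(self, keys_and_rmses):
        rows = []
        for key, rmses in keys_and_rmses.items():
            for subject, r in enumerate(rmses):
                rows.append({"set_key": key, "model": "regmod",
                             "subject": f"S{subject}", "rmse": r})
                rows.append({"set_key": key, "model": "emgmod",
                             "subject": f"S{subject}", "rmse": 99.0})
        return pd.DataFrame(rows)

    def test_known_maximum_is_returned(self):
        table = self._results({"a": [1.0, 2.0], "b": [5.0, 6.0],
                               "c": [3.0, 3.0]})
        assert worst_selected(table) == "b"

    def test_single_member_family(self):
        assert worst_selected(self._results({"only": [2.0]})) == "only"

    def test_worst_mean_dominates_all_members(self):
        rng = np.random.default_rng(4)
        table = self._results(
            {f"k{i}": rng.uniform(1, 9, size=5).tolist() for i in range(6)})
        reg = table[table["model"] == "regmod"]
        means = reg.groupby("set_key")["rmse"].mean()
        assert means[worst_selected(table)] == means.max()


class TestTaskGroupRmse:
    def _row(self, rmse, n, group="exo_lift", subject="S1", label="full",
             model="regmod", trial="t"):
        return {"subject": subject, "set_label": label, "model": model,
                "task_group": group, "trial_id": trial,
                "sq_err": rmse**2 * n, "n_samples": n, "rmse": rmse}

    def test_single_trial_group_equals_trial_rmse(self):
        out = task_group_rmse(pd.DataFrame([self._row(4.2, 100)]))
        assert out["rmse"].iloc[0] == pytest.approx(4.2)

    def test_two_equal_length_trials_pool_in_quadrature(self):
        a, b = 3.0, 5.0
        out = task_group_rmse(pd.DataFrame([
            self._row(a, 200, trial="t1"), self._row(b, 200, trial="t2")]))
        assert out["rmse"].iloc[0] == pytest.approx(
            math.sqrt((a**2 + b**2) / 2))

    def test_constant_bias_gives_rmse_equal_to_bias(self):
        pred = np.full(50, 5.0)
        assert np.sqrt(np.mean(pred**2)) == pytest.approx(5.0)

    def test_unknown_task_group_rejected(self):
        with pytest.raises(StudyInputError, match="walking"):
            task_group_rmse(pd.DataFrame([self._row(1.0, 10,
                                                    group="walking")]))

    def test_battery_has_five_task_groups(self, noisy_subject):
        groups = {t.condition.task_group for t in noisy_subject.test_trials}
        assert len(groups) == 5


class TestRmAnova:
    #: 2 x 2 within-subject design, 3 subjects; sums of squares and F ratios
    #: computed by hand from cell/marginal means (and cross-checked against
    #: an independent library implementation).
    FIXTURE = {
        (1, "a1", "b1"): 10, (1, "a1", "b2"): 12,
        (1, "a2", "b1"): 14, (1, "a2", "b2"): 18,
        (2, "a1", "b1"): 11, (2, "a1", "b2"): 15,
        (2, "a2", "b1"): 17, (2, "a2", "b2"): 21,
        (3, "a1", "b1"): 9, (3, "a1", "b2"): 12,
        (3, "a2", "b1"): 12, (3, "a2", "b2"): 16,
    }

    def _table(self, values=None):
        values = values or self.FIXTURE
        return pd.DataFrame([
            {"subject": s, "task_group": a, "set_label": b, "rmse": v}
            for (s, a, b), v in values.items()])

    def test_hand_computed_sums_of_squares(self):
        res = rm_anova(self._table())
        table = res["anova"].set_index("effect")
        assert table.loc["task_group", "SS"] == pytest.approx(70.0833333333)
        assert table.loc["set_label", "SS"] == pytest.approx(36.75)
        assert table.loc["task_group*set_label", "SS"] == pytest.approx(0.75)
        assert table.loc["task_group", "F"] == pytest.approx(44.2631578947)
        assert table.loc["set_label", "F"] == pytest.approx(147.0)
        assert table.loc["task_group*set_label", "F"] == pytest.approx(3.0)
        assert table.loc["task_group", "p"] == pytest.approx(0.0218542768)
        assert table.loc["set_label", "p"] == pytest.approx(0.0067340833)

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        values = {(s, a, b): float(rng.uniform(5, 30))
                  for s in range(6) for a in ("g1", "g2", "g3")
                  for b in ("x", "y")}
        table = self._table(values)
        mine = rm_anova(table)["anova"].set_index("effect")
        theirs = pingouin.rm_anova(
            dv="rmse", within=["task_group", "set_label"], subject="subject",
            data=table, detailed=True).set_index("Source")
        for eff, src in (("task_group", "task_group"),
                         ("set_label", "set_label"),
                         ("task_group*set_label", "task_group * set_label")):
            assert mine.loc[eff, "F"] == pytest.approx(theirs.loc[src, "F"])
            assert mine.loc[eff, "p"] == pytest.approx(
                theirs.loc[src, "p_unc"])

    def test_all_equal_cells_give_zero_f(self):
        values = {k: 7.0 for k in self.FIXTURE}
        res = rm_anova(self._table(values))
        assert np.allclose(res["anova"]["F"], 0.0)

    def test_bonferroni_adjustment_definition(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 4) == 1.0
        res = rm_anova(self._table())
        for _, row in res["posthoc"]["task_group"].iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_raw"]))  # one pair: m == 1

    def test_unbalanced_design_lists_missing_cells(self):
        table = self._table().iloc[:-1]
        with pytest.raises(StudyInputError, match="missing cells"):
            rm_anova(table)


class TestCalibrationSetBinding:
    def test_full_set_selects_both_repetitions(self, noisy_subject):
        trials = full_set().select(noisy_subject.calibration_trials)
        assert len(trials) == 28

    def test_quasi_static_selects_four_trials(self, noisy_subject):
        trials = quasi_static_set().select(noisy_subject.calibration_trials)
        assert len(trials) == 4
        assert all(t.condition.velocity == "very_slow" for t in trials)

    def test_label_cardinality_validated(self):
        with pytest.raises(StudyInputError):
            CalibrationSet("full", ("stoop-7.5-slow",))
        with pytest.raises(StudyInputError):
            CalibrationSet("selected", ("stoop-7.5-slow",))


class TestPipeline:
    def test_noise_free_full_set_is_nearly_exact(self, noise_free_cache):
        """With exact EMG the calibrated model reproduces the reference
        moment on unseen test trials to well under a newton-metre."""
        df = evaluate_calibration_set(full_set(), noise_free_cache,
                                      EvalOptions(n_starts=1))
        emg = df[df["model"] == "emgmod"]
        assert (emg["rmse"] < 1.0).all()

    def test_study_run_is_deterministic(self):
        fast = EvalOptions(n_starts=0, maxiter=30, tol=1e-4,
                           svr_max_train=300, cal_stride=4, eval_stride=4)
        cfg = StudyConfig(n_subjects=2, seed=42, options=fast)
        a = CalibrationStudy(cfg).run()
        b = CalibrationStudy(cfg).run()
        pd.testing.assert_frame_equal(a.per_trial, b.per_trial)
        assert a.worst_selected_key == b.worst_selected_key
        assert set(a.per_trial["set_label"]) >= {"full", "quasi_static",
                                                 "selected", "worst_selected"}
        assert a.summary()  # renders

    def test_study_outputs_and_figures(self, tmp_path):
        from trunkmoment.study import run_study
        from trunkmoment import plotting

        fast = EvalOptions(n_starts=0, maxiter=30, tol=1e-4,
                           svr_max_train=300, cal_stride=4, eval_stride=4)
        cfg = StudyConfig(n_subjects=2, seed=43, options=fast)
        result = run_study(cfg, out_dir=tmp_path)
        assert (tmp_path / "per_trial_rmse.csv").exists()
        assert (tmp_path / "task_group_rmse.png").exists()
        assert (tmp_path / "report.md").exists()
        with pytest.raises(ValueError, match="sweep"):
            plotting.plot_rmse_vs_n(result)
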