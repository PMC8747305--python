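"""Calibration-set construction and the full evaluation study.

Builds the Full / Selected-family / Worst-selected / Quasi-static
calibration sets over the 14 lifting conditions, runs the three-model
pipeline (inverse dynamics -> EMG-driven model -> reduced-sensor SVR) for
each set, pools RMSEs per task group, and tests calibration-set and
task-group effects with a two-way within-subject ANOVA plus Bonferroni
post-hocs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .emgmod import EMGDrivenModel, MuscleGeometry, default_geometry
from .inverse_dynamics import human_moment_from_trial
from .regmod import MomentRegression, build_features
from .synthetic_data import (SubjectData, calibration_conditions,
                             generate_study)
from .trial_model import (MomentSeries, Trial, TrialCondition, VELOCITY_ORDER)

EVALUATED_SETS = ("full", "worst_selected", "quasi_static")
TEST_TASK_GROUPS = ("exo_lift", "stack_carry", "stack_lift", "shelf_lift",
                    "push_pull")


class StudyInputError(ValueError):
    pass


# -- calibration sets ----------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSet:
    """A labelled set of calibration-lift conditions.

    ``conditions`` are condition labels (``technique-mass-velocity``); both
    repetitions of each condition are included when the set is bound to a
    subject's trials.  ``n`` is the number of conditions.
    """

    label: str  # full | subset | selected | worst_selected | quasi_static
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label == "full" and len(self.conditions) != 14:
            raise StudyInputError("the Full set must contain all 14 conditions")
        if self.label in ("selected", "worst_selected") \
                and len(self.conditions) != 3:
            raise StudyInputError("Selected-family members contain 3 conditions")
        if self.label == "quasi_static" and len(self.conditions) != 2:
            raise StudyInputError("the Quasi-static set contains 2 conditions")

    @property
    def n(self) -> int:
        return len(self.conditions)

    def select(self, trials: list[Trial]) -> list[Trial]:
        """All repetitions of the member conditions, in manifest order."""
        wanted = set(self.conditions)
        out = [t for t in trials if t.condition.label in wanted]
        if not out:
            raise StudyInputError(
                f"no trials match calibration set {self.label!r}"
            )
        return out

    @property
    def key(self) -> str:
        return "|".join(sorted(self.conditions))


def full_set(conditions: list[TrialCondition] | None = None) -> CalibrationSet:
    conditions = conditions or calibration_conditions()
    return CalibrationSet("full", tuple(c.label for c in conditions))


def enumerate_subsets(conditions: list[TrialCondition], n: int
                      ) -> list[tuple[TrialCondition, ...]]:
    """All C(len(conditions), n) condition subsets, deterministic order."""
    if not 1 <= n <= len(conditions):
        raise StudyInputError(
            f"subset size {n} out of range 1..{len(conditions)}"
        )
    return list(itertools.combinations(conditions, n))


def is_selected(subset, conditions: list[TrialCondition]) -> bool:
    """Coverage criterion: both extreme masses, both distinct techniques
    (stoop and squat), and both velocity extremes — the slow extreme is any
    very-slow/slow trial; the fast extreme is the fastest class present in
    the whole battery."""
    masses = {c.mass_kg for c in conditions}
    max_rank = max(VELOCITY_ORDER[c.velocity] for c in conditions)
    sub_masses = {c.mass_kg for c in subset}
    sub_tech = {c.technique for c in subset}
    ranks = [VELOCITY_ORDER[c.velocity] for c in subset]
    return (
        {min(masses), max(masses)} <= sub_masses
        and {"stoop", "squat"} <= sub_tech
        and any(r <= VELOCITY_ORDER["slow"] for r in ranks)
        and any(r == max_rank for r in ranks)
    )


def selected_family(conditions: list[TrialCondition] | None = None,
                    n: int = 3) -> list[CalibrationSet]:
    """All n-condition sets covering the extremes of mass, technique and
    velocity, in deterministic enumeration order."""
    conditions = conditions or calibration_conditions()
    family = []
    for subset in enumerate_subsets(conditions, n):
        if is_selected(subset, conditions):
            family.append(CalibrationSet(
                "selected", tuple(c.label for c in subset)))
    return family


def quasi_static_set(conditions: list[TrialCondition] | None = None
                     ) -> CalibrationSet:
    """Free-technique very-slow lifts at both masses."""
    conditions = conditions or calibration_conditions()
    members = [c for c in conditions
               if c.technique == "free" and c.velocity == "very_slow"]
    if len(members) != 2:
        raise StudyInputError(
            "battery lacks the two free/very-slow conditions"
        )
    return CalibrationSet("quasi_static", tuple(c.label for c in members))


# -- pipeline evaluation -------------------------------------------------------

@dataclass
class EvalOptions:
    """Numerical knobs of one pipeline evaluation."""

    n_starts: int = 2          # EMGMod calibration multi-starts (plus midpoint)
    maxiter: int = 120         # calibration function-evaluation cap
    tol: float = 1e-8          # calibration convergence tolerance
    seed: int = 0
    svr_max_train: int = 2000  # SVR training-row cap (uniform decimation)
    cal_stride: int = 1        # calibration-sample stride for EMGMod fitting
    eval_stride: int = 1       # test-sample stride for RMSE evaluation


@dataclass
class SubjectCache:
    """Per-subject quantities shared by every calibration-set evaluation."""

    data: SubjectData
    references: dict            # trial_id -> human MomentSeries (bottom-up ID)
    test_features: dict         # trial_id -> (n, 9) matrix
    geometry: MuscleGeometry


def prepare_subject(data: SubjectData,
                    geometry: MuscleGeometry | None = None) -> SubjectCache:
    """Run inverse dynamics on every trial and cache test features."""
    geometry = geometry if geometry is not None else default_geometry()
    references = {}
    for trial in data.calibration_trials + data.test_trials:
        references[trial.trial_id] = human_moment_from_trial(
            trial, data.subject)
    test_features = {t.trial_id: build_features(t) for t in data.test_trials}
    return SubjectCache(data=data, references=references,
                        test_features=test_features, geometry=geometry)


def evaluate_calibration_set(calset: CalibrationSet, cache: SubjectCache,
                             options: EvalOptions | None = None) -> pd.DataFrame:
    """Run the calibrate-train-predict pipeline for one calibration set.

    Returns one row per test trial and model with the squared-error sum,
    sample count and RMSE of the human-moment prediction against the
    inverse-dynamics reference.
    """
    options = options or EvalOptions()
    cal_trials = calset.select(cache.data.calibration_trials)
    cal_refs = [cache.references[t.trial_id] for t in cal_trials]
    emg_res = EMGDrivenModel(cal_trials, cal_refs, cache.geometry,
                             stride=options.cal_stride).fit(
        n_starts=options.n_starts, seed=options.seed, maxiter=options.maxiter,
        tol=options.tol)
    responses = [emg_res.active_series(t) for t in cal_trials]
    reg_res = MomentRegression.from_trials(cal_trials, responses).fit(
        compute_cv=False, max_train_samples=options.svr_max_train)
    rows = []
    stride = max(1, options.eval_stride)
    for trial in cache.data.test_trials:
        ref = cache.references[trial.trial_id].values_nm[::stride]
        emg_pred = emg_res.predict(trial).values_nm[::stride]
        passive = emg_res.passive_series(trial).values_nm[::stride]
        reg_active = reg_res.predict(cache.test_features[trial.trial_id][::stride])
        for model, pred in (("emgmod", emg_pred), ("regmod", reg_active + passive)):
            err = pred - ref
            sq = float(np.dot(err, err))
            rows.append({
                "subject": cache.data.subject.subject_id,
                "set_label": calset.label,
                "set_key": calset.key,
                "trial_id": trial.trial_id,
                "task_group": trial.condition.task_group,
                "model": model,
                "sq_err": sq,
                "n_samples": err.size,
                "rmse": float(np.sqrt(sq / err.size)),
            })
    return pd.DataFrame(rows)


def worst_selected(family_results: pd.DataFrame) -> str:
    """Family member key with the largest across-subject mean RegMod RMSE
    over all test trials; ties broken lexicographically by key."""
    reg = family_results[family_results["model"] == "regmod"]
    if reg.empty:
        raise StudyInputError("no RegMod results for the Selected family")
    means = (reg.groupby("set_key")["rmse"].mean()
             .sort_index())
    worst = means[means == means.max()].index.min()
    return str(worst)


def task_group_rmse(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Pool per-trial errors within subject x set x model x task group.

    Pooled RMSE is the root of the pooled mean squared error over all
    concatenated samples of the group.
    """
    unknown = set(per_trial["task_group"]) - set(TEST_TASK_GROUPS)
    if unknown:
        raise StudyInputError(f"unknown task group(s): {sorted(unknown)}")
    grouped = per_trial.groupby(
        ["subject", "set_label", "model", "task_group"], as_index=False
    ).agg(sq_err=("sq_err", "sum"), n_samples=("n_samples", "sum"))
    grouped["rmse"] = np.sqrt(grouped["sq_err"] / grouped["n_samples"])
    return grouped.drop(columns=["sq_err", "n_samples"])


# -- repeated-measures ANOVA ---------------------------------------------------

def rm_anova(table: pd.DataFrame, dv: str = "rmse",
             within: tuple[str, str] = ("task_group", "set_label"),
             subject: str = "subject", alpha: float = 0.05) -> dict:
    """Two-way within-subject ANOVA from the sums-of-squares decomposition.

    Each effect is tested against its interaction with subjects (no
    sphericity correction).  Bonferroni pairwise comparisons (paired
    t-tests, adjusted p = min(1, m * p)) are reported per factor.
    """
    fa, fb = within
    pivot = table.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if pivot.isna().any().any():
        missing = pivot.columns[pivot.isna().any()].tolist()
        raise StudyInputError(f"unbalanced design; missing cells: {missing}")
    a_levels = sorted({c[0] for c in pivot.columns})
    b_levels = sorted({c[1] for c in pivot.columns})
    subjects = pivot.index.tolist()
    a, b, s = len(a_levels), len(b_levels), len(subjects)
    order = [a_levels.index(c[0]) * b + b_levels.index(c[1])
             for c in pivot.columns]
    y = pivot.to_numpy()[:, np.argsort(order)].reshape(s, a, b)

    grand = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_s - ss_ab - ss_as - ss_bs

    def effect(name, ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        return {"effect": name, "SS": float(ss_eff), "df": int(df_eff),
                "MS": float(ms_eff), "F": float(f), "p": p,
                "SS_error": float(ss_err), "df_error": int(df_err)}

    anova = [
        effect(fa, ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        effect(fb, ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        effect(f"{fa}*{fb}", ss_ab, (a - 1) * (b - 1), ss_abs,
               (a - 1) * (b - 1) * (s - 1)),
    ]

    def posthoc(levels, means_by_subject):
        pairs = list(itertools.combinations(range(len(levels)), 2))
        m = len(pairs)
        rows = []
        for i, j in pairs:
            diff = means_by_subject[:, i] - means_by_subject[:, j]
            if np.allclose(diff.std(ddof=1), 0.0):
                t_val, p_raw = 0.0, 1.0
            else:
                t_val, p_raw = stats.ttest_rel(
                    means_by_subject[:, i], means_by_subject[:, j])
            rows.append({
                "level_a": levels[i], "level_b": levels[j],
                "mean_diff": float(diff.mean()), "t": float(t_val),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, m * float(p_raw))),
            })
        return pd.DataFrame(rows)

    return {
        "anova": pd.DataFrame(anova),
        "posthoc": {fa: posthoc(a_levels, m_as),
                    fb: posthoc(b_levels, m_bs)},
        "alpha": alpha,
        "n_subjects": s,
    }


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p_raw)


# -- study orchestration -------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration of a full synthetic evaluation study."""

    n_subjects: int = 10
    seed: int = 1
    emg_noise_sd: float = 0.05
    kin_noise_sd: float = 0.005
    sweep_subsets: bool = False   # evaluate every n in {1,2,3} subset
    sweep_max_n: int = 3
    sweep_n_subjects: int | None = None  # None = all subjects
    options: EvalOptions = field(default_factory=EvalOptions)
    sweep_options: EvalOptions = field(default_factory=lambda: EvalOptions(
        n_starts=0, maxiter=30, tol=1e-4, svr_max_train=400, cal_stride=3,
        eval_stride=3))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_subjects", "seed", "emg_noise_sd", "kin_noise_sd",
            "sweep_subsets", "sweep_max_n", "sweep_n_subjects")}
        d["options"] = vars(self.options)
        d["sweep_options"] = vars(self.sweep_options)
        return d


@dataclass
class StudyResult:
    """Long RMSE tables plus ANOVA summaries for one study run."""

    config: StudyConfig
    per_trial: pd.DataFrame          # every evaluated (set, trial, model)
    task_group: pd.DataFrame         # pooled per task group (3 final sets)
    family_summary: pd.DataFrame     # mean RMSE per Selected-family member
    worst_selected_key: str
    anova: dict                      # model -> rm_anova output
    sweep: pd.DataFrame | None = None

    def mean_rmse(self, set_label: str, model: str,
                  task_group: str | None = None) -> float:
        """Across-subject mean RMSE (per-trial mean) for one set and model."""
        df = self.per_trial
        mask = (df["set_label"] == set_label) & (df["model"] == model)
        if task_group is not None:
            mask &= df["task_group"] == task_group
        return float(df.loc[mask, "rmse"].mean())

    def summary(self) -> str:
        lines = [
            f"Calibration-set study: {self.config.n_subjects} synthetic "
            f"subjects, seed {self.config.seed}",
            "-" * 64,
            f"{'calibration set':<18}{'EMGMod RMSE':>14}{'RegMod RMSE':>14}",
        ]
        for label in ("full", "worst_selected", "quasi_static"):
            lines.append(
                f"{label:<18}{self.mean_rmse(label, 'emgmod'):>13.2f} "
                f"{self.mean_rmse(label, 'regmod'):>13.2f}"
            )
        fam = self.family_summary
        if not fam.empty:
            lines.append(
                f"Selected family ({len(fam)} members): RegMod RMSE "
                f"{fam['regmod_rmse'].min():.2f}-{fam['regmod_rmse'].max():.2f} N·m"
            )
        for model, res in self.anova.items():
            tab = res["anova"]
            terms = ", ".join(
                f"{r['effect']}: F({r['df']},{r['df_error']})="
                f"{r['F']:.2f}, p={r['p']:.3f}" for _, r in tab.iterrows())
            lines.append(f"ANOVA [{model}]: {terms}")
        return "\n".join(lines)


class CalibrationStudy:
    """End-to-end synthetic evaluation study, statsmodels-style."""

    def __init__(self, config: StudyConfig | None = None):
        self.config = config or StudyConfig()

    def run(self, subjects: list[SubjectData] | None = None,
            geometry: MuscleGeometry | None = None) -> StudyResult:
        cfg = self.config
        if subjects is None:
            subjects = generate_study(
                cfg.n_subjects, seed=cfg.seed,
                emg_noise_sd=cfg.emg_noise_sd, kin_noise_sd=cfg.kin_noise_sd)
        caches = [prepare_subject(sd, geometry) for sd in subjects]
        conditions = calibration_conditions()
        fullset = full_set(conditions)
        family = selected_family(conditions)
        quasi = quasi_static_set(conditions)

        frames = []
        for cache in caches:
            frames.append(evaluate_calibration_set(fullset, cache, cfg.options))
            frames.append(evaluate_calibration_set(quasi, cache, cfg.options))
            for member in family:
                frames.append(
                    evaluate_calibration_set(member, cache, cfg.options))
        per_trial = pd.concat(frames, ignore_index=True)

        fam_rows = per_trial[per_trial["set_label"] == "selected"]
        worst_key = worst_selected(fam_rows)
        family_summary = (
            fam_rows.groupby(["set_key", "model"])["rmse"].mean()
            .unstack("model").reset_index()
            .rename(columns={"emgmod": "emgmod_rmse", "regmod": "regmod_rmse"})
        )
        # relabel the worst member for the final three-set analysis
        per_trial.loc[
            (per_trial["set_label"] == "selected")
            & (per_trial["set_key"] == worst_key), "set_label"
        ] = "worst_selected"

        final = per_trial[per_trial["set_label"].isin(EVALUATED_SETS)]
        group_table = task_group_rmse(final)
        anova = {
            model: rm_anova(group_table[group_table["model"] == model])
            for model in ("emgmod", "regmod")
        }

        sweep = None
        if cfg.sweep_subsets:
            sweep = self._run_sweep(caches, conditions)

        return StudyResult(
            config=cfg, per_trial=per_trial, task_group=group_table,
            family_summary=family_summary, worst_selected_key=worst_key,
            anova=anova, sweep=sweep)

    def _run_sweep(self, caches, conditions) -> pd.DataFrame:
        """Evaluate every n-condition subset for n = 1..sweep_max_n and
        return the across-subject mean RMSE per subset and model."""
        cfg = self.config
        if cfg.sweep_n_subjects is not None:
            caches = caches[:cfg.sweep_n_subjects]
        rows = []
        for n in range(1, cfg.sweep_max_n + 1):
            for subset in enumerate_subsets(conditions, n):
                calset = CalibrationSet(
                    "subset", tuple(c.label for c in subset))
                rmses = {"emgmod": [], "regmod": []}
                for cache in caches:
                    df = evaluate_calibration_set(
                        calset, cache, cfg.sweep_options)
                    for model in rmses:
                        rmses[model].append(
                            df.loc[df["model"] == model, "rmse"].mean())
                rows.append({
                    "n": n, "set_key": calset.key,
                    "emgmod_rmse": float(np.mean(rmses["emgmod"])),
                    "regmod_rmse": float(np.mean(rmses["regmod"])),
                })
        return pd.DataFrame(rows)


def run_study(config: StudyConfig | None = None, out_dir=None) -> StudyResult:
    """Run a study and optionally write tables, figures and a run log."""
    result = CalibrationStudy(config).run()
    if out_dir is not None:
        from pathlib import Path

        from . import plotting

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.per_trial.to_csv(out / "per_trial_rmse.csv", index=False)
        result.task_group.to_csv(out / "task_group_rmse.csv", index=False)
        result.family_summary.to_csv(out / "selected_family.csv", index=False)
        for model, res in result.anova.items():
            res["anova"].to_csv(out / f"anova_{model}.csv", index=False)
        if result.sweep is not None:
            result.sweep.to_csv(out / "subset_sweep.csv", index=False)
        plotting.plot_task_group_bars(result, out / "task_group_rmse.png")
        if result.sweep is not None:
            plotting.plot_rmse_vs_n(result, out / "rmse_vs_n.png")
        (out / "report.md").write_text(
            "# Calibration-set study report\n\n```\n" + result.summary()
            + "\n```\n", encoding="utf-8")
        (out / "run_log.json").write_text(
            json.dumps({"config": result.config.to_dict(),
                        "worst_selected": result.worst_selected_key},
                       indent=2, default=str),
            encoding="utf-8")
    return result
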