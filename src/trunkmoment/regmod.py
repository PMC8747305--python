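"""Reduced-sensor regression model (RegMod).

Predicts the actively generated L5/S1 moment from signals available during
exoskeleton operation: four back-muscle EMG envelopes (bilateral longissimus
thoracis pars lumborum and pars thoracis) plus five kinematic channels
measurable by exoskeleton-embedded sensors (trunk inclination, its angular
velocity and acceleration, trunk flexion and hip angle).

The learner is an epsilon-SVR with a Gaussian kernel in its "coarse"
configuration: after z-scoring the predictors, kernel scale
``4 * sqrt(n_features)``; box constraint ``IQR(response)/1.349`` and tube
width ``IQR(response)/13.49`` (the interquartile-range heuristic).  The
response variable is always the active moment predicted by the calibrated
EMG-driven model, never the inverse-dynamics moment.  Ten-fold
cross-validation with trial-blocked contiguous folds (samples are serially
correlated) is reported as a training diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR

from .trial_model import REGMOD_EMG_CHANNELS, MomentSeries, Trial

FEATURE_COLUMNS = tuple(f"emg_{ch}" for ch in REGMOD_EMG_CHANNELS) + (
    "trunk_inclination", "trunk_inclination_vel", "trunk_inclination_acc",
    "trunk_flexion", "hip_angle",
)

N_FEATURES = len(FEATURE_COLUMNS)  # 9
KERNEL_SCALE = 4.0 * np.sqrt(N_FEATURES)  # "coarse" Gaussian setting
IQR_NORMAL = 1.349  # IQR of a standard normal


class FeatureSchemaError(ValueError):
    pass


def build_features(trial: Trial) -> np.ndarray:
    """(n_samples, 9) predictor matrix in the fixed column order."""
    missing = [c for c in FEATURE_COLUMNS if c not in trial.data.columns]
    if missing:
        raise FeatureSchemaError(f"missing feature channel(s): {missing}")
    return trial.data[list(FEATURE_COLUMNS)].to_numpy()


def _blocked_folds(group_ids: np.ndarray, n_folds: int) -> np.ndarray:
    """Assign contiguous trial blocks to folds (no within-trial splits).

    With fewer trials than folds, each trial becomes its own fold; fold ids
    are always compact (0..k-1 with every fold non-empty)."""
    unique = list(dict.fromkeys(group_ids.tolist()))
    k = min(n_folds, len(unique))
    fold_of_group = {g: i * k // len(unique) for i, g in enumerate(unique)}
    return np.array([fold_of_group[g] for g in group_ids], dtype=int)


class MomentRegression:
    """Coarse-Gaussian SVR of the active moment, statsmodels-style.

    Parameters
    ----------
    features : (n, 9) array
        Pooled predictor rows (see :data:`FEATURE_COLUMNS`).
    response : (n,) array
        Active moment from the calibrated EMG-driven model (N·m).
    group_ids : (n,) array, optional
        Trial identifier per row, used for trial-blocked CV folds.
    """

    def __init__(self, features, response, group_ids=None):
        self.features = np.asarray(features, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise FeatureSchemaError(
                f"expected (n, {N_FEATURES}) features, got {self.features.shape}"
            )
        if self.features.shape[0] != self.response.shape[0]:
            raise FeatureSchemaError("features and response lengths differ")
        if np.isnan(self.features).any() or np.isnan(self.response).any():
            raise FeatureSchemaError("features/response contain missing values")
        if group_ids is None:
            group_ids = np.zeros(self.features.shape[0], dtype=int)
        self.group_ids = np.asarray(group_ids)

    @classmethod
    def from_trials(cls, trials, responses) -> "MomentRegression":
        """Pool features/response over trials; responses are per-trial active
        moment arrays or :class:`MomentSeries`."""
        feats, resp, gids = [], [], []
        for trial, r in zip(trials, responses):
            values = r.values_nm if isinstance(r, MomentSeries) else np.asarray(r)
            feats.append(build_features(trial))
            resp.append(values)
            gids.append(np.full(trial.n_samples, trial.trial_id, dtype=object))
        return cls(np.vstack(feats), np.concatenate(resp),
                   np.concatenate(gids))

    def fit(self, cv_folds: int = 10, max_train_samples: int | None = 2000,
            compute_cv: bool = True) -> "MomentRegressionResults":
        """Fit the SVR; optionally report trial-blocked CV RMSE.

        ``max_train_samples`` caps the rows passed to the solver by uniform
        decimation (50 Hz samples are strongly serially correlated, so this
        loses little information while bounding the cubic solver cost).
        """
        x, y, gid = self.features, self.response, self.group_ids
        if x.shape[0] < 100:
            raise FeatureSchemaError("need at least 100 training samples")
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        q75, q25 = np.percentile(y, [75, 25])
        iqr = max(q75 - q25, 1e-6)
        c = iqr / IQR_NORMAL
        epsilon = iqr / (10 * IQR_NORMAL)
        gamma = 1.0 / KERNEL_SCALE**2

        def make_svr():
            return SVR(kernel="rbf", gamma=gamma, C=c, epsilon=epsilon)

        def subsample(idx):
            if max_train_samples is not None and idx.size > max_train_samples:
                sel = np.linspace(0, idx.size - 1, max_train_samples).astype(int)
                return idx[sel]
            return idx

        cv_rmse = np.nan
        if compute_cv:
            folds = _blocked_folds(gid, cv_folds)
            n_folds = folds.max() + 1
            if n_folds >= 2:
                sq_sum, n_total = 0.0, 0
                for k in range(n_folds):
                    train = subsample(np.flatnonzero(folds != k))
                    test = np.flatnonzero(folds == k)
                    svr = make_svr()
                    svr.fit((x[train] - mean) / std, y[train])
                    err = svr.predict((x[test] - mean) / std) - y[test]
                    sq_sum += float(np.dot(err, err))
                    n_total += err.size
                cv_rmse = float(np.sqrt(sq_sum / n_total))
        final = make_svr()
        train = subsample(np.arange(x.shape[0]))
        final.fit((x[train] - mean) / std, y[train])
        return MomentRegressionResults(
            model=self, svr=final, feature_mean=mean, feature_std=std,
            kernel_scale=KERNEL_SCALE, c=c, epsilon=epsilon, cv_rmse=cv_rmse,
            n_train=int(train.size))


@dataclass
class MomentRegressionResults:
    """Trained regressor with frozen standardization constants."""

    model: MomentRegression
    svr: SVR
    feature_mean: np.ndarray
    feature_std: np.ndarray
    kernel_scale: float
    c: float
    epsilon: float
    cv_rmse: float
    n_train: int
    metadata: dict = field(default_factory=dict)

    def predict(self, features) -> np.ndarray:
        """Per-sample active-moment prediction (features instantaneous)."""
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != N_FEATURES:
            raise FeatureSchemaError(
                f"feature schema mismatch: expected (n, {N_FEATURES}), "
                f"got {features.shape}"
            )
        z = (features - self.feature_mean) / self.feature_std
        return self.svr.predict(z)

    def predict_trial(self, trial: Trial) -> MomentSeries:
        return MomentSeries(trial.time_s, self.predict(build_features(trial)),
                            "active")

    def summary(self) -> str:
        lines = [
            "Coarse-Gaussian SVR of the active L5/S1 moment",
            "-" * 48,
            f"features            : {N_FEATURES} "
            f"(4 EMG + 5 kinematic channels)",
            f"kernel scale        : {self.kernel_scale:.3f} (z-scored inputs)",
            f"box constraint C    : {self.c:.4g}",
            f"epsilon tube        : {self.epsilon:.4g}",
            f"training samples    : {self.n_train}",
            f"support vectors     : {self.svr.support_.size}",
            f"10-fold CV RMSE     : {self.cv_rmse:.4g} N·m (trial-blocked)",
        ]
        return "\n".join(lines)


def train(trials, responses, **fit_kwargs) -> MomentRegressionResults:
    """Functional wrapper over :class:`MomentRegression`."""
    return MomentRegression.from_trials(trials, responses).fit(**fit_kwargs)


def predict(results: MomentRegressionResults, trial: Trial) -> MomentSeries:
    """Functional wrapper over :meth:`MomentRegressionResults.predict_trial`."""
    return results.predict_trial(trial)
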