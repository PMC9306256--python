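"""Elastic-net epigenetic age clock.

A penalized linear model predicting chronological age (months) from β
values. The penalty mixes L1 and L2 (mixing 0.5 by default); the
regularization strength is chosen over a log-spaced path by minimizing
mean absolute error under k-fold cross-validation, and the fitted model
stores per-probe training means so prediction stays defined on masked
arrays (missing β imputed by the training mean).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold


class ClockError(ValueError):
    pass


@dataclass
class ClockModel:
    """Serialized clock: intercept (months), sparse per-probe weights
    (months per β unit), elastic-net mixing and selected penalty, and
    per-probe training-mean imputation values."""

    intercept: float
    weights: pd.Series
    mixing: float
    penalty: float
    imputation_values: pd.Series
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all():
            raise ClockError("clock weights must be finite")
        missing = self.weights.index.difference(self.imputation_values.index)
        if len(missing):
            raise ClockError(
                f"no imputation value for weighted probes {list(missing)[:3]}..."
            )

    def save(self, weights_path, header_path) -> None:
        self.weights.rename("weight").rename_axis("probe_id").reset_index().to_csv(
            weights_path, sep="\t", index=False
        )
        header = {
            "intercept": self.intercept,
            "mixing": self.mixing,
            "penalty": self.penalty,
            "imputation_values": self.imputation_values.to_dict(),
            "training_meta": self.training_meta,
        }
        with open(header_path, "w") as fh:
            json.dump(header, fh, indent=1)

    @classmethod
    def load(cls, weights_path, header_path) -> "ClockModel":
        w = pd.read_csv(weights_path, sep="\t").set_index("probe_id")["weight"]
        with open(header_path) as fh:
            h = json.load(fh)
        return cls(
            intercept=h["intercept"],
            weights=w,
            mixing=h["mixing"],
            penalty=h["penalty"],
            imputation_values=pd.Series(h["imputation_values"]),
            training_meta=h.get("training_meta", {}),
        )


class EpigeneticClock(BaseEstimator, RegressorMixin):
    """Elastic-net age clock (sklearn estimator).

    ``fit(X, y)`` takes samples x probes β values (DataFrame preferred,
    so probe IDs are retained) and ages in months; ``predict(X)`` returns
    ages. Missing β are imputed by the training means both at fit and at
    predict time.

    Parameters
    ----------
    mixing : float, default 0.5
        Elastic-net mixing between L1 (1.0) and L2 (0.0).
    folds : int, default 10
        Cross-validation folds for penalty selection.
    n_penalties : int, default 30
        Length of the log-spaced penalty path.
    penalty : float or None
        Fix the regularization strength instead of selecting it by CV
        (e.g. a previously published value).
    rule : {"1se", "min"}, default "1se"
        Penalty choice along the CV curve: the one-standard-error rule
        (largest penalty whose mean CV MAE is within one SE of the
        minimum — the sparser, better-calibrated choice and the default
        of the reference elastic-net tooling) or the MAE minimizer.
    seed : int, default 0
        Controls the CV fold assignment (and nothing else).
    """

    def __init__(
        self,
        mixing: float = 0.5,
        folds: int = 10,
        n_penalties: int = 30,
        penalty: float | None = None,
        rule: str = "1se",
        seed: int = 0,
    ):
        self.mixing = mixing
        self.folds = folds
        self.n_penalties = n_penalties
        self.penalty = penalty
        self.rule = rule
        self.seed = seed

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def _penalty_path(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        n = len(y)
        l1 = max(self.mixing, 1e-3)
        alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * l1)
        alpha_max = max(alpha_max, 1e-6)
        return np.geomspace(alpha_max, alpha_max * 1e-3, self.n_penalties)

    def fit(self, X, y) -> "EpigeneticClock":
        Xf = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(Xf) != len(y):
            raise ClockError("X and y have mismatched sample counts")
        if len(Xf) < 2 * self.folds:
            raise ClockError(f"need at least {2 * self.folds} samples for {self.folds}-fold CV")
        if np.ptp(y) == 0:
            raise ClockError("ages are constant; cannot fit a clock")
        means = Xf.mean(axis=0)
        Xi = Xf.fillna(means).to_numpy(dtype=float)

        if self.penalty is not None:
            chosen = float(self.penalty)
            cv_mae = float("nan")
        else:
            path = self._penalty_path(Xi, y)
            kf = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
            maes = np.zeros((self.folds, len(path)))
            for k, (tr, te) in enumerate(kf.split(Xi)):
                model = ElasticNet(
                    l1_ratio=self.mixing, warm_start=True, max_iter=5000, tol=1e-5
                )
                for j, a in enumerate(path):
                    model.set_params(alpha=a)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model.fit(Xi[tr], y[tr])
                    maes[k, j] = np.mean(np.abs(model.predict(Xi[te]) - y[te]))
            mean_mae = maes.mean(axis=0)
            jmin = int(np.argmin(mean_mae))
            if self.rule == "1se":
                se = float(maes[:, jmin].std(ddof=1) / np.sqrt(self.folds))
                # path is decreasing, so the first qualifying index is the
                # largest (sparsest) penalty within one SE of the minimum
                jbest = int(np.flatnonzero(mean_mae <= mean_mae[jmin] + se)[0])
            elif self.rule == "min":
                jbest = jmin
            else:
                raise ClockError(f"unknown selection rule {self.rule!r}")
            chosen = float(path[jbest])
            cv_mae = float(mean_mae[jbest])

        final = ElasticNet(alpha=chosen, l1_ratio=self.mixing, max_iter=20000, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(Xi, y)
        self.intercept_ = float(final.intercept_)
        self.coef_ = pd.Series(final.coef_, index=Xf.columns)
        self.alpha_ = chosen
        self.cv_mae_ = cv_mae if self.penalty is None else None
        self.feature_means_ = means
        self.n_features_in_ = Xf.shape[1]
        return self

    @property
    def support_(self) -> pd.Index:
        return self.coef_.index[self.coef_ != 0]

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise ClockError("clock is not fitted; call fit() first")

    def predict(self, X) -> np.ndarray:
        ages, _ = self.predict_with_flags(X)
        return ages

    def predict_with_flags(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predict ages; flags mark low-confidence predictions where more
        than half of the weighted probes are missing."""
        self._check_fitted()
        Xf = self._as_frame(X)
        Xa = Xf.reindex(columns=self.coef_.index)
        support = self.support_
        if len(support):
            miss_frac = Xa[support].isna().mean(axis=1).to_numpy()
        else:
            miss_frac = np.zeros(len(Xa))
        Xi = Xa.fillna(self.feature_means_).to_numpy(dtype=float)
        ages = self.intercept_ + Xi @ self.coef_.to_numpy()
        return ages, miss_frac > 0.5

    def to_model(self) -> ClockModel:
        self._check_fitted()
        w = self.coef_[self.coef_ != 0]
        return ClockModel(
            intercept=self.intercept_,
            weights=w,
            mixing=self.mixing,
            penalty=self.alpha_,
            imputation_values=self.feature_means_[w.index],
            training_meta={"folds": self.folds, "cv_mae_months": self.cv_mae_},
        )


def fit_clock(
    betas: pd.DataFrame,
    ages,
    mixing: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    penalty: float | None = None,
) -> ClockModel:
    """Fit a clock from a probes x samples β matrix and ages in months."""
    clock = EpigeneticClock(mixing=mixing, folds=folds, seed=seed, penalty=penalty)
    clock.fit(betas.T, np.asarray(ages, dtype=float))
    model = clock.to_model()
    model.training_meta.update({"n_samples": betas.shape[1], "folds": folds})
    return model


def predict_age(betas: pd.DataFrame, model: ClockModel) -> tuple[pd.Series, pd.Series]:
    """Apply a clock to a probes x samples β matrix.

    Missing β values are imputed by the stored training means; samples
    with more than half of the weighted probes missing are flagged
    low-confidence.
    """
    X = betas.reindex(model.weights.index).T
    miss_frac = X.isna().mean(axis=1)
    Xi = X.fillna(model.imputation_values)
    ages = model.intercept + Xi.to_numpy(dtype=float) @ model.weights.to_numpy()
    return (
        pd.Series(ages, index=betas.columns, name="predicted_age_months"),
        (miss_frac > 0.5).rename("low_confidence"),
    )
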