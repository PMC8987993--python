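"""Modality-specific brain-age models.

A :class:`BrainAgeModel` wraps the cascade-forward network with the
modality feature contract (124 gray-matter or 90 white-matter features,
plus sex as an additional predictor), feature-name checking at prediction
time, k-fold cross-validated performance reporting (Pearson r and mean
absolute error in years), and JSON serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cascade import CascadeForwardRegressor
from .cohort import FeatureTable, sex_to_code

PANEL_SIZES = {"GM": 124, "WM": 90}


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, FeatureTable):
        return features.values
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError("features must be a FeatureTable or a pandas DataFrame")


def evaluate_predictions(predicted, chronological):
    """Pearson r and mean absolute error (years) of age predictions.

    Raises if lengths differ; r is undefined (raises) when the
    chronological ages have zero variance.
    """
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {c.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 predictions")
    if np.std(c) == 0:
        raise ValueError("zero variance in chronological age: r undefined")
    mae = float(np.mean(np.abs(p - c)))
    if np.std(p) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, c)[0])
    return r, mae


class BrainAgeModel(RegressorMixin, BaseEstimator):
    """Brain-age predictor for one modality panel.

    Parameters
    ----------
    modality : {"GM", "WM"}
        Which feature panel the model consumes (124 or 90 features).
    n_layers, width, alpha, max_iter, tol, validation_fraction, random_state
        Passed to the underlying :class:`CascadeForwardRegressor`.
    min_samples : int, default=10
        Minimum number of training participants.

    Attributes
    ----------
    feature_names_ : list of str
        Input feature order (checked at prediction time); sex is appended
        internally as the last predictor.
    net_ : CascadeForwardRegressor
        The fitted network (holds the standardization parameters).
    """

    def __init__(
        self,
        modality: str = "GM",
        n_layers: int = 12,
        width: int = 16,
        alpha: float = 1e-3,
        max_iter: int = 500,
        tol: float = 1e-6,
        validation_fraction: float = 0.1,
        random_state: int = 0,
        min_samples: int = 10,
    ):
        self.modality = modality
        self.n_layers = n_layers
        self.width = width
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.min_samples = min_samples

    def _check_panel(self, frame: pd.DataFrame) -> None:
        if self.modality not in PANEL_SIZES:
            raise ValueError(f"modality must be GM or WM, got {self.modality!r}")
        expected = PANEL_SIZES[self.modality]
        if frame.shape[1] != expected:
            raise ValueError(
                f"{self.modality} model expects {expected} features, got {frame.shape[1]}"
            )

    def fit(self, features, ages, sexes):
        frame = _as_frame(features)
        self._check_panel(frame)
        if len(frame) < self.min_samples:
            raise ValueError(
                f"need at least {self.min_samples} participants, got {len(frame)}"
            )
        ages = np.asarray(ages, dtype=float)
        X = np.column_stack([frame.to_numpy(dtype=float), sex_to_code(sexes)])
        if not np.isfinite(X).all() or not np.isfinite(ages).all():
            raise ValueError("non-finite values in training inputs")
        self.feature_names_ = list(frame.columns)
        self.net_ = CascadeForwardRegressor(
            n_layers=self.n_layers,
            width=self.width,
            alpha=self.alpha,
            max_iter=self.max_iter,
            tol=self.tol,
            validation_fraction=self.validation_fraction,
            random_state=self.random_state,
        ).fit(X, ages)
        return self

    def predict(self, features, sexes):
        check_is_fitted(self, "net_")
        frame = _as_frame(features)
        missing = [n for n in self.feature_names_ if n not in frame.columns]
        extra = [n for n in frame.columns if n not in set(self.feature_names_)]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
            )
        frame = frame[self.feature_names_]
        X = np.column_stack([frame.to_numpy(dtype=float), sex_to_code(sexes)])
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in prediction inputs")
        return self.net_.predict(X)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "net_")
        net = self.net_
        return {
            "modality": self.modality,
            "feature_names": self.feature_names_,
            "hyperparams": {
                "n_layers": self.n_layers,
                "width": self.width,
                "alpha": self.alpha,
                "max_iter": self.max_iter,
                "tol": self.tol,
                "validation_fraction": self.validation_fraction,
                "random_state": self.random_state,
                "min_samples": self.min_samples,
            },
            "scaling": {
                "x_mean": net.x_mean_.tolist(),
                "x_scale": net.x_scale_.tolist(),
                "y_mean": net.y_mean_,
                "y_scale": net.y_scale_,
            },
            "weights": {
                "coefs": [W.tolist() for W in net.coefs_],
                "intercepts": [b.tolist() for b in net.intercepts_],
                "output_coef": net.output_coef_.tolist(),
                "output_intercept": net.output_intercept_,
            },
            "training": {
                "n_iter": net.n_iter_,
                "loss_curve": [float(v) for v in net.loss_curve_],
                "optimizer": net.optimizer_result_,
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BrainAgeModel":
        model = cls(modality=d["modality"], **d["hyperparams"])
        model.feature_names_ = list(d["feature_names"])
        net = CascadeForwardRegressor(
            n_layers=d["hyperparams"]["n_layers"],
            width=d["hyperparams"]["width"],
            alpha=d["hyperparams"]["alpha"],
            max_iter=d["hyperparams"]["max_iter"],
            tol=d["hyperparams"]["tol"],
            validation_fraction=d["hyperparams"]["validation_fraction"],
            random_state=d["hyperparams"]["random_state"],
        )
        sc, wt = d["scaling"], d["weights"]
        net.n_features_in_ = len(sc["x_mean"])
        net.x_mean_ = np.asarray(sc["x_mean"], dtype=float)
        net.x_scale_ = np.asarray(sc["x_scale"], dtype=float)
        net.y_mean_ = float(sc["y_mean"])
        net.y_scale_ = float(sc["y_scale"])
        net.coefs_ = [np.asarray(W, dtype=float) for W in wt["coefs"]]
        net.intercepts_ = [np.asarray(b, dtype=float) for b in wt["intercepts"]]
        net.output_coef_ = np.asarray(wt["output_coef"], dtype=float)
        net.output_intercept_ = float(wt["output_intercept"])
        net.n_iter_ = int(d["training"]["n_iter"])
        net.loss_curve_ = list(d["training"]["loss_curve"])
        net.optimizer_result_ = d["training"]["optimizer"]
        model.net_ = net
        return model

    @classmethod
    def load(cls, path) -> "BrainAgeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_brain_age_model(
    features, ages, sexes, modality: str = "GM", seed: int = 0, **hyperparams
) -> BrainAgeModel:
    """Functional wrapper over :class:`BrainAgeModel`."""
    return BrainAgeModel(modality=modality, random_state=seed, **hyperparams).fit(
        features, ages, sexes
    )


def predict_age(model: BrainAgeModel, features, sexes) -> np.ndarray:
    return model.predict(features, sexes)


@dataclass
class CVReport:
    """k-fold cross-validation report for a brain-age model."""

    k: int
    fold_assignments: np.ndarray  # fold index per participant
    fold_r: List[float]
    fold_mae: List[float]
    pooled_r: float
    pooled_mae: float
    predictions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        folds = np.asarray(self.fold_assignments)
        sizes = np.bincount(folds, minlength=self.k)
        if sizes.sum() != len(folds) or len(sizes) != self.k:
            raise ValueError("fold assignments do not partition the sample")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")


def cross_validate(
    features,
    ages,
    sexes,
    k: int = 10,
    modality: str = "GM",
    seed: int = 0,
    **hyperparams,
) -> CVReport:
    """k-fold cross-validation with pooled out-of-fold metrics.

    Folds are a uniform seeded permutation with sizes differing by at most
    one; every participant is predicted exactly once out-of-fold, and the
    pooled r / MAE are computed over the concatenated predictions.
    """
    frame = _as_frame(features)
    ages = np.asarray(ages, dtype=float)
    sexes = sex_to_code(sexes)
    n = len(frame)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k

    preds = np.empty(n, dtype=float)
    fold_r, fold_mae = [], []
    for fold in range(k):
        test = folds == fold
        model = BrainAgeModel(
            modality=modality, random_state=seed + fold, min_samples=2, **hyperparams
        ).fit(frame.loc[~test], ages[~test], sexes[~test])
        preds[test] = model.predict(frame.loc[test], sexes[test])
        if test.sum() >= 2 and np.std(ages[test]) > 0:
            r_f, mae_f = evaluate_predictions(preds[test], ages[test])
        else:
            r_f, mae_f = float("nan"), float(np.mean(np.abs(preds[test] - ages[test])))
        fold_r.append(r_f)
        fold_mae.append(mae_f)
    pooled_r, pooled_mae = evaluate_predictions(preds, ages)
    return CVReport(k, folds, fold_r, fold_mae, pooled_r, pooled_mae, preds)
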