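"""Gaussian-process normative models and standardized deviance Z-scores.

One GP regression per regional feature is fitted on the reference
population with age and sex as inputs.  The default model is
semi-parametric: an unpenalized linear basis in (age, sex) carries the
dominant trend, and a GP with a squared-exponential kernel (ARD over the
scaled age and the binary sex dimension) plus white noise models the
residual structure.  The predictive SD *includes* the white-noise term,
so a healthy held-out observation scores
Z = (observed - predictive mean) / predictive SD ~ N(0, 1).

To keep the cubic cost of exact GP inference bounded across the full
feature panel, each per-feature fit uses a seeded subsample of the
reference participants (default 250); hyperparameters maximize the log
marginal likelihood from a small set of seeded restarts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    WhiteKernel,
)

from .cohort import FeatureTable, sex_to_code


@dataclass
class NormativeKernelConfig:
    """Kernel and optimizer settings shared by all per-feature models.

    Length scales are in scaled-input units (age standardized on the
    training sample; sex is 0/1).  With ``linear_basis`` (the default) the
    linear age and sex trend is absorbed by an unpenalized least-squares
    basis and the GP models only the residual structure; this avoids the
    prior shrinkage a purely kernel-based fit applies to the dominant
    linear trend.  Set it to False to obtain a plain GP with an added
    dot-product (linear) kernel component.
    """

    rbf_length_scale: Tuple[float, float] = (1.0, 1.0)
    # lower bound ~0.75 scaled units (~15 years of age): aging trajectories
    # are smooth over decades, and shorter scales only chase noise
    rbf_length_bounds: Tuple[float, float] = (0.75, 1e3)
    noise_level: float = 0.5
    n_restarts: int = 2
    max_points: int = 250
    extrapolation_margin: float = 5.0  # years beyond the training range
    linear_basis: bool = True

    def build_kernel(self):
        k = ConstantKernel(1.0, (1e-4, 1e3)) * RBF(
            np.asarray(self.rbf_length_scale), self.rbf_length_bounds
        ) + WhiteKernel(self.noise_level, (1e-8, 1e3))
        if not self.linear_basis:
            k = k + ConstantKernel(0.5, (1e-4, 1e3)) * DotProduct(
                sigma_0=1.0, sigma_0_bounds=(1e-3, 1e3)
            )
        return k


class GPNormativeModel:
    """Normative model for a single feature (exact GP posterior)."""

    def __init__(self, feature_name: str, config: Optional[NormativeKernelConfig] = None):
        self.feature_name = feature_name
        self.config = config or NormativeKernelConfig()

    def _scale_inputs(self, ages, sexes) -> np.ndarray:
        a = (np.asarray(ages, dtype=float) - self.age_mean_) / self.age_scale_
        s = sex_to_code(sexes)
        return np.column_stack([a, s])

    def fit(self, values, ages, sexes, seed: int = 0):
        values = np.asarray(values, dtype=float)
        ages = np.asarray(ages, dtype=float)
        sexes = sex_to_code(sexes)
        n = len(values)
        if n < 10:
            raise ValueError(f"need at least 10 reference participants, got {n}")
        if not (np.isfinite(values).all() and np.isfinite(ages).all()):
            raise ValueError("non-finite inputs to normative fit")
        rng = np.random.default_rng(seed)
        if n > self.config.max_points:
            idx = rng.choice(n, self.config.max_points, replace=False)
            idx.sort()
        else:
            idx = np.arange(n)
        self.age_mean_ = float(ages.mean())
        self.age_scale_ = float(ages.std()) or 1.0
        self.age_range_ = (float(ages.min()), float(ages.max()))
        self.degenerate_ = bool(np.std(values) == 0)
        if self.degenerate_:
            self.constant_value_ = float(values[0])
            self.gp_ = None
            self.log_marginal_likelihood_ = float("nan")
            return self
        # linear basis fitted on the full reference sample (unpenalized OLS)
        if self.config.linear_basis:
            B = np.column_stack([np.ones(n), self._scale_inputs(ages, sexes)])
            self.basis_coef_, *_ = np.linalg.lstsq(B, values, rcond=None)
            targets = values - B @ self.basis_coef_
            self.target_mean_ = 0.0  # residuals are centered by construction
        else:
            self.basis_coef_ = None
            self.target_mean_ = float(values.mean())
            targets = values - self.target_mean_
        # centering and scaling use the FULL reference sample, so the GP's
        # zero prior mean is the best available estimate even when only a
        # subsample enters the kernel matrix
        scale = float(np.std(targets))
        self.target_scale_ = scale if scale > 0 else 1.0
        X = self._scale_inputs(ages[idx], sexes[idx])
        self.X_fit_ = X
        self.y_fit_ = targets[idx] / self.target_scale_
        self.gp_ = GaussianProcessRegressor(
            kernel=self.config.build_kernel(),
            normalize_y=False,
            alpha=1e-10,
            n_restarts_optimizer=max(0, self.config.n_restarts - 1),
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.gp_.fit(X, self.y_fit_)
        self.log_marginal_likelihood_ = float(self.gp_.log_marginal_likelihood_value_)
        # recalibrate against the FULL reference sample.  A subsampled GP
        # can re-introduce a small intercept/tilt (its near-constant kernel
        # components are free to follow the subsample mean), and the ML
        # noise estimate carries the subsample's chi-square fluctuation
        # (~sqrt(2/m)); both are removable because the full-sample
        # residuals are centered and trend-free by construction.
        X_all = self._scale_inputs(ages, sexes)
        mu_all, sd_all = self.gp_.predict(X_all, return_std=True)
        resid = targets / self.target_scale_ - mu_all
        if self.config.linear_basis:
            B_all = np.column_stack([np.ones(n), X_all])
            delta, *_ = np.linalg.lstsq(B_all, resid, rcond=None)
            self.basis_coef_ = self.basis_coef_ + delta * self.target_scale_
            resid = resid - B_all @ delta
        else:
            shift = float(resid.mean())
            self.target_mean_ += shift * self.target_scale_
            resid = resid - shift
        self.sd_calibration_ = 1.0
        rms = float(np.sqrt(np.mean((resid / np.maximum(sd_all, 1e-12)) ** 2)))
        if rms > 0:
            self.sd_calibration_ = rms
        return self

    def predict(self, ages, sexes, warn_extrapolation: bool = True):
        """Predictive mean and SD (noise included) at the given age/sex."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        sexes = np.atleast_1d(sex_to_code(sexes))
        lo, hi = self.age_range_
        m = self.config.extrapolation_margin
        outside = (ages < lo - m) | (ages > hi + m)
        if warn_extrapolation and outside.any():
            warnings.warn(
                f"{self.feature_name}: {int(outside.sum())} quer(ies) outside the "
                f"training age range [{lo:.1f}, {hi:.1f}] +/- {m:.0f} y",
                UserWarning,
                stacklevel=2,
            )
        if self.degenerate_:
            mean = np.full(len(ages), self.constant_value_)
            sd = np.full(len(ages), 1e-8)
            return mean, sd
        X = self._scale_inputs(ages, sexes)
        mean, sd = self.gp_.predict(X, return_std=True)
        mean = mean * self.target_scale_ + self.target_mean_
        sd = sd * self.target_scale_ * self.sd_calibration_
        if self.basis_coef_ is not None:
            mean = mean + np.column_stack([np.ones(len(X)), X]) @ self.basis_coef_
        return mean, np.maximum(sd, 1e-12)

    def zscore(self, observed, ages, sexes) -> np.ndarray:
        mean, sd = self.predict(ages, sexes, warn_extrapolation=False)
        return (np.asarray(observed, dtype=float) - mean) / sd

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "feature_name": self.feature_name,
            "age_mean": self.age_mean_,
            "age_scale": self.age_scale_,
            "age_range": list(self.age_range_),
            "degenerate": self.degenerate_,
            "log_marginal_likelihood": self.log_marginal_likelihood_,
            "config": {
                "rbf_length_scale": list(self.config.rbf_length_scale),
                "noise_level": self.config.noise_level,
                "n_restarts": self.config.n_restarts,
                "max_points": self.config.max_points,
                "extrapolation_margin": self.config.extrapolation_margin,
                "linear_basis": self.config.linear_basis,
            },
        }
        if self.degenerate_:
            d["constant_value"] = self.constant_value_
        else:
            d["kernel_theta"] = self.gp_.kernel_.theta.tolist()
            d["X_train"] = self.X_fit_.tolist()
            d["y_train"] = self.y_fit_.tolist()
            d["target_mean"] = self.target_mean_
            d["target_scale"] = self.target_scale_
            d["sd_calibration"] = self.sd_calibration_
            d["basis_coef"] = (
                None if self.basis_coef_ is None else self.basis_coef_.tolist()
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GPNormativeModel":
        cfg = NormativeKernelConfig(
            rbf_length_scale=tuple(d["config"]["rbf_length_scale"]),
            noise_level=d["config"]["noise_level"],
            n_restarts=d["config"]["n_restarts"],
            max_points=d["config"]["max_points"],
            extrapolation_margin=d["config"]["extrapolation_margin"],
            linear_basis=d["config"].get("linear_basis", True),
        )
        model = cls(d["feature_name"], cfg)
        model.age_mean_ = d["age_mean"]
        model.age_scale_ = d["age_scale"]
        model.age_range_ = tuple(d["age_range"])
        model.degenerate_ = d["degenerate"]
        model.log_marginal_likelihood_ = d["log_marginal_likelihood"]
        if model.degenerate_:
            model.constant_value_ = d["constant_value"]
            model.gp_ = None
            return model
        kernel = cfg.build_kernel()
        kernel.theta = np.asarray(d["kernel_theta"], dtype=float)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, alpha=1e-10, optimizer=None
        )
        model.X_fit_ = np.asarray(d["X_train"], dtype=float)
        model.y_fit_ = np.asarray(d["y_train"], dtype=float)
        model.target_mean_ = float(d["target_mean"])
        model.target_scale_ = float(d["target_scale"])
        model.sd_calibration_ = float(d.get("sd_calibration", 1.0))
        model.basis_coef_ = (
            None if d.get("basis_coef") is None
            else np.asarray(d["basis_coef"], dtype=float)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(model.X_fit_, model.y_fit_)
        model.gp_ = gp
        return model


def fit_normative(values, ages, sexes, config=None, seed: int = 0,
                  feature_name: str = "feature") -> GPNormativeModel:
    """Fit a single-feature normative model (functional wrapper)."""
    return GPNormativeModel(feature_name, config).fit(values, ages, sexes, seed=seed)


def predict_norm(model: GPNormativeModel, ages, sexes):
    return model.predict(ages, sexes)


class NormativeModelSet:
    """One GP normative model per feature of a panel.

    ``fit`` takes the reference feature table with ages and sexes;
    ``transform`` converts any cohort's feature table into a Z-score
    profile (participants x features DataFrame, same feature order).
    """

    def __init__(self, config: Optional[NormativeKernelConfig] = None, seed: int = 0):
        self.config = config or NormativeKernelConfig()
        self.seed = seed

    def fit(self, features, ages, sexes):
        frame = features.values if isinstance(features, FeatureTable) else features
        self.feature_names_ = list(frame.columns)
        self.models_: Dict[str, GPNormativeModel] = {}
        seeds = np.random.SeedSequence(self.seed).generate_state(len(self.feature_names_))
        for name, s in zip(self.feature_names_, seeds):
            self.models_[name] = GPNormativeModel(name, self.config).fit(
                frame[name].to_numpy(dtype=float), ages, sexes, seed=int(s % (2**31))
            )
        return self

    def transform(self, features, ages, sexes) -> pd.DataFrame:
        frame = features.values if isinstance(features, FeatureTable) else features
        missing = [n for n in frame.columns if n not in self.models_]
        if missing:
            raise ValueError(f"no normative model for feature(s): {missing[:5]}")
        out = {}
        for name in frame.columns:
            out[name] = self.models_[name].zscore(
                frame[name].to_numpy(dtype=float), ages, sexes
            )
        return pd.DataFrame(out, index=frame.index)[list(frame.columns)]

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "features": [self.models_[n].to_dict() for n in self.feature_names_],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NormativeModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(seed=payload.get("seed", 0))
        obj.feature_names_ = [d["feature_name"] for d in payload["features"]]
        obj.models_ = {
            d["feature_name"]: GPNormativeModel.from_dict(d) for d in payload["features"]
        }
        if obj.models_:
            obj.config = next(iter(obj.models_.values())).config
        return obj


def compute_zscores(model_set: NormativeModelSet, features, ages, sexes) -> pd.DataFrame:
    """Z-score profiles for a cohort (wrapper over ``transform``)."""
    return model_set.transform(features, ages, sexes)
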