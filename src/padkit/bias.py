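"""Predicted-age-difference (PAD) scores and their linear age-bias correction.

PAD = predicted age - chronological age.  Raw PAD carries an age-related
bias (regression dilution makes young brains look old and old brains look
young), so the standard linear correction regresses PAD on chronological
age in a reference sample and subtracts the fitted trend:

    corrected PAD = PAD - (a * age + b)

On the reference sample itself the corrected PAD is exactly orthogonal to
age (an OLS residual property).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def compute_pad(predicted, chronological) -> np.ndarray:
    """Elementwise predicted minus chronological age, in years."""
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {c.shape}")
    return p - c


class PadBiasCorrector(TransformerMixin, BaseEstimator):
    """Linear age-bias correction for PAD scores.

    ``fit(pad, ages)`` performs an OLS regression of PAD on age in the
    reference sample; ``transform(pad, ages)`` subtracts the fitted trend.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted regression coefficients (a, b).
    reference_ : str
        Tag naming the reference sample used for the fit.
    """

    def __init__(self, reference: str = "HC"):
        self.reference = reference

    def fit(self, pad, ages):
        pad = np.asarray(pad, dtype=float)
        ages = np.asarray(ages, dtype=float)
        if pad.shape != ages.shape:
            raise ValueError("pad and ages must have equal length")
        if pad.size < 3:
            raise ValueError("need at least 3 reference participants")
        if np.std(ages) == 0:
            raise ValueError("zero age variance in reference sample")
        A = np.column_stack([ages, np.ones_like(ages)])
        coef, *_ = np.linalg.lstsq(A, pad, rcond=None)
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1])
        self.reference_ = self.reference
        return self

    def transform(self, pad, ages) -> np.ndarray:
        check_is_fitted(self, "slope_")
        pad = np.asarray(pad, dtype=float)
        ages = np.asarray(ages, dtype=float)
        return pad - (self.slope_ * ages + self.intercept_)


def fit_bias_correction(pad, ages, reference: str = "HC") -> PadBiasCorrector:
    return PadBiasCorrector(reference=reference).fit(pad, ages)


def apply_bias_correction(pad, ages, correction: PadBiasCorrector) -> np.ndarray:
    return correction.transform(pad, ages)


@dataclass
class PADResult:
    """Per-participant PAD scores for one modality."""

    modality: str
    ids: list
    predicted_age: np.ndarray
    pad: np.ndarray
    corrected_pad: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "modality": self.modality,
                "predicted_age": self.predicted_age,
                "pad": self.pad,
                "corrected_pad": self.corrected_pad,
            }
        )


def pad_scores(
    model,
    cohort,
    corrector: Optional[PadBiasCorrector] = None,
    reference_mask=None,
) -> PADResult:
    """Predict ages for a cohort and return raw plus corrected PAD.

    If ``corrector`` is None, one is fitted on the participants selected by
    ``reference_mask`` (default: the cohort's HC group).
    """
    panel = model.modality
    table = cohort.tables[panel]
    predicted = model.predict(table, cohort.sex_codes)
    pad = compute_pad(predicted, cohort.ages)
    if corrector is None:
        if reference_mask is None:
            reference_mask = cohort.participants["group"].to_numpy() == "HC"
        reference_mask = np.asarray(reference_mask, dtype=bool)
        if reference_mask.sum() < 3:
            raise ValueError("reference sample for bias correction too small")
        corrector = PadBiasCorrector().fit(pad[reference_mask], cohort.ages[reference_mask])
    corrected = corrector.transform(pad, cohort.ages)
    return PADResult(panel, cohort.ids, predicted, pad, corrected)
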