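"""Synthetic cohort generator with known brain-age ground truth.

The generator emulates the tabular inputs of the analysis: a normative
(training) population of cognitively normal adults spanning ages 14-92,
and clinical groups (HC / MSA / PD-like) whose regional features are
evaluated at an *effective age* ``age + delta_i``, where ``delta_i`` is a
per-participant brain-age offset (group shift plus jitter).  That
construction makes the "true PAD" well defined, so every downstream stage
(prediction, bias correction, normative Z-scores, contribution profiles)
can be tested for parameter recovery.

Each feature f follows an independent trajectory

    mu_f(age, sex) = b0 + b1 * (age - ref) + b2 * (age - ref)^2 + bs * sex

with additive Gaussian noise of SD sigma_f.  Default signs follow biology:
volumes, thickness and GFA decline with age (b1 < 0), MD rises (b1 > 0).
Sex is coded female=0 / male=1.  Optional focal deviance adds a shift (in
units of sigma_f) to named features; optional clinical scores are linear
in the realized offset delta_i plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import Cohort, FeatureTable
from .features import FeatureDescriptor, gm_descriptors, wm_descriptors

# Training-population age distribution (truncated normal).
DEFAULT_AGE_MEAN = 36.9
DEFAULT_AGE_SD = 19.1
DEFAULT_AGE_RANGE = (14.0, 92.0)
REFERENCE_AGE = 50.0

_PARAM_COLS = ["beta0", "beta1", "beta2", "beta_sex", "sigma"]


@dataclass
class TrajectoryConfig:
    """Per-feature trajectory parameters plus the sampling distributions.

    ``params`` is indexed by feature name with columns beta0, beta1, beta2,
    beta_sex, sigma (feature units; sigma >= 0).
    """

    descriptors: List[FeatureDescriptor]
    params: pd.DataFrame
    reference_age: float = REFERENCE_AGE
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    age_range: Tuple[float, float] = DEFAULT_AGE_RANGE
    male_fraction: float = 0.47

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        missing = [n for n in names if n not in self.params.index]
        if missing:
            raise ValueError(f"trajectory params missing features: {missing[:3]}...")
        extra = [n for n in self.params.index if n not in set(names)]
        if extra:
            raise ValueError(f"trajectory params for unknown features: {extra[:3]}...")
        if (self.params["sigma"] < 0).any():
            bad = self.params.index[self.params["sigma"] < 0][0]
            raise ValueError(f"negative residual SD for feature {bad!r}")
        self.params = self.params.loc[names, _PARAM_COLS].astype(float)

    def mean(self, ages: np.ndarray, sex_codes: np.ndarray) -> np.ndarray:
        """Trajectory means mu_f(age, sex): (n_participants, n_features)."""
        a = np.asarray(ages, dtype=float)[:, None] - self.reference_age
        s = np.asarray(sex_codes, dtype=float)[:, None]
        p = self.params
        return (
            p["beta0"].to_numpy()[None, :]
            + p["beta1"].to_numpy()[None, :] * a
            + p["beta2"].to_numpy()[None, :] * a**2
            + p["beta_sex"].to_numpy()[None, :] * s
        )

    def with_sigma(self, sigma) -> "TrajectoryConfig":
        """Copy with every residual SD replaced (scalar or per-feature)."""
        params = self.params.copy()
        params["sigma"] = sigma
        return TrajectoryConfig(
            self.descriptors, params, self.reference_age, self.age_mean,
            self.age_sd, self.age_range, self.male_fraction,
        )

    def to_dict(self) -> dict:
        return {
            "reference_age": self.reference_age,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_range": list(self.age_range),
            "male_fraction": self.male_fraction,
            "params": {
                name: {c: float(row[c]) for c in _PARAM_COLS}
                for name, row in self.params.iterrows()
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict, descriptors: List[FeatureDescriptor]) -> "TrajectoryConfig":
        params = pd.DataFrame.from_dict(d["params"], orient="index")
        params.index.name = "name"
        return cls(
            descriptors,
            params,
            reference_age=d.get("reference_age", REFERENCE_AGE),
            age_mean=d.get("age_mean", DEFAULT_AGE_MEAN),
            age_sd=d.get("age_sd", DEFAULT_AGE_SD),
            age_range=tuple(d.get("age_range", DEFAULT_AGE_RANGE)),
            male_fraction=d.get("male_fraction", 0.47),
        )

    @classmethod
    def load(cls, path, descriptors: Optional[List[FeatureDescriptor]] = None):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if descriptors is None:
            descriptors = gm_descriptors() + wm_descriptors()
        return cls.from_dict(d, descriptors)


def default_trajectory_config(
    descriptors: Optional[List[FeatureDescriptor]] = None,
    param_seed: int = 20220330,
    noise_scale: float = 1.0,
) -> TrajectoryConfig:
    """Plausible per-feature trajectories, drawn once from a fixed seed.

    Residual SDs are expressed through an "age-equivalent noise" of 6-12
    years per feature (sigma = |b1| * U(6, 12) * noise_scale), so a single
    feature dates the brain only coarsely while the full panel does so to
    about a year.
    """
    if descriptors is None:
        descriptors = gm_descriptors() + wm_descriptors()
    rng = np.random.default_rng(param_seed)
    rows = []
    for d in descriptors:
        if d.modality == "GM_volume":
            b0 = rng.uniform(3.0, 30.0)
            b1 = -b0 * rng.uniform(0.0015, 0.004)
            bs = b0 * rng.uniform(0.02, 0.08)
        elif d.modality == "GM_thickness":
            b0 = rng.uniform(2.0, 3.2)
            b1 = -rng.uniform(0.002, 0.006)
            bs = rng.uniform(-0.03, 0.03)
        elif d.modality == "WM_GFA":
            b0 = rng.uniform(0.30, 0.55)
            b1 = -rng.uniform(0.0005, 0.0015)
            bs = rng.uniform(-0.01, 0.01)
        else:  # WM_MD, units 1e-3 mm^2/s
            b0 = rng.uniform(0.65, 0.95)
            b1 = rng.uniform(0.0008, 0.0020)
            bs = rng.uniform(-0.01, 0.01)
        sigma = abs(b1) * rng.uniform(6.0, 12.0) * noise_scale
        rows.append((d.name, b0, b1, 0.0, bs, sigma))
    params = pd.DataFrame(
        rows, columns=["name"] + _PARAM_COLS
    ).set_index("name")
    return TrajectoryConfig(descriptors, params)


@dataclass
class ClinicalCohortConfig:
    """Ground-truth recipe for one clinical group.

    ``pad_shift`` is the mean brain-age offset delta (years) added to the
    effective age at which trajectories are evaluated; per-participant
    jitter of SD ``jitter_sd`` is added on top.  ``pad_shift_features``
    optionally restricts the shift to a named subset (default: all
    features), giving ground truth for attribution tests.
    ``deviant_features`` adds a focal shift in units of that feature's
    sigma.  ``clinical_coupling`` maps a score name to
    (base, loading, noise_sd): score = base + loading * delta_i + noise.
    """

    group: str
    n: int
    pad_shift: float = 0.0
    jitter_sd: float = 2.0
    pad_shift_features: Optional[Sequence[str]] = None
    deviant_features: Dict[str, float] = field(default_factory=dict)
    clinical_coupling: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    age_mean: float = 66.0
    age_sd: float = 7.0
    age_range: Tuple[float, float] = (50.0, 85.0)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size n must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def default_clinical_coupling(jitter_sd: float = 2.0, rho: float = 0.4):
    """Couplings that give corr(score, delta) = rho for the default jitter."""
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    noise = jitter_sd * np.sqrt(1.0 / rho**2 - 1.0)
    return {
        "UPDRS_total": (20.0, 1.0, noise),
        "UPDRS_III": (10.0, 1.0, noise),
        "MoCA": (25.0, -1.0, noise),
    }


def _truncnorm(rng, mean, sd, lo, hi, n):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _sample_core(rng, n, config: TrajectoryConfig, age_mean, age_sd, age_range):
    ages = _truncnorm(rng, age_mean, age_sd, *age_range, n)
    sexes = (rng.random(n) < config.male_fraction).astype(int)
    education = np.clip(rng.normal(13.0, 3.5, n), 6.0, 20.0)
    noise = rng.standard_normal((n, len(config.descriptors)))
    return ages, sexes, education, noise


def _build_tables(config: TrajectoryConfig, ids, values: np.ndarray) -> Dict[str, FeatureTable]:
    frame = pd.DataFrame(values, index=ids, columns=[d.name for d in config.descriptors])
    tables: Dict[str, FeatureTable] = {}
    for panel, prefixes in (("GM", ("GM_volume", "GM_thickness")), ("WM", ("WM_GFA", "WM_MD"))):
        descs = [d for d in config.descriptors if d.modality in prefixes]
        if not descs:
            continue
        sub = frame[[d.name for d in descs]].copy()
        # keep GFA inside its open unit interval; trajectories leave wide margins
        for d in descs:
            if d.modality == "WM_GFA":
                sub[d.name] = np.clip(sub[d.name], 1e-4, 1 - 1e-4)
        tables[panel] = FeatureTable(descs, sub)
    return tables


def generate_normative_population(
    n: int,
    config: Optional[TrajectoryConfig] = None,
    seed: int = 0,
    group: str = "TRAIN",
    id_prefix: str = "norm",
) -> Cohort:
    """Draw a cognitively-normal population from the trajectory model.

    Deterministic: identical (n, config, seed) give bit-identical cohorts.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if config is None:
        config = default_trajectory_config()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ages, sexes, education, noise = _sample_core(
        rng, n, config, config.age_mean, config.age_sd, config.age_range
    )
    values = config.mean(ages, sexes) + noise * config.params["sigma"].to_numpy()[None, :]
    ids = [f"{id_prefix}-{i:04d}" for i in range(n)]
    participants = pd.DataFrame(
        {
            "id": ids,
            "age": ages,
            "sex": np.where(sexes == 1, "male", "female"),
            "education": education,
            "group": group,
        }
    )
    return Cohort(participants, _build_tables(config, ids, values))


def generate_clinical_cohort(
    clinical: ClinicalCohortConfig,
    config: Optional[TrajectoryConfig] = None,
    seed: int = 0,
    id_prefix: Optional[str] = None,
) -> Cohort:
    """Draw a clinical group with a known brain-age offset.

    Feature values are mu_f(age + delta_i, sex) + focal deviance + noise,
    with delta_i = pad_shift + jitter.  The realized delta_i is returned in
    the participants column ``true_delta`` for recovery tests.  With
    pad_shift = 0, jitter_sd = 0 and no deviance the output is identical to
    :func:`generate_normative_population` at the same seed (up to the group
    label and age distribution).
    """
    if config is None:
        config = default_trajectory_config()
    names = [d.name for d in config.descriptors]
    name_set = set(names)
    for f in clinical.deviant_features:
        if f not in name_set:
            raise ValueError(f"deviant feature {f!r} not in descriptor list")
    if clinical.pad_shift_features is not None:
        unknown = [f for f in clinical.pad_shift_features if f not in name_set]
        if unknown:
            raise ValueError(f"pad_shift features not in descriptor list: {unknown}")

    seq = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(seq[0])  # demographics + feature noise (shared stream)
    rng_delta = np.random.default_rng(seq[1])
    rng_clin = np.random.default_rng(seq[2])

    n = clinical.n
    ages, sexes, education, noise = _sample_core(
        rng, n, config, clinical.age_mean, clinical.age_sd, clinical.age_range
    )
    delta = clinical.pad_shift + clinical.jitter_sd * rng_delta.standard_normal(n)

    if clinical.pad_shift_features is None:
        shift_mask = np.ones(len(names), dtype=bool)
    else:
        shift_mask = np.isin(names, list(clinical.pad_shift_features))
    eff_age = ages[:, None] + delta[:, None] * shift_mask[None, :]
    p = config.params
    a = eff_age - config.reference_age
    mu = (
        p["beta0"].to_numpy()[None, :]
        + p["beta1"].to_numpy()[None, :] * a
        + p["beta2"].to_numpy()[None, :] * a**2
        + p["beta_sex"].to_numpy()[None, :] * sexes[:, None]
    )
    values = mu + noise * p["sigma"].to_numpy()[None, :]
    for fname, shift in clinical.deviant_features.items():
        j = names.index(fname)
        values[:, j] += shift * p["sigma"].iloc[j]

    prefix = id_prefix if id_prefix is not None else clinical.group.lower()
    ids = [f"{prefix}-{i:04d}" for i in range(n)]
    participants = pd.DataFrame(
        {
            "id": ids,
            "age": ages,
            "sex": np.where(sexes == 1, "male", "female"),
            "education": education,
            "group": clinical.group,
            "true_delta": delta,
        }
    )
    for score, (base, loading, noise_sd) in clinical.clinical_coupling.items():
        participants[score] = base + loading * delta + noise_sd * rng_clin.standard_normal(n)
    return Cohort(participants, _build_tables(config, ids, values))
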