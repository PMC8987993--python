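"""End-to-end analysis pipeline driven by a single config.

Stages, in dependency order: simulate (or load) the normative training
population and the clinical groups -> train one brain-age model per
modality panel (with optional k-fold CV) -> predict ages and PAD for the
clinical cohort -> fit the linear age-bias correction on the designated
reference group -> fit the GP normative model set on the training
population -> Z-score the clinical cohort -> robust contribution profiles
per group, top-k ranking, ΔES table -> group statistics (ANCOVA +
BH post-hoc, partial correlations between modality PADs, Fisher r-to-z
comparisons, clinical associations, outlier-exclusion re-analysis).

All intermediates are written under the output directory; the run report
(JSON) records per-stage provenance and seeds so an identical config
reproduces identical numbers.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import PadBiasCorrector, compute_pad
from .brain_age import BrainAgeModel, cross_validate
from .cohort import Cohort, read_cohort, write_cohort
from .contribution import (
    aggregate_by_region,
    contribution_profile,
    delta_effect_size,
    rank_top,
)
from .normative import NormativeKernelConfig, NormativeModelSet
from .robust import MMConfig
from .simulate import (
    ClinicalCohortConfig,
    TrajectoryConfig,
    default_clinical_coupling,
    default_trajectory_config,
    generate_clinical_cohort,
    generate_normative_population,
)
from .stats import ancova_compare, clinical_associations, compare_correlations, exclude_lowest, partial_correlation

REQUIRED_SEEDS = ("simulate", "train", "cv", "normative", "contribution")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run."""

    output_dir: str = "padkit_run"
    modalities: List[str] = field(default_factory=lambda: ["GM", "WM"])
    train_n: int = 500
    train_path: Optional[str] = None  # load instead of simulate
    clinical_path: Optional[str] = None
    clinical_groups: Dict[str, dict] = field(
        default_factory=lambda: {
            "HC": {"n": 34, "pad_shift": 0.0},
            "MSA": {"n": 23, "pad_shift": 9.0},
            "PD": {"n": 33, "pad_shift": 1.0},
        }
    )
    model: Dict[str, float] = field(default_factory=dict)  # BrainAgeModel kwargs
    cv_k: int = 0  # 0 disables cross-validation
    kernel: Dict[str, float] = field(default_factory=dict)  # NormativeKernelConfig kwargs
    mm: Dict[str, float] = field(default_factory=dict)  # MMConfig kwargs
    covariates: List[str] = field(default_factory=lambda: ["age", "sex", "education"])
    clinical_scores: List[str] = field(default_factory=lambda: ["UPDRS_total", "UPDRS_III", "MoCA"])
    delta_threshold: float = 0.3
    top_k: int = 20
    exclude_lowest_counts: Dict[str, int] = field(default_factory=dict)
    reference_group: str = "HC"
    seeds: Dict[str, int] = field(
        default_factory=lambda: {s: i for i, s in enumerate(REQUIRED_SEEDS, start=1)}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg._from_file = True
        return cfg

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def validate_config(config: PipelineConfig) -> List[str]:
    """Return a list of issues; empty iff the pipeline can run."""
    issues: List[str] = []
    for stage in REQUIRED_SEEDS:
        if config.seeds.get(stage) is None:
            issues.append(f"missing seed for stage {stage!r}")
    for m in config.modalities:
        if m not in ("GM", "WM"):
            issues.append(f"unknown modality {m!r}")
    if config.train_path is None and config.train_n < 10:
        issues.append(f"train_n={config.train_n} too small (need >= 10)")
    for group, spec in config.clinical_groups.items():
        n = spec.get("n", -1)
        if n < 0:
            issues.append(f"negative n for clinical group {group!r}")
    allowed_cov = {"age", "sex", "education"}
    for cov in config.covariates:
        if cov not in allowed_cov:
            issues.append(f"unknown covariate {cov!r}")
    if config.reference_group not in config.clinical_groups and config.clinical_path is None:
        issues.append(f"reference group {config.reference_group!r} not among clinical groups")
    if not 0 < config.delta_threshold:
        issues.append("delta_threshold must be positive")
    for group, cnt in config.exclude_lowest_counts.items():
        if cnt < 0:
            issues.append(f"negative exclusion count for {group!r}")
    return issues


def _covariate_frame(participants: pd.DataFrame, names) -> pd.DataFrame:
    from .cohort import sex_to_code

    return pd.DataFrame(
        {
            name: (sex_to_code(participants["sex"]) if name == "sex"
                   else participants[name].to_numpy(dtype=float))
            for name in names
        }
    )


def run_pipeline(config: PipelineConfig, trajectory: Optional[TrajectoryConfig] = None) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "padkit_version": __version__,
        "python": platform.python_version(),
        "seeds": dict(config.seeds),
        "warnings": [],
        "stages": {},
    }

    def stage(name):
        report["stages"][name] = {"status": "running"}
        return name

    try:
        # ---- simulate / load --------------------------------------------
        name = stage("simulate")
        if trajectory is None:
            trajectory = default_trajectory_config()
        if config.train_path:
            train = read_cohort(config.train_path)
        else:
            train = generate_normative_population(
                config.train_n, trajectory, seed=config.seeds["simulate"]
            )
        if config.clinical_path:
            clinical = read_cohort(config.clinical_path)
        else:
            pieces = []
            for i, (group, spec) in enumerate(sorted(config.clinical_groups.items())):
                ccfg = ClinicalCohortConfig(
                    group=group,
                    n=spec.get("n", 30),
                    pad_shift=spec.get("pad_shift", 0.0),
                    jitter_sd=spec.get("jitter_sd", 2.0),
                    deviant_features=spec.get("deviant_features", {}) or {},
                    clinical_coupling=(
                        spec.get("clinical_coupling")
                        or (default_clinical_coupling(spec.get("jitter_sd", 2.0))
                            if group != "HC" else {})
                    ),
                )
                pieces.append(
                    generate_clinical_cohort(
                        ccfg, trajectory, seed=config.seeds["simulate"] + 1000 + i
                    )
                )
            participants = pd.concat([c.participants for c in pieces], ignore_index=True)
            tables = {}
            for panel in pieces[0].tables:
                from .cohort import FeatureTable

                vals = pd.concat([c.tables[panel].values for c in pieces])
                tables[panel] = FeatureTable(pieces[0].tables[panel].descriptors, vals)
            clinical = Cohort(participants, tables)
        write_cohort(train, out / "train_cohort")
        write_cohort(clinical, out / "clinical_cohort")
        report["stages"][name] = {
            "status": "done", "train_n": len(train.participants),
            "clinical_n": len(clinical.participants),
        }

        groups = clinical.participants["group"].to_numpy()
        hc_mask = groups == config.reference_group
        covs = _covariate_frame(clinical.participants, config.covariates)

        pad_frames = []
        for modality in config.modalities:
            # ---- train ---------------------------------------------------
            name = stage(f"train_{modality}")
            model = BrainAgeModel(
                modality=modality, random_state=config.seeds["train"], **config.model
            ).fit(train.tables[modality], train.ages, train.sex_codes)
            model.save(out / f"model_{modality.lower()}.json")
            entry = {"status": "done", "n_iter": model.net_.n_iter_}
            if config.cv_k and config.cv_k >= 2:
                cv = cross_validate(
                    train.tables[modality], train.ages, train.sex_codes,
                    k=config.cv_k, modality=modality, seed=config.seeds["cv"],
                    **config.model,
                )
                entry["cv"] = {
                    "k": cv.k, "pooled_r": cv.pooled_r, "pooled_mae": cv.pooled_mae,
                    "fold_r": cv.fold_r, "fold_mae": cv.fold_mae,
                }
            report["stages"][name] = entry

            # ---- PAD + bias correction ----------------------------------
            name = stage(f"pad_{modality}")
            predicted = model.predict(clinical.tables[modality], clinical.sex_codes)
            pad = compute_pad(predicted, clinical.ages)
            corrector = PadBiasCorrector(reference=config.reference_group).fit(
                pad[hc_mask], clinical.ages[hc_mask]
            )
            corrected = corrector.transform(pad, clinical.ages)
            pad_frames.append(
                pd.DataFrame(
                    {
                        "id": clinical.ids, "modality": modality,
                        "predicted_age": predicted, "pad": pad,
                        "corrected_pad": corrected,
                    }
                )
            )
            report["stages"][name] = {
                "status": "done",
                "bias_slope": corrector.slope_, "bias_intercept": corrector.intercept_,
                "group_mean_corrected_pad": {
                    g: float(np.mean(corrected[groups == g])) for g in np.unique(groups)
                },
            }

        pad_table = pd.concat(pad_frames, ignore_index=True)
        pad_table.to_csv(out / "pad.csv", index=False)

        # ---- normative + Z ----------------------------------------------
        zscores: Dict[str, pd.DataFrame] = {}
        kernel_cfg = NormativeKernelConfig(**config.kernel)
        for modality in config.modalities:
            name = stage(f"normative_{modality}")
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                nset = NormativeModelSet(kernel_cfg, seed=config.seeds["normative"]).fit(
                    train.tables[modality], train.ages, train.sex_codes
                )
                Z = nset.transform(
                    clinical.tables[modality], clinical.ages, clinical.sex_codes
                )
            report["warnings"] += [str(w.message) for w in caught]
            nset.save(out / f"norms_{modality.lower()}.json")
            Z.to_csv(out / f"zscores_{modality.lower()}.csv", index_label="id")
            zscores[modality] = Z
            report["stages"][name] = {"status": "done", "n_models": len(nset.models_)}

        # ---- contribution ------------------------------------------------
        name = stage("contribution")
        mm_cfg = MMConfig(**{**{"seed": config.seeds["contribution"]}, **config.mm})
        contrib: Dict[str, dict] = {}
        profiles: Dict[str, dict] = {}
        for modality in config.modalities:
            profiles[modality] = {}
            corrected = pad_table[pad_table["modality"] == modality].set_index("id")
            for group in np.unique(groups):
                mask = groups == group
                ids = clinical.participants.loc[mask, "id"]
                prof = contribution_profile(
                    zscores[modality].loc[ids],
                    corrected.loc[ids, "corrected_pad"].to_numpy(),
                    group=group, modality=modality, mm_config=mm_cfg,
                )
                profiles[modality][group] = prof
                prof.table.to_csv(out / f"contrib_{modality.lower()}_{group.lower()}.csv")
            entry = {"top": {}, "aggregate": {}}
            for group, prof in profiles[modality].items():
                entry["top"][group] = rank_top(prof, config.top_k)
                entry["aggregate"][group] = aggregate_by_region(
                    prof, clinical.tables[modality].descriptors
                ).to_dict(orient="records")
            pair = [g for g in ("MSA", "PD") if g in profiles[modality]]
            if len(pair) == 2:
                delta = delta_effect_size(
                    profiles[modality]["MSA"], profiles[modality]["PD"],
                    profiles[modality].get(config.reference_group),
                    threshold=config.delta_threshold,
                )
                delta.table.to_csv(out / f"delta_es_{modality.lower()}.csv")
                entry["delta_selected"] = delta.selected_features()
            contrib[modality] = entry
        report["stages"][name] = {"status": "done", **contrib}

        # ---- statistics ---------------------------------------------------
        name = stage("stats")
        stats_entry: dict = {}
        for modality in config.modalities:
            sub = pad_table[pad_table["modality"] == modality]
            y = sub.set_index("id").loc[clinical.ids, "corrected_pad"].to_numpy()
            comp = ancova_compare(y, groups, covs)
            stats_entry[f"ancova_{modality}"] = comp.to_dict()
            if config.exclude_lowest_counts:
                mask = exclude_lowest(y, groups, config.exclude_lowest_counts)
                comp_ex = ancova_compare(y[mask], groups[mask], covs.loc[mask])
                stats_entry[f"ancova_{modality}_after_exclusion"] = {
                    "n_excluded": int((~mask).sum()), **comp_ex.to_dict()
                }
        if set(config.modalities) >= {"GM", "WM"}:
            gm = pad_table[pad_table["modality"] == "GM"].set_index("id")
            wm = pad_table[pad_table["modality"] == "WM"].set_index("id")
            rhos = {}
            for group in np.unique(groups):
                ids = clinical.participants.loc[groups == group, "id"]
                rho, p = partial_correlation(
                    gm.loc[ids, "corrected_pad"], wm.loc[ids, "corrected_pad"],
                    covs.loc[(groups == group)],
                )
                rhos[group] = {"rho": rho, "p": p, "n": len(ids)}
            stats_entry["gm_wm_partial_correlation"] = rhos
            pairs = [(a, b) for i, a in enumerate(sorted(rhos)) for b in sorted(rhos)[i + 1:]]
            stats_entry["correlation_comparisons"] = {
                f"{a}_vs_{b}": dict(
                    zip(("z", "p"), compare_correlations(
                        rhos[a]["rho"], rhos[a]["n"], rhos[b]["rho"], rhos[b]["n"]
                    ))
                )
                for a, b in pairs
            }
        assoc = clinical_associations(
            pad_table, clinical.participants, config.clinical_scores,
            covariate_names=config.covariates,
        )
        stats_entry["clinical_associations"] = assoc.to_dict(orient="records")
        report["stages"][name] = {"status": "done", **stats_entry}

    except Exception as exc:
        failed = [k for k, v in report["stages"].items() if v.get("status") == "running"]
        stage_name = failed[0] if failed else "unknown"
        report["stages"].setdefault(stage_name, {})["status"] = "failed"
        report["stages"][stage_name]["error"] = str(exc)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
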