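"""Participant tables, feature tables, and their delimited-text round trip.

A cohort is a participants table (id, age, sex, education, group, optional
clinical scores, optional ground-truth brain-age offset) plus one feature
table per modality panel.  Everything is stored as plain CSV: one
``participants.csv`` and, per panel, ``<panel>_features.csv`` (wide,
keyed by id) and ``<panel>_descriptors.csv`` (feature metadata).

Units: volumes in mL, cortical thickness in mm, GFA unitless in (0, 1),
MD in 1e-3 mm^2/s.  Sex is stored as ``male``/``female`` and encoded
numerically as female=0, male=1 everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .features import (
    GM_N_THICKNESS,
    GM_N_VOLUME,
    WM_N_TRACTS,
    FeatureDescriptor,
    descriptors_to_frame,
    frame_to_descriptors,
)

SEX_CODES = {"female": 0, "male": 1}
GROUPS = ("TRAIN", "TEST", "HC", "MSA", "PD")
CLINICAL_SCORES = (
    "UPDRS_I",
    "UPDRS_II",
    "UPDRS_III",
    "UPDRS_total",
    "UMSARS_I",
    "UMSARS_II",
    "UMSARS_total",
    "HY",
    "MMSE",
    "MoCA",
)

_PARTICIPANT_COLUMNS = ["id", "age", "sex", "education", "group"]


def sex_to_code(sex) -> np.ndarray:
    """Map 'female'/'male' labels (or 0/1 already) to the 0/1 encoding."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "OU":
        try:
            return np.array([SEX_CODES[str(s)] for s in arr], dtype=float)
        except KeyError as exc:
            raise ValueError(f"unknown sex label {exc.args[0]!r}") from exc
    return arr.astype(float)


@dataclass
class FeatureTable:
    """Participants x regional-features matrix with feature metadata.

    ``values`` is a pandas DataFrame indexed by participant id with one
    column per feature, ordered as ``descriptors``.
    """

    descriptors: List[FeatureDescriptor]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in descriptor list")
        if list(self.values.columns) != names:
            raise ValueError("feature-table columns do not match descriptor order")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing values in feature column {bad!r}")
        self.validate()

    @property
    def feature_names(self) -> List[str]:
        return list(self.values.columns)

    @property
    def participant_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def panel(self) -> str:
        """'GM' or 'WM' according to the modalities present."""
        mods = {d.modality for d in self.descriptors}
        if mods <= {"GM_volume", "GM_thickness"}:
            return "GM"
        if mods <= {"WM_GFA", "WM_MD"}:
            return "WM"
        raise ValueError("mixed GM/WM modalities in one table")

    def validate(self) -> None:
        counts: Dict[str, int] = {}
        for d in self.descriptors:
            counts[d.modality] = counts.get(d.modality, 0) + 1
        panel = self.panel
        if len(self.values):  # value-range checks are vacuous when empty
            arr = self.values.to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError("non-finite feature values")
        if panel == "GM":
            if counts.get("GM_volume", 0) != GM_N_VOLUME:
                raise ValueError(
                    f"GM table needs {GM_N_VOLUME} volume features, "
                    f"got {counts.get('GM_volume', 0)}"
                )
            if counts.get("GM_thickness", 0) != GM_N_THICKNESS:
                raise ValueError(
                    f"GM table needs {GM_N_THICKNESS} thickness features, "
                    f"got {counts.get('GM_thickness', 0)}"
                )
        else:
            for m in ("WM_GFA", "WM_MD"):
                if counts.get(m, 0) != WM_N_TRACTS:
                    raise ValueError(
                        f"WM table needs {WM_N_TRACTS} {m} features, got {counts.get(m, 0)}"
                    )
        if len(self.values):
            for d in self.descriptors:
                col = self.values[d.name].to_numpy(dtype=float)
                if d.modality == "WM_GFA":
                    if (col <= 0).any() or (col >= 1).any():
                        raise ValueError(f"GFA feature {d.name!r} outside (0, 1)")
                elif d.modality in ("GM_volume", "WM_MD"):
                    if (col <= 0).any():
                        raise ValueError(f"{d.name!r} must be strictly positive")

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, ids) -> "FeatureTable":
        return FeatureTable(self.descriptors, self.values.loc[list(ids)])


@dataclass
class Cohort:
    """A participants table plus the GM and/or WM feature tables."""

    participants: pd.DataFrame
    tables: Dict[str, FeatureTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _PARTICIPANT_COLUMNS if c not in self.participants.columns]
        if missing:
            raise ValueError(f"participants table missing columns: {missing}")
        ids = self.participants["id"]
        if ids.duplicated().any():
            raise ValueError("participant ids are not unique")
        bad_sex = set(self.participants["sex"]) - set(SEX_CODES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        bad_grp = set(self.participants["group"]) - set(GROUPS)
        if bad_grp:
            raise ValueError(f"unknown group labels: {sorted(bad_grp)}")
        for panel, table in self.tables.items():
            if list(table.values.index) != list(ids):
                raise ValueError(f"{panel} feature table ids do not match participants")

    @property
    def ids(self) -> List[str]:
        return list(self.participants["id"])

    @property
    def ages(self) -> np.ndarray:
        return self.participants["age"].to_numpy(dtype=float)

    @property
    def sex_codes(self) -> np.ndarray:
        return sex_to_code(self.participants["sex"])

    @property
    def true_delta(self) -> Optional[np.ndarray]:
        """Ground-truth brain-age offsets when the cohort is synthetic."""
        if "true_delta" in self.participants.columns:
            return self.participants["true_delta"].to_numpy(dtype=float)
        return None

    def subset(self, mask) -> "Cohort":
        part = self.participants.loc[np.asarray(mask)].reset_index(drop=True)
        tables = {p: t.subset(part["id"]) for p, t in self.tables.items()}
        return Cohort(part, tables)


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write a cohort to a directory of delimited-text files (full precision)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # %.17g makes the float64 text form exactly round-trippable
    cohort.participants.to_csv(
        path / "participants.csv", sep=sep, index=False, float_format="%.17g"
    )
    for panel, table in cohort.tables.items():
        tag = panel.lower()
        table.values.to_csv(
            path / f"{tag}_features.csv", sep=sep, index=True, index_label="id",
            float_format="%.17g",
        )
        descriptors_to_frame(table.descriptors).to_csv(
            path / f"{tag}_descriptors.csv", sep=sep, index=False
        )


def _read_numeric(path, sep) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, index_col="id", float_precision="round_trip")
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = frame.index[vals.isna().to_numpy()][0]
            raise ValueError(
                f"non-numeric or missing cell in {path.name}: row {row!r}, column {col!r}"
            )
        frame[col] = vals
    return frame


def read_cohort(path, sep: str = ",") -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    pfile = path / "participants.csv"
    if not pfile.exists():
        raise FileNotFoundError(f"no participants.csv in {path}")
    participants = pd.read_csv(pfile, sep=sep, float_precision="round_trip")
    tables: Dict[str, FeatureTable] = {}
    for tag, panel in (("gm", "GM"), ("wm", "WM")):
        ffile = path / f"{tag}_features.csv"
        dfile = path / f"{tag}_descriptors.csv"
        if not ffile.exists():
            continue
        descriptors = frame_to_descriptors(pd.read_csv(dfile, sep=sep))
        values = _read_numeric(ffile, sep)
        missing = [d.name for d in descriptors if d.name not in values.columns]
        if missing:
            raise ValueError(f"{ffile.name} missing feature column(s): {missing}")
        values = values[[d.name for d in descriptors]]
        values.index = values.index.astype(str)
        values.index.name = None
        tables[panel] = FeatureTable(descriptors, values)
    participants["id"] = participants["id"].astype(str)
    return Cohort(participants, tables)
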