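"""Feature contributions to brain age: robust Z-vs-PAD effect sizes.

Within a clinical group, each regional feature's contribution to the
brain-age gap is scored as the robust (MM-estimate) effect size of the
linear association between that feature's normative Z-score and the
participant's corrected PAD.  Profiles are ranked by |ES|, differenced
between groups (ΔES, with |ΔES| > 0.3 flagging a medium between-group
difference), and aggregated into percent contributions per macroscopic
region group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureDescriptor
from .robust import MMConfig, robust_effect_size


@dataclass
class ContributionProfile:
    """Per-feature robust effect sizes for one group and modality panel."""

    group: str
    modality: str
    table: pd.DataFrame  # index: feature; columns: es, degenerate, n

    @property
    def es(self) -> pd.Series:
        return self.table["es"]


def contribution_profile(
    zscores: pd.DataFrame,
    pads: np.ndarray,
    group: str = "",
    modality: str = "",
    mm_config: Optional[MMConfig] = None,
) -> ContributionProfile:
    """Robust effect size of each feature's Z-score against the PAD vector.

    ``zscores`` rows must be aligned with ``pads`` (one participant each).
    Degenerate features (zero spread) are flagged, not dropped.
    """
    pads = np.asarray(pads, dtype=float)
    if len(zscores) != len(pads):
        raise ValueError(
            f"participant misalignment: {len(zscores)} Z rows vs {len(pads)} PADs"
        )
    rows = []
    for name in zscores.columns:
        z = zscores[name].to_numpy(dtype=float)
        if np.ptp(z) == 0:
            rows.append({"feature": name, "es": np.nan, "degenerate": True, "n": len(z)})
            continue
        es, flags = robust_effect_size(z, pads, mm_config)
        rows.append(
            {"feature": name, "es": es, "degenerate": flags["degenerate"], "n": flags["n"]}
        )
    table = pd.DataFrame(rows).set_index("feature")
    return ContributionProfile(group, modality, table)


def rank_top(profile: ContributionProfile, k: int = 20) -> List[str]:
    """Top-k feature names by |ES|, descending; ties broken by name."""
    es = profile.es.dropna()
    order = sorted(es.index, key=lambda f: (-abs(es[f]), f))
    return order[:k]


@dataclass
class DeltaESTable:
    """Between-group effect-size differences with the selection rule."""

    group_a: str
    group_b: str
    threshold: float
    table: pd.DataFrame  # columns: es_a, es_b, es_ref, delta_es, selected

    def selected_features(self) -> List[str]:
        return self.table.index[self.table["selected"]].tolist()


def delta_effect_size(
    profile_a: ContributionProfile,
    profile_b: ContributionProfile,
    profile_ref: Optional[ContributionProfile] = None,
    threshold: float = 0.3,
) -> DeltaESTable:
    """Signed ΔES = ES_A − ES_B per feature; |ΔES| > threshold selects.

    The reference-group profile (typically healthy controls) is carried
    along for reporting but does not influence selection.
    """
    a, b = profile_a.es, profile_b.es
    if list(a.index) != list(b.index):
        raise ValueError("profiles cover different feature sets")
    ref = profile_ref.es if profile_ref is not None else pd.Series(np.nan, index=a.index)
    if profile_ref is not None and list(ref.index) != list(a.index):
        raise ValueError("reference profile covers a different feature set")
    delta = a - b
    table = pd.DataFrame(
        {
            "es_a": a,
            "es_b": b,
            "es_ref": ref,
            "delta_es": delta,
            "selected": delta.abs() > threshold,
        }
    )
    return DeltaESTable(profile_a.group, profile_b.group, threshold, table)


def aggregate_by_region(
    profile: ContributionProfile,
    descriptors: Sequence[FeatureDescriptor],
    by: str = "region_group",
) -> pd.DataFrame:
    """Percent contribution per region group (or hemisphere), by feature type.

    Within each feature modality, percent = 100 * sum(|ES|) in the region
    group / sum(|ES|) over all features of that modality.  Percents sum to
    100 per modality (up to NaN-degenerate features, which are excluded).
    """
    if by not in ("region_group", "hemisphere"):
        raise ValueError("by must be 'region_group' or 'hemisphere'")
    meta = {d.name: d for d in descriptors}
    missing = [f for f in profile.es.index if f not in meta]
    if missing:
        raise ValueError(f"descriptors missing for feature(s): {missing[:5]}")
    rows = []
    frame = profile.table.copy()
    frame["modality"] = [meta[f].modality for f in frame.index]
    frame["cat"] = [getattr(meta[f], by) for f in frame.index]
    frame["abs_es"] = frame["es"].abs()
    for modality, sub in frame.groupby("modality"):
        total = sub["abs_es"].sum(skipna=True)
        if not total > 0:
            rows.append({"modality": modality, by: "(all)", "percent": np.nan,
                         "flag": "all-zero profile"})
            continue
        for cat, catsub in sub.groupby("cat"):
            rows.append(
                {"modality": modality, by: cat,
                 "percent": 100.0 * catsub["abs_es"].sum(skipna=True) / total,
                 "flag": ""}
            )
    return pd.DataFrame(rows)
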