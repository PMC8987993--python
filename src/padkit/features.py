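"""Regional feature catalogues for the two modality panels.

The gray-matter (GM) panel pairs 56 regional volumes (an LPBA-style
whole-brain parcellation, cortical plus subcortical) with 68 cortical
thicknesses (a Desikan-Killiany-style surface parcellation, 34 regions per
hemisphere), for 124 features.  The white-matter (WM) panel carries
generalized fractional anisotropy (GFA) and mean diffusivity (MD) averaged
over 45 major fiber-tract bundles each, for 90 features.

Every feature carries a ``region_group`` used when contributions are
aggregated macroscopically: a lobe for GM (frontal / parietal / temporal /
occipital / other) and a fiber system for WM (association / callosal /
projection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import pandas as pd

MODALITIES = ("GM_volume", "GM_thickness", "WM_GFA", "WM_MD")
GM_N_VOLUME = 56
GM_N_THICKNESS = 68
WM_N_TRACTS = 45

HEMISPHERES = ("left", "right", "midline")
GM_REGION_GROUPS = ("frontal", "parietal", "temporal", "occipital", "other")
WM_REGION_GROUPS = ("association", "callosal", "projection")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Metadata for one regional feature.

    Parameters
    ----------
    name : str
        Unique feature name, e.g. ``"Vol L Mid OrbFron Gy"``.
    modality : str
        One of ``GM_volume``, ``GM_thickness``, ``WM_GFA``, ``WM_MD``.
    region_group : str
        Lobe (GM) or fiber system (WM) used for macroscopic aggregation.
    hemisphere : str
        ``left``, ``right`` or ``midline``.
    """

    name: str
    modality: str
    region_group: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        groups = GM_REGION_GROUPS if self.modality.startswith("GM") else WM_REGION_GROUPS
        if self.region_group not in groups:
            raise ValueError(
                f"region_group {self.region_group!r} invalid for {self.modality}"
            )


# (region, lobe) pairs; 27 bilateral structures + 2 midline = 56 volumes.
_VOLUME_REGIONS = [
    ("Sup Fron Gy", "frontal"),
    ("Mid Fron Gy", "frontal"),
    ("Inf Fron Gy", "frontal"),
    ("PreCen Gy", "frontal"),
    ("Mid OrbFron Gy", "frontal"),
    ("Lat OrbFron Gy", "frontal"),
    ("Gy Rectus", "frontal"),
    ("PostCen Gy", "parietal"),
    ("Sup Parie Gy", "parietal"),
    ("SupraMar Gy", "parietal"),
    ("Angular Gy", "parietal"),
    ("PreCuneus", "parietal"),
    ("Sup Occi Gy", "occipital"),
    ("Mid Occi Gy", "occipital"),
    ("Inf Occi Gy", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual Gy", "occipital"),
    ("Sup Temp Gy", "temporal"),
    ("Mid Temp Gy", "temporal"),
    ("Inf Temp Gy", "temporal"),
    ("ParaHip Gy", "temporal"),
    ("Hippocampus", "temporal"),
    ("Fusiform Gy", "temporal"),
    ("Insula", "other"),
    ("Cingulate Gy", "other"),
    ("Caudate", "other"),
    ("Putamen", "other"),
]
_VOLUME_MIDLINE = [("Brainstem", "other"), ("Cerebellum", "other")]

# 34 regions per hemisphere (Desikan-Killiany-style) = 68 thicknesses.
_THICKNESS_REGIONS = [
    ("Sup Fron Gy", "frontal"),
    ("Ros Mid Fron Gy", "frontal"),
    ("Caud Mid Fron Gy", "frontal"),
    ("Pars Oper", "frontal"),
    ("Pars Tri", "frontal"),
    ("Pars Orb", "frontal"),
    ("Lat OrbFron Gy", "frontal"),
    ("Med OrbFron Gy", "frontal"),
    ("PreCen Gy", "frontal"),
    ("ParaCen Lob", "frontal"),
    ("Fron Pole", "frontal"),
    ("PostCen Gy", "parietal"),
    ("Sup Parie Gy", "parietal"),
    ("Inf Parie Gy", "parietal"),
    ("SupraMar Gy", "parietal"),
    ("PreCuneus", "parietal"),
    ("Lat Occi Gy", "occipital"),
    ("Lingual Gy", "occipital"),
    ("Cuneus", "occipital"),
    ("PeriCalc", "occipital"),
    ("Sup Temp Gy", "temporal"),
    ("Mid Temp Gy", "temporal"),
    ("Inf Temp Gy", "temporal"),
    ("Banks STS", "temporal"),
    ("Fusiform Gy", "temporal"),
    ("Trans Temp Gy", "temporal"),
    ("Entorhinal", "temporal"),
    ("Temp Pole", "temporal"),
    ("ParaHip Gy", "temporal"),
    ("Ros Ant Cing", "other"),
    ("Caud Ant Cing", "other"),
    ("Post Cing", "other"),
    ("Isth Cing", "other"),
    ("Insula", "other"),
]

# 45 tract bundles: 7 callosal (midline) + 11 association pairs + 8 projection pairs.
_TRACT_MIDLINE = [
    ("CC Genu", "callosal"),
    ("CC PreMotor", "callosal"),
    ("CC Motor", "callosal"),
    ("CC Parie", "callosal"),
    ("CC Temp", "callosal"),
    ("CC Occi", "callosal"),
    ("CC Sple", "callosal"),
]
_TRACT_BILATERAL = [
    ("UF", "association"),
    ("ILF", "association"),
    ("IFOF", "association"),
    ("SLF", "association"),
    ("AF", "association"),
    ("CG Cing", "association"),
    ("CG Hip", "association"),
    ("MdLF", "association"),
    ("VOF", "association"),
    ("FAT", "association"),
    ("Extreme Caps", "association"),
    ("TR PreFron", "projection"),
    ("TR SM", "projection"),
    ("TR Aud", "projection"),
    ("TR Opt", "projection"),
    ("TR Parie", "projection"),
    ("CST", "projection"),
    ("Fornix", "projection"),
    ("Cereb Ped", "projection"),
]

assert len(_VOLUME_REGIONS) * 2 + len(_VOLUME_MIDLINE) == GM_N_VOLUME
assert len(_THICKNESS_REGIONS) * 2 == GM_N_THICKNESS
assert len(_TRACT_MIDLINE) + len(_TRACT_BILATERAL) * 2 == WM_N_TRACTS


def _bilateral(regions, modality, prefix):
    out = []
    for side, hemi in (("L", "left"), ("R", "right")):
        for region, group in regions:
            out.append(
                FeatureDescriptor(f"{prefix} {side} {region}", modality, group, hemi)
            )
    return out


def gm_descriptors() -> List[FeatureDescriptor]:
    """The 124-feature gray-matter panel (56 volumes then 68 thicknesses)."""
    vols = _bilateral(_VOLUME_REGIONS, "GM_volume", "Vol")
    vols += [
        FeatureDescriptor(f"Vol {r}", "GM_volume", g, "midline")
        for r, g in _VOLUME_MIDLINE
    ]
    cts = _bilateral(_THICKNESS_REGIONS, "GM_thickness", "CT")
    return vols + cts


def wm_descriptors() -> List[FeatureDescriptor]:
    """The 90-feature white-matter panel (45 GFA then 45 MD tract averages)."""
    out = []
    for metric, modality in (("GFA", "WM_GFA"), ("MD", "WM_MD")):
        out += [
            FeatureDescriptor(f"{metric} {t}", modality, g, "midline")
            for t, g in _TRACT_MIDLINE
        ]
        out += _bilateral(_TRACT_BILATERAL, modality, metric)
    return out


def descriptors_to_frame(descriptors: List[FeatureDescriptor]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [d.name for d in descriptors],
            "modality": [d.modality for d in descriptors],
            "region_group": [d.region_group for d in descriptors],
            "hemisphere": [d.hemisphere for d in descriptors],
        }
    )


def frame_to_descriptors(frame: pd.DataFrame) -> List[FeatureDescriptor]:
    required = {"name", "modality", "region_group", "hemisphere"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    return [
        FeatureDescriptor(r.name, r.modality, r.region_group, r.hemisphere)
        for r in frame.itertuples(index=False)
    ]
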