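"""Cortical region-of-interest vocabularies, region sets and pathways.

ROI names are normalised to lower-case snake_case. An alias map covers the
common Desikan-Killiany abbreviations and a handful of Destrieux-style
labels so that morphometry tables produced by different tools can be joined.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import TwinscopeError


ROI_ALIASES = {
    # Desikan-Killiany abbreviations
    "bankssts": "banks_superior_temporal",
    "banks_sts": "banks_superior_temporal",
    "banks_of_superior_temporal_sulcus": "banks_superior_temporal",
    "banks_superior_temporal_sulcus": "banks_superior_temporal",
    "transversetemporal": "transverse_temporal",
    "heschl": "transverse_temporal",
    "heschls_gyrus": "transverse_temporal",
    "superiortemporal": "superior_temporal",
    "supramarginal_gyrus": "supramarginal",
    "angular_gyrus": "angular",
    "fusiform_gyrus": "fusiform",
    "inferior_occipital_gyrus": "inferior_occipital",
    "inferiorparietal": "inferior_parietal",
    "parsopercularis": "pars_opercularis",
    "parstriangularis": "pars_triangularis",
    "parsorbitalis": "pars_orbitalis",
    "inferior_frontal_gyrus_pars_opercularis": "pars_opercularis",
    "inferior_frontal_gyrus_pars_triangularis": "pars_triangularis",
    "inferior_frontal_gyrus_pars_orbitalis": "pars_orbitalis",
    # Destrieux-style labels
    "g_temp_sup": "superior_temporal",
    "g_temp_sup_g_t_transv": "transverse_temporal",
    "g_temp_sup_plan_tempo": "planum_temporale",
    "g_temp_sup_plan_polar": "planum_polare",
    "g_pariet_inf_supramar": "supramarginal",
    "g_pariet_inf_angular": "angular",
    "g_occipital_inf": "inferior_occipital",
    "g_oc_temp_lat_fusifor": "fusiform",
    "g_front_inf_opercular": "pars_opercularis",
    "g_front_inf_triangul": "pars_triangularis",
    "g_front_inf_orbital": "pars_orbitalis",
}


def canonical_roi(name: str) -> str:
    """Normalise an ROI name to its canonical snake_case key."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_").replace(".", "_")
    while "__" in key:
        key = key.replace("__", "_")
    return ROI_ALIASES.get(key, key)


@dataclass(frozen=True)
class RegionSet:
    name: str
    rois: tuple[str, ...]

    def __post_init__(self):
        if len(self.rois) == 0:
            raise TwinscopeError(f"region set {self.name!r} is empty")
        object.__setattr__(self, "rois", tuple(canonical_roi(r) for r in self.rois))

    def __len__(self) -> int:
        return len(self.rois)

    def __contains__(self, roi: str) -> bool:
        return canonical_roi(roi) in self.rois


#: The seven reading-related parcels used for the focused ICC analyses.
READING_SET = RegionSet(
    "reading",
    (
        "fusiform",
        "inferior_parietal",
        "banks_superior_temporal",
        "pars_opercularis",
        "pars_triangularis",
        "supramarginal",
        "transverse_temporal",
    ),
)

#: Desikan-Killiany cortical parcellation (34 parcels per hemisphere),
#: the default "whole cortex" region set for simulated morphometry.
DESIKAN_ROIS = (
    "banks_superior_temporal",
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "parahippocampal",
    "paracentral",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "pericalcarine",
    "postcentral",
    "posterior_cingulate",
    "precentral",
    "precuneus",
    "rostral_anterior_cingulate",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_parietal",
    "superior_temporal",
    "supramarginal",
    "frontal_pole",
    "temporal_pole",
    "transverse_temporal",
    "insula",
)

WHOLE_CORTEX_SET = RegionSet("whole_cortex", DESIKAN_ROIS)

#: The seven parcels tabulated in the asymmetry analysis.
ASYMMETRY_ROIS = (
    "fusiform",
    "banks_superior_temporal",
    "pars_opercularis",
    "pars_triangularis",
    "supramarginal",
    "transverse_temporal",
    "superior_temporal",
)


@dataclass(frozen=True)
class PathwayDefinition:
    """A reading-network pathway: a named group of ROIs whose pairwise
    intra-subject comparisons are enumerated in the image analysis."""

    name: str
    function: str
    rois: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "rois", tuple(canonical_roi(r) for r in self.rois))


VENTRAL_PATHWAY = PathwayDefinition(
    "ventral",
    "phonological processing",
    ("inferior_occipital", "fusiform"),
)
FRONTAL_PATHWAY = PathwayDefinition(
    "frontal",
    "attention and verbalization",
    ("pars_orbitalis", "pars_triangularis", "pars_opercularis"),
)
DORSAL_PATHWAY = PathwayDefinition(
    "dorsal",
    "automatic word recognition",
    (
        "supramarginal",
        "angular",
        "superior_temporal",
        "transverse_temporal",
        "planum_temporale",
        "planum_polare",
    ),
)

DEFAULT_PATHWAYS = (VENTRAL_PATHWAY, FRONTAL_PATHWAY, DORSAL_PATHWAY)

#: Union of all pathway ROIs — the eleven parcels entering the mask/luminosity
#: analysis.
PATHWAY_ROIS = tuple(
    dict.fromkeys(r for p in DEFAULT_PATHWAYS for r in p.rois)
)

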