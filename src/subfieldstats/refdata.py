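"""Reference data: region naming across FreeSurfer versions and default
simulation parameters.

FreeSurfer's v5.3 subfield module labels eight hippocampal subregions;
the v6.0 module labels twelve, with revised boundary definitions.  The
harmonization map below records which v5.3 region(s) each v6.0 region
is compared against in a between-version agreement analysis.  The three
cornu-ammonis sectors are cross-compared against all three v5.3 CA
labels (CA1, CA2_3, CA4_DG) because the v6.0 boundary revision moved
tissue between sectors; the four regions new in v6.0 (parasubiculum,
molecular layer, GC-ML-DG, HATA) have no v5.3 counterpart.
"""

from __future__ import annotations

# v6.0 region -> list of v5.3 regions it is paired with (order = report
# column order).  Regions absent from the map have no v5.3 counterpart.
V6_TO_V53_PAIRING: dict[str, list[str]] = {
    "hippocampal_tail": ["hippocampal_tail"],
    "CA1": ["CA1", "CA2_3", "CA4_DG"],
    "CA3": ["CA1", "CA2_3", "CA4_DG"],
    "CA4": ["CA1", "CA2_3", "CA4_DG"],
    "fimbria": ["fimbria"],
    "fissure": ["fissure"],
    "presubiculum": ["presubiculum"],
    "subiculum": ["subiculum"],
}

V53_REGIONS = [
    "hippocampal_tail", "CA1", "CA2_3", "CA4_DG",
    "fimbria", "fissure", "presubiculum", "subiculum",
]

V6_ONLY_REGIONS = ["parasubiculum", "molecular_layer", "GC_ML_DG", "HATA"]

V6_REGIONS = list(V6_TO_V53_PAIRING) + V6_ONLY_REGIONS

# The hippocampal fissure is a CSF cleft, not tissue; by default it is
# excluded from whole-structure overlap and volume summaries.
NON_TISSUE_REGIONS = ("fissure",)

# Default per-region simulation parameters: bilateral mean volume (mm^3)
# at the scale of a young-adult cohort, total phenotypic SD (mm^3), and
# true narrow-sense heritability.  SD defaults to 12% of the mean, a
# typical coefficient of variation for automated subfield volumes.
#
# (mean_mm3, sd_mm3, h2)
DEFAULT_REGION_PARAMS: dict[str, tuple[float, float, float]] = {
    "whole_hippocampus": (3200.0, 384.0, 0.88),
    "molecular_layer": (520.0, 62.4, 0.85),
    "CA1": (590.0, 70.8, 0.84),
    "hippocampal_tail": (510.0, 61.2, 0.84),
    "GC_ML_DG": (283.0, 34.0, 0.82),
    "CA4": (247.0, 29.6, 0.79),
    "subiculum": (388.0, 46.6, 0.76),
    "CA3": (212.0, 25.4, 0.75),
    "presubiculum": (284.0, 34.1, 0.72),
    "HATA": (56.0, 6.7, 0.67),
    "fimbria": (55.0, 6.6, 0.64),
    "parasubiculum": (61.0, 7.3, 0.57),
    "fissure": (161.0, 19.3, 0.56),
}

# Published trans-platform (1.5 T vs 3 T) ICC values for the two
# algorithm versions, used as demonstration input for median-ICC
# summaries.  The v5.3 module segments 9 (sub)regions, v6.0 thirteen.
TRANS_PLATFORM_ICC_V53: dict[str, float] = {
    "whole_hippocampus": 0.855,
    "CA1": 0.725,
    "CA2_3": 0.856,
    "CA4_DG": 0.892,
    "fimbria": 0.720,
    "fissure": 0.465,
    "presubiculum": 0.818,
    "subiculum": 0.866,
    "hippocampal_tail": 0.875,
}

TRANS_PLATFORM_ICC_V60: dict[str, float] = {
    "whole_hippocampus": 0.960,
    "CA1": 0.915,
    "CA2_3": 0.871,
    "CA4_DG": 0.792,
    "fimbria": 0.721,
    "fissure": 0.575,
    "presubiculum": 0.853,
    "subiculum": 0.858,
    "hippocampal_tail": 0.863,
    "parasubiculum": 0.659,
    "GC_ML_DG": 0.828,
    "molecular_layer": 0.932,
    "HATA": 0.801,
}
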