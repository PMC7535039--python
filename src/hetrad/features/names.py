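"""Canonical names and ordering of the 47 radiomic features.

Seven first-order intensity-histogram features plus 40 texture features
from four matrix families: gray-level co-occurrence (GLCM, 9), gray-level
run length (GLRLM, 13), gray-level size zone (GLSZM, 13) and neighbourhood
gray-tone difference (NGTDM, 5).  The order here fixes CSV column order.
"""

INTENSITY_FEATURES = (
    "Intensity_Mean",
    "Intensity_Variance",
    "Intensity_Skewness",
    "Intensity_Kurtosis",
    "Intensity_MAD",
    "Intensity_Hyperskewness",
    "Intensity_Hyperflatness",
)

GLCM_FEATURES = (
    "GLCM_Energy",
    "GLCM_Contrast",
    "GLCM_Entropy",
    "GLCM_Homogeneity",
    "GLCM_Correlation",
    "GLCM_SumAverage",
    "GLCM_Variation",
    "GLCM_Dissimilarity",
    "GLCM_AutoCorrelation",
)

GLRLM_FEATURES = (
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_GLN",
    "GLRLM_RLN",
    "GLRLM_RP",
    "GLRLM_LGRE",
    "GLRLM_HGRE",
    "GLRLM_SRLGE",
    "GLRLM_SRHGE",
    "GLRLM_LRLGE",
    "GLRLM_LRHGE",
    "GLRLM_GLV",
    "GLRLM_RLV",
)

GLSZM_FEATURES = (
    "GLSZM_SZE",
    "GLSZM_LZE",
    "GLSZM_GLN",
    "GLSZM_ZSN",
    "GLSZM_ZP",
    "GLSZM_LGZE",
    "GLSZM_HGZE",
    "GLSZM_SZLGE",
    "GLSZM_SZHGE",
    "GLSZM_LZLGE",
    "GLSZM_LZHGE",
    "GLSZM_GLV",
    "GLSZM_ZSV",
)

NGTDM_FEATURES = (
    "NGTDM_Coarseness",
    "NGTDM_Contrast",
    "NGTDM_Busyness",
    "NGTDM_Complexity",
    "NGTDM_Strength",
)

FEATURE_NAMES = INTENSITY_FEATURES + GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES

FAMILY_COUNTS = {
    "Intensity": len(INTENSITY_FEATURES),
    "GLCM": len(GLCM_FEATURES),
    "GLRLM": len(GLRLM_FEATURES),
    "GLSZM": len(GLSZM_FEATURES),
    "NGTDM": len(NGTDM_FEATURES),
}

assert len(FEATURE_NAMES) == 47
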