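"""Published feature-set presets for the classifier and the EE models.

Feature selection itself is not re-run here: the selected sets are shipped as
fixed, named configuration. An optional greedy forward-selection utility
lives in :mod:`iscee.ee_models` for exploration, clearly separate from these
presets.
"""

from __future__ import annotations

#: Five features of the activity classifier (k = 10, squared-inverse-distance).
CLASSIFIER_FEATURES = (
    "PERC_95(ω_Z_DA)",
    "IQR(ω_Z_DA)",
    "PERC_99(ω_M_Ch)",
    "PERC_25(ω_M_NDW)",
    "SD(H_NDW)",
)

#: Direct (single-model) EE regression feature sets.
MLR_DIRECT_FEATURES = (
    "REE",
    "MEAN(a_M_DW)",
    "PERC_1(a_M_Ch)",
    "MEAN(ω_M_DW)",
    "VAR(H_Ch)",
    "PERC_25(a_M_DA)",
    "VAR(a_M_NDF)",
)

ANN_DIRECT_FEATURES = (
    "REE",
    "MEAN(a_M_Ch)",
    "MEDIAN(ω_Z_DA)",
    "PERC_25(a_M_DW)",
    "VAR(ω_M_DF)",
)

#: Class-conditional EE regression feature sets (one per activity class).
MLR_CLASS_FEATURES = {
    "sedentary": ("REE", "PERC_25(ω_M_Ch)", "AC(a_M_NDF)", "LAT_feet"),
    "low_intensity": ("REE", "SD(H_NDW)", "PERC_75(a_M_Hi)", "VAR(H_DF)", "LAT_feet"),
    "high_intensity": ("REE", "PERC_3(ω_M_NDW)", "SD(H_NDW)", "PERC_5(a_M_Ch)",
                       "RMS(a_M_DA)", "PERC_1(a_M_DF)"),
    "walking": ("REE", "weight", "MEDIAN(a_M_Ch)", "PERC_1(ω_M_Hi)",
                "IQR(a_M_NDF)", "MEDIAN(ω_M_NDF)"),
}

ANN_CLASS_FEATURES = {
    "sedentary": ("REE", "PERC_25(ω_M_Ch)", "SD(H_Ch)", "PERC_3(a_M_DF)"),
    "low_intensity": ("REE", "VAR(H_Ch)", "AC(a_M_Hi)"),
    "high_intensity": ("REE", "PERC_1(a_M_Ch)", "VAR(H_Ch)", "RMS(a_M_DA)", "CORR_feet"),
    "walking": ("REE", "weight", "PERC_25(a_M_Ch)", "VAR(ω_M_Hi)", "IQR(ω_M_Hi)"),
}

#: Hidden-layer sizes for the ANN presets.
ANN_HIDDEN_UNITS = {
    "direct": 6,
    "sedentary": 3,
    "low_intensity": 3,
    "high_intensity": 3,
    "walking": 3,
}


def preset_features(architecture: str, regressor: str):
    """Return the preset feature set(s) for an architecture/regressor pair.

    direct -> tuple of names; class_conditional -> {class: tuple of names}.
    """
    if architecture == "direct":
        return MLR_DIRECT_FEATURES if regressor == "mlr" else ANN_DIRECT_FEATURES
    if architecture == "class_conditional":
        return MLR_CLASS_FEATURES if regressor == "mlr" else ANN_CLASS_FEATURES
    raise ValueError(f"unknown architecture {architecture!r}")


def all_preset_feature_names() -> set:
    """Union of every feature any shipped preset or the classifier uses."""
    names = set(CLASSIFIER_FEATURES) | set(MLR_DIRECT_FEATURES) | set(ANN_DIRECT_FEATURES)
    for d in (MLR_CLASS_FEATURES, ANN_CLASS_FEATURES):
        for feats in d.values():
            names |= set(feats)
    return names
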