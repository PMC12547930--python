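"""The 118-feature catalogue.

Features are grouped into seven families with fixed cardinalities:
first-order statistics (FOS, 23), grey level co-occurrence matrix
(GLCM, 25), grey level run length matrix (GLRLM, 16), grey level size
zone matrix (GLSZM, 16), grey level distance zone matrix (GLDZM, 16),
neighbourhood grey tone difference matrix (NGTDM, 5) and neighbouring
grey level dependence matrix (NGLDM, 17) -- 118 in total.  Features are
referred to by short codes ``FAMILYk`` (1-based within family, e.g.
``GLSZM5``); the human-readable identifier for each code is listed
here and exportable as CSV.
"""

from __future__ import annotations

import pandas as pd

CATALOGUE_VERSION = "1.0"

FOS_NAMES = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mode",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "histogram_entropy",
    "uniformity",
    "max_histogram_gradient",
    "max_histogram_gradient_level",
    "min_histogram_gradient",
    "min_histogram_gradient_level",
]

GLCM_NAMES = [
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalised",
    "inverse_difference_moment",
    "inverse_difference_moment_normalised",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
]

GLRLM_NAMES = [
    "short_run_emphasis",
    "long_run_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalised",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
]

GLSZM_NAMES = [
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
]

GLDZM_NAMES = [
    "small_distance_emphasis",
    "large_distance_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_distance_variance",
    "zone_distance_entropy",
]

NGTDM_NAMES = [
    "coarseness",
    "contrast",
    "busyness",
    "complexity",
    "strength",
]

NGLDM_NAMES = [
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_grey_level_count_emphasis",
    "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalised",
    "dependence_count_percentage",
    "grey_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
    "dependence_count_energy",
]

FAMILIES = (
    ("FOS", FOS_NAMES),
    ("GLCM", GLCM_NAMES),
    ("GLRLM", GLRLM_NAMES),
    ("GLSZM", GLSZM_NAMES),
    ("GLDZM", GLDZM_NAMES),
    ("NGTDM", NGTDM_NAMES),
    ("NGLDM", NGLDM_NAMES),
)

#: Ordered short codes for the full catalogue: FOS1..FOS23, GLCM1..GLCM25, ...
FEATURE_CODES: list[str] = [
    f"{fam}{k}" for fam, names in FAMILIES for k in range(1, len(names) + 1)
]

#: Short code -> human readable identifier.
FEATURE_IDENTIFIERS: dict[str, str] = {
    f"{fam}{k}": name
    for fam, names in FAMILIES
    for k, name in enumerate(names, start=1)
}

N_FEATURES = len(FEATURE_CODES)
assert N_FEATURES == 118

FAMILY_SIZES = {fam: len(names) for fam, names in FAMILIES}


def catalogue_table() -> pd.DataFrame:
    """Catalogue as a data frame with columns index, code, family, identifier."""
    rows = []
    for idx, code in enumerate(FEATURE_CODES):
        fam = code.rstrip("0123456789")
        rows.append(
            {
                "index": idx,
                "code": code,
                "family": fam,
                "identifier": FEATURE_IDENTIFIERS[code],
            }
        )
    return pd.DataFrame(rows)


def export_catalogue(path) -> None:
    """Write the feature catalogue listing as CSV."""
    catalogue_table().to_csv(path, index=False)
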