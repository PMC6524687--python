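"""Published reference values for intestinal-microbiota co-occurrence networks.

A study of colorectal-cancer chemotherapy reported the topological
properties of seven RMT-thresholded intestinal microbiota networks — one
for healthy controls (H) and one per treatment stage (T0-T5) — together
with degree-preserving random-network baselines.  Those printed values
are bundled here, statsmodels-datasets style, for two uses: arithmetic
self-consistency checks (average degree must equal 2E/N) and the
percentage-change statements the study derives from them.
"""

from __future__ import annotations

import pandas as pd

GROUPS = ("H", "T0", "T1", "T2", "T3", "T4", "T5")

_EMPIRICAL = {
    "original_otus": (655, 778, 727, 793, 814, 788, 758),
    "network_size": (105, 99, 102, 103, 80, 103, 103),
    "total_links": (110, 238, 228, 239, 173, 210, 231),
    "average_degree": (2.095, 4.808, 4.471, 4.641, 4.325, 4.078, 4.485),
    "average_path_distance": (5.942, 2.893, 2.982, 3.216, 3.403, 3.701, 3.210),
    "average_clustering": (0.07, 0.191, 0.209, 0.175, 0.140, 0.119, 0.240),
    "harmonic_geodesic_distance": (4.165, 2.488, 2.539, 2.759, 2.717, 3.022, 2.668),
    "threshold": (0.660,) * 7,
    "power_law_r2": (0.786, 0.794, 0.724, 0.821, 0.808, 0.861, 0.870),
    "modularity": (0.773, 0.429, 0.450, 0.475, 0.405, 0.500, 0.498),
}

_RANDOM_MEAN = {
    "average_path_distance": (5.584, 2.693, 2.705, 3.02, 2.883, 3.228, 3.022),
    "average_clustering": (0.014, 0.209, 0.200, 0.101, 0.139, 0.077, 0.102),
    "harmonic_geodesic_distance": (4.318, 2.401, 2.415, 2.635, 2.509, 2.803, 2.647),
    "modularity": (0.731, 0.355, 0.381, 0.393, 0.380, 0.434, 0.396),
}

_RANDOM_SD = {
    "average_path_distance": (0.467, 0.045, 0.047, 0.052, 0.068, 0.069, 0.064),
    "average_clustering": (0.010, 0.025, 0.024, 0.018, 0.022, 0.017, 0.018),
    "harmonic_geodesic_distance": (0.254, 0.026, 0.026, 0.031, 0.042, 0.043, 0.039),
    "modularity": (0.015, 0.010, 0.010, 0.011, 0.011, 0.012, 0.011),
}


def load_published_indices() -> pd.DataFrame:
    """Empirical network indices of the seven published networks (columns H..T5)."""
    return pd.DataFrame(_EMPIRICAL, index=list(GROUPS)).T


def load_published_null_summary() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(mean, sd) DataFrames of the published 100-network null ensembles."""
    mean = pd.DataFrame(_RANDOM_MEAN, index=list(GROUPS)).T
    sd = pd.DataFrame(_RANDOM_SD, index=list(GROUPS)).T
    return mean, sd


def percent_decrease(reference: float, other: float) -> float:
    """Decrease of `other` relative to `reference`, in percent: (ref-other)/ref*100."""
    return (reference - other) / reference * 100.0


def percent_increase(reference: float, other: float) -> float:
    """Increase of `other` relative to `reference`, in percent: (other-ref)/ref*100."""
    return (other - reference) / reference * 100.0
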