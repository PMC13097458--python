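"""Individual-level overlap: minimal ΔE*ab to another group's samples.

For each measurement in a reference group, find the single most similar
measurement in a comparison group (the minimal ΔE*ab over all of that
group's samples) and ask whether that best match is perceptually
indistinguishable — below the perceptibility threshold PT ≈ 2 ΔE*ab
units, the just-noticeable difference adopted for skin.  The fraction of
reference samples with an indistinguishable counterpart is the overlap
percentage; computed for every ordered group pair it fills an 8×8
matrix whose rows are reference groups.

ΔE*ab is Euclidean, so the nearest-neighbour search uses a k-d tree and
is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dataset import SkinDataset
from .matrices import OverlapMatrix

__all__ = [
    "ThresholdConfig",
    "MinDistanceSet",
    "min_delta_e_profile",
    "overlap_fraction",
    "individual_overlap_matrix",
]

#: Literature perceptibility/acceptability thresholds (ΔE*ab) for skin
#: replicas: PT ≈ 1.1 (lighter) / 1.6 (darker), AT ≈ 3.0 / 4.4.  They are
#: context only; computation uses the adopted suprathreshold PT below.
LITERATURE_THRESHOLDS = {"PT_lighter": 1.1, "PT_darker": 1.6, "AT_lighter": 3.0, "AT_darker": 4.4}


@dataclass(frozen=True)
class ThresholdConfig:
    """Perceptual threshold in ΔE*ab units; ``inclusive`` switches the
    below-threshold test from strict ``<`` to ``<=`` (sensitivity)."""

    pt: float = 2.0
    inclusive: bool = False

    def __post_init__(self) -> None:
        if not self.pt > 0:
            raise ValueError("PT must be positive")


@dataclass
class MinDistanceSet:
    """One minimal ΔE*ab per reference sample against a comparison group."""

    reference: str
    comparison: str
    distances: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1 or self.distances.size == 0:
            raise ValueError("distances must be a non-empty 1-D array")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


def min_delta_e_profile(
    reference_lab: np.ndarray,
    comparison_lab: np.ndarray,
    reference: str = "ref",
    comparison: str = "cmp",
) -> MinDistanceSet:
    """Exact minimal ΔE*ab from every reference sample to the comparison set."""
    ref = np.atleast_2d(np.asarray(reference_lab, dtype=float))
    cmp_ = np.atleast_2d(np.asarray(comparison_lab, dtype=float))
    if ref.size == 0 or cmp_.size == 0:
        raise ValueError("both sample sets must be non-empty")
    tree = cKDTree(cmp_)
    dist, _ = tree.query(ref, k=1)
    return MinDistanceSet(reference=reference, comparison=comparison, distances=dist)


def overlap_fraction(distances: MinDistanceSet, threshold: ThresholdConfig | float = 2.0) -> float:
    """Percentage of minimal distances below the perceptual threshold."""
    cfg = threshold if isinstance(threshold, ThresholdConfig) else ThresholdConfig(float(threshold))
    d = distances.distances
    below = d <= cfg.pt if cfg.inclusive else d < cfg.pt
    return 100.0 * float(below.sum()) / d.size


def individual_overlap_matrix(
    dataset: SkinDataset, threshold: ThresholdConfig | float = 2.0
) -> OverlapMatrix:
    """Overlap percentage for every ordered group pair.

    The diagonal is 100 by definition (every sample is indistinguishable
    from itself) and is excluded from downstream medians/correlations.
    """
    groups = dataset.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labs = {g: dataset.lab(g) for g in groups}
    trees = {g: cKDTree(labs[g]) for g in groups}
    k = len(groups)
    values = np.full((k, k), 100.0)
    cfg = threshold if isinstance(threshold, ThresholdConfig) else ThresholdConfig(float(threshold))
    for i, ref in enumerate(groups):
        for j, cmp_ in enumerate(groups):
            if i == j:
                continue
            dist, _ = trees[cmp_].query(labs[ref], k=1)
            mds = MinDistanceSet(ref, cmp_, dist)
            values[i, j] = overlap_fraction(mds, cfg)
    return OverlapMatrix(method="individual", groups=groups, values=values)
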