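"""Group-level overlap via voxelized colour gamuts.

A group's gamut is the region of CIELAB space its measurements occupy.
Convex hulls overestimate it badly for skin (the lightness–chroma cloud
is banana-shaped, i.e. concave), so the gamut is instead represented as
the set of occupied 3×3×3 unit cubes on a fixed global grid anchored at
the CIELAB origin.  The 3-unit edge keeps adjacent cube centres more
than a perceptual threshold apart, so distinct cubes are perceptually
meaningful clusters.  Two single-pass morphological refinements assume
skin-colour continuity:

1. remove isolated cubes (all six face neighbours empty) — outliers;
2. fill gaps (empty cubes with all six face neighbours filled).

Both passes are evaluated on a snapshot of their input (no cascading),
removal first.  The overlap of a reference group A with a comparison
group B is 100·|cubes(A) ∩ cubes(B)| / |cubes(A)| on refined gamuts;
the shared count is symmetric but the percentage is not, because gamut
volumes differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .dataset import SkinDataset
from .matrices import OverlapMatrix

__all__ = [
    "VoxelGamut",
    "voxelize",
    "refine_gamut",
    "gamut_volume",
    "gamut_overlap_matrix",
    "gamut_volumes",
]

_FACE_NEIGHBOURS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass(frozen=True)
class VoxelGamut:
    """Occupied cube indices (iL, ia, ib) on the global edge-length grid."""

    group: str
    edge: float
    cubes: frozenset[tuple[int, int, int]]
    refined: bool = False

    def __post_init__(self) -> None:
        if not self.edge > 0:
            raise ValueError("edge must be positive")
        object.__setattr__(self, "cubes", frozenset(map(tuple, self.cubes)))

    @property
    def volume(self) -> int:
        return len(self.cubes)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.cubes)
        return pd.DataFrame(rows, columns=["iL", "ia", "ib"])


def voxelize(lab: np.ndarray, edge: float = 3.0, group: str = "") -> VoxelGamut:
    """Map CIELAB samples to occupied cubes: index = floor(coord / edge).

    Cells are half-open ([k·edge, (k+1)·edge)) and the grid is anchored
    at the origin, so cube sets are dataset-independent; floor (not
    truncation) keeps cells uniform across negative a*/b*.
    """
    arr = np.atleast_2d(np.asarray(lab, dtype=float))
    if arr.size == 0:
        raise ValueError("cannot voxelize an empty sample set")
    if not edge > 0:
        raise ValueError("edge must be positive")
    idx = np.floor(arr / edge).astype(int)
    cubes = frozenset(map(tuple, idx))
    return VoxelGamut(group=group, edge=edge, cubes=cubes, refined=False)


def refine_gamut(gamut: VoxelGamut) -> VoxelGamut:
    """Single-pass outlier removal then gap filling (snapshot semantics).

    Cubes with one to five filled face neighbours are never touched.
    """
    cubes = set(gamut.cubes)

    def neighbours(c):
        return [(c[0] + d[0], c[1] + d[1], c[2] + d[2]) for d in _FACE_NEIGHBOURS]

    # pass 1: drop isolated cubes, judged against the original set
    kept = {c for c in cubes if any(n in cubes for n in neighbours(c))}

    # pass 2: fill empty cubes fully surrounded by pass-1 cubes
    candidates = {n for c in kept for n in neighbours(c)} - kept
    filled = {c for c in candidates if all(n in kept for n in neighbours(c))}

    return VoxelGamut(
        group=gamut.group, edge=gamut.edge, cubes=frozenset(kept | filled), refined=True
    )


def gamut_volume(gamut: VoxelGamut) -> int:
    """Gamut volume as the number of occupied cubes."""
    return gamut.volume


def _refined_gamuts(dataset: SkinDataset, edge: float, refine: bool) -> dict[str, VoxelGamut]:
    out = {}
    for g in dataset.groups:
        vg = voxelize(dataset.lab(g), edge=edge, group=g)
        if refine:
            vg = refine_gamut(vg)
        if vg.volume == 0:
            raise ValueError(f"group {g!r} has an empty gamut after refinement")
        out[g] = vg
    return out


def gamut_overlap_matrix(
    dataset: SkinDataset, edge: float = 3.0, refine: bool = True
) -> OverlapMatrix:
    """Shared-gamut percentage for every ordered group pair (refined gamuts)."""
    groups = dataset.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gamuts = _refined_gamuts(dataset, edge, refine)
    k = len(groups)
    values = np.full((k, k), 100.0)
    for i, j in product(range(k), repeat=2):
        if i == j:
            continue
        a, b = gamuts[groups[i]], gamuts[groups[j]]
        values[i, j] = 100.0 * len(a.cubes & b.cubes) / a.volume
    return OverlapMatrix(method="gamut", groups=groups, values=values)


def gamut_volumes(dataset: SkinDataset, edge: float = 3.0, refine: bool = True) -> pd.Series:
    """Refined gamut volume (cube count) per group, canonical order."""
    gamuts = _refined_gamuts(dataset, edge, refine)
    return pd.Series({g: gamuts[g].volume for g in dataset.groups}, name="volume")
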