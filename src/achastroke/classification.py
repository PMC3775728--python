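"""CBV-map thresholding and the anterior choroidal artery occlusion call.

The decision procedure mirrors the imaging analysis of the thread-occlusion
model. For each animal:

1. Voxels containing large blood vessels are flagged by the standard CBV
   large-vessel threshold (10 ml/100 g) and excluded from every downstream
   mean and count. Values are never modified — exclusion is a flag, so maps
   stay grid-complete for rendering.
2. The mean CBV of the hemisphere contralateral to the occlusion is computed
   over non-excluded voxels, and applied as a stringent threshold: voxels
   with CBV greater than or equal to that mean are "signal".
3. The AChA is called occluded when the ipsilateral AChA territory contains
   no signal voxels (at most ``tolerance_voxels``, default 0) on the caudal
   slice, where the territory exists.

The call is a pure function of the maps, the atlas and the parameters: it
never sees ground truth, matching the blinded read in the original analysis.

A separate 2 ml/100 g threshold marks the tissue predicted to infarct
(strictly below threshold, within the brain mask); it is illustrative and
plays no role in the occlusion call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import GridMismatchError, GridSpec, TerritoryAtlas

__all__ = [
    "CBVMap",
    "ClassificationResult",
    "EmptyROIError",
    "exclude_large_vessels",
    "mean_contralateral_cbv",
    "classify_achao",
    "predicted_infarct_mask",
    "LARGE_VESSEL_THRESHOLD",
    "INFARCT_CBV_THRESHOLD",
]

#: Standard CBV large-vessel exclusion threshold, ml/100 g.
LARGE_VESSEL_THRESHOLD = 10.0

#: CBV below which tissue is predicted to infarct, ml/100 g.
INFARCT_CBV_THRESHOLD = 2.0


class EmptyROIError(ValueError):
    """A region of interest is empty after vessel exclusion."""


@dataclass
class CBVMap:
    """One coronal slice of cerebral blood volume values.

    ``values`` is a 2D array in ml/100 g on the atlas grid;
    ``occluded_side`` names the hemisphere carrying the occlusion
    ('left' or 'right').
    """

    values: np.ndarray
    grid: GridSpec
    bregma_level: float
    animal_id: str
    occluded_side: str = "right"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"CBV map shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("CBV values must be non-negative")
        if self.occluded_side not in ("left", "right"):
            raise ValueError("occluded_side must be 'left' or 'right'")

    @property
    def contralateral_side(self) -> str:
        return "left" if self.occluded_side == "right" else "right"


@dataclass
class ClassificationResult:
    """Outcome of the AChA occlusion call for one animal."""

    animal_id: str
    mean_contralateral_cbv: float
    supra_threshold_voxels_in_acha: int
    acha_occluded: bool
    excluded_vessel_voxels: int
    slice_used: float
    tolerance_voxels: int = 0


def exclude_large_vessels(
    cbv_map: CBVMap, threshold: float = LARGE_VESSEL_THRESHOLD
) -> np.ndarray:
    """Boolean mask of voxels excluded as large vessels (CBV > threshold).

    The underlying map values are untouched; the mask is applied by the
    callers when averaging or counting.
    """
    if threshold < 0:
        raise ValueError("vessel threshold must be non-negative")
    return cbv_map.values > threshold


def mean_contralateral_cbv(
    cbv_map: CBVMap,
    atlas: TerritoryAtlas,
    excluded: np.ndarray | None = None,
) -> float:
    """Mean CBV over the non-excluded contralateral hemisphere.

    ``excluded`` is the large-vessel mask from :func:`exclude_large_vessels`;
    pass None for no exclusion. Raises :class:`EmptyROIError` if no
    contralateral voxel survives exclusion.
    """
    level = atlas.grid.level_index(cbv_map.bregma_level)
    hemi = atlas.hemisphere(cbv_map.contralateral_side)[level]
    valid = hemi if excluded is None else (hemi & ~excluded)
    if not valid.any():
        raise EmptyROIError(
            "contralateral hemisphere is empty after vessel exclusion"
        )
    return float(cbv_map.values[valid].mean())


def classify_achao(
    maps: Sequence[CBVMap] | Iterable[CBVMap],
    atlas: TerritoryAtlas,
    vessel_threshold: float = LARGE_VESSEL_THRESHOLD,
    tolerance_voxels: int = 0,
    pool_contralateral: bool = False,
) -> ClassificationResult:
    """Call AChA occlusion from one animal's CBV maps.

    Uses the caudal slice, where the AChA territory is defined. The
    contralateral-mean threshold is computed on that slice by default;
    ``pool_contralateral=True`` pools the contralateral hemisphere across
    all provided slices instead.

    Occlusion is called when the count of ipsilateral AChA-territory voxels
    with CBV >= the mean contralateral CBV (after vessel exclusion) does not
    exceed ``tolerance_voxels``.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("at least one CBV map is required")
    if tolerance_voxels < 0:
        raise ValueError("tolerance_voxels must be non-negative")

    acha_level = atlas.acha_level_index()
    acha_bregma = atlas.grid.bregma_levels[acha_level]
    by_level = {m.bregma_level: m for m in maps}
    caudal = None
    for m in maps:
        if abs(m.bregma_level - acha_bregma) <= 1e-6:
            caudal = m
    if caudal is None:
        raise ValueError(
            f"no CBV map at the caudal AChA level ({acha_bregma} mm bregma)"
        )

    excluded = exclude_large_vessels(caudal, vessel_threshold)
    if pool_contralateral:
        vals, n_excl = [], 0
        for m in by_level.values():
            excl = exclude_large_vessels(m, vessel_threshold)
            lvl = atlas.grid.level_index(m.bregma_level)
            hemi = atlas.hemisphere(m.contralateral_side)[lvl]
            valid = hemi & ~excl
            vals.append(m.values[valid])
            n_excl += int((hemi & excl).sum())
        pooled = np.concatenate(vals)
        if pooled.size == 0:
            raise EmptyROIError(
                "contralateral hemisphere is empty after vessel exclusion"
            )
        mean_contra = float(pooled.mean())
    else:
        mean_contra = mean_contralateral_cbv(caudal, atlas, excluded)

    acha_ipsi = atlas.side_mask("acha_territory", caudal.occluded_side)[acha_level]
    counted = acha_ipsi & ~excluded
    supra = int(np.count_nonzero(caudal.values[counted] >= mean_contra))
    return ClassificationResult(
        animal_id=caudal.animal_id,
        mean_contralateral_cbv=mean_contra,
        supra_threshold_voxels_in_acha=supra,
        acha_occluded=supra <= tolerance_voxels,
        excluded_vessel_voxels=int(excluded.sum()),
        slice_used=caudal.bregma_level,
        tolerance_voxels=tolerance_voxels,
    )


def predicted_infarct_mask(
    cbv_map: CBVMap,
    atlas: TerritoryAtlas,
    threshold: float = INFARCT_CBV_THRESHOLD,
) -> np.ndarray:
    """Brain voxels predicted to infarct: CBV strictly below ``threshold``.

    The strict inequality means a voxel at exactly the threshold value is
    spared; the mask is restricted to the brain.
    """
    if threshold < 0:
        raise ValueError("infarct threshold must be non-negative")
    level = atlas.grid.level_index(cbv_map.bregma_level)
    return atlas.brain[level] & (cbv_map.values < threshold)
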