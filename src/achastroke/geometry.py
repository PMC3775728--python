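"""Parametric coronal territory atlas for rat perfusion-CT analysis.

The experimental read-outs in the intraluminal MCA-occlusion model are all
referenced to a small set of 2D coronal territories: the two hemispheres, the
cortical mantle vs. the subcortex, the middle cerebral artery (MCA) territory
(lateral, spanning cortex and subcortex), and the anterior choroidal artery
(AChA) territory (a small, entirely subcortical region present only on the
caudal analysis slice). No digital rat atlas accompanies the analysis, so the
atlas here is parametric: a half-ellipse hemisphere, an annular cortex, an
angular MCA sector, and a medial subcortical AChA blob, mirrored exactly
across the midline.

Coordinates are row-major 0-based voxel indices; a voxel is wholly in or out
of a mask. Laterality is carried as explicit metadata and never inferred from
image orientation (radiological vs. neurological display conventions differ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GeometryError",
    "GridMismatchError",
    "GridSpec",
    "AtlasShape",
    "TerritoryAtlas",
    "build_atlas",
    "mask_volume",
    "save_atlas",
    "load_atlas",
]

#: CT acquisition scale: 512 x 512 matrix over a 50 mm field of view.
NATIVE_PIXEL_SIZE_MM = 50.0 / 512.0

#: Canonical analysis slice positions, mm relative to bregma (rostral first).
DEFAULT_BREGMA_LEVELS = (0.0, -2.4)

MASK_NAMES = (
    "left_hemisphere",
    "right_hemisphere",
    "cortex",
    "subcortex",
    "mca_territory",
    "acha_territory",
)


class GeometryError(ValueError):
    """Invalid grid or degenerate territory geometry."""


class GridMismatchError(GeometryError):
    """A mask or map does not share the atlas grid."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry shared by maps, masks and traces.

    Parameters
    ----------
    n_rows, n_cols:
        In-plane voxel counts (>= 16; ``n_cols`` must be even so the midline
        falls between columns and left/right mirror exactly).
    pixel_size:
        In-plane voxel edge, mm. Default is the native CT scale,
        50 mm FOV / 512 matrix.
    slice_thickness:
        Slice thickness, mm (2.4 mm in the acquisition this models).
    bregma_levels:
        Rostro-caudal slice positions in mm relative to bregma, strictly
        decreasing (rostral to caudal).
    """

    n_rows: int = 128
    n_cols: int = 128
    pixel_size: float = NATIVE_PIXEL_SIZE_MM
    slice_thickness: float = 2.4
    bregma_levels: tuple[float, ...] = DEFAULT_BREGMA_LEVELS

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise GeometryError("grid must be at least 16x16 voxels")
        if self.n_cols % 2:
            raise GeometryError("n_cols must be even (midline between columns)")
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise GeometryError("pixel_size and slice_thickness must be > 0")
        levels = tuple(float(b) for b in self.bregma_levels)
        if not levels:
            raise GeometryError("at least one bregma level is required")
        if any(levels[i] <= levels[i + 1] for i in range(len(levels) - 1)):
            raise GeometryError("bregma_levels must be strictly decreasing")
        object.__setattr__(self, "bregma_levels", levels)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_levels(self) -> int:
        return len(self.bregma_levels)

    @property
    def voxel_area(self) -> float:
        """In-plane voxel area, mm^2."""
        return self.pixel_size**2

    @property
    def voxel_volume(self) -> float:
        """Voxel volume, mm^3 (area x slice thickness)."""
        return self.voxel_area * self.slice_thickness

    def level_index(self, bregma: float, atol: float = 1e-6) -> int:
        for i, b in enumerate(self.bregma_levels):
            if abs(b - bregma) <= atol:
                return i
        raise GeometryError(f"no slice at bregma {bregma} mm")

    def nearest_level_index(self, position: float) -> int:
        """Index of the bregma level nearest a rostro-caudal position (mm)."""
        d = [abs(b - position) for b in self.bregma_levels]
        return int(np.argmin(d))


@dataclass(frozen=True)
class AtlasShape:
    """Territory-shape parameters, as fractions of the grid extent.

    The AChA extent is a free parameter of the model (no published pixel
    extent exists for it); the default is a small medial subcortical blob.
    """

    hemisphere_row_frac: float = 0.42  # ellipse semi-axis / n_rows
    hemisphere_col_frac: float = 0.45  # ellipse semi-axis / n_cols
    cortex_inner_frac: float = 0.68  # normalized radius where cortex begins
    mca_half_angle_deg: float = 40.0  # half-width of the lateral MCA sector
    mca_inner_frac: float = 0.25  # inner normalized radius of the sector
    acha_row_offset_frac: float = 0.15  # ventral offset of the AChA blob
    acha_col_offset_frac: float = 0.12  # medial->lateral offset from midline
    acha_radius_frac: float = 0.04  # blob radius / n_cols


@dataclass
class TerritoryAtlas:
    """Per-slice territory masks on a shared grid.

    ``masks`` maps each name in :data:`MASK_NAMES` to a boolean array of
    shape ``(n_levels, n_rows, n_cols)``. Territory masks (MCA, AChA) are
    bilateral and mirror-symmetric; side-specific masks are obtained with
    :meth:`side_mask`. The AChA territory is non-empty only on the caudal
    slice, matching where it is assessed.
    """

    grid: GridSpec
    masks: dict[str, np.ndarray]
    laterality: str = "neurological: image left is anatomical left"
    shape_params: AtlasShape = field(default_factory=AtlasShape)

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def brain(self) -> np.ndarray:
        return self.masks["left_hemisphere"] | self.masks["right_hemisphere"]

    def hemisphere(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {side!r}")
        return self.masks[f"{side}_hemisphere"]

    def side_mask(self, name: str, side: str) -> np.ndarray:
        """Territory mask restricted to one hemisphere."""
        return self.masks[name] & self.hemisphere(side)

    def acha_level_index(self) -> int:
        """Index of the (unique caudal) level carrying the AChA territory."""
        counts = self.masks["acha_territory"].sum(axis=(1, 2))
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            raise GeometryError("atlas has an empty AChA territory at all levels")
        return int(nz[-1])


def _radial_fields(grid: GridSpec, shape: AtlasShape):
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    r0 = (grid.n_rows - 1) / 2.0
    c0 = (grid.n_cols - 1) / 2.0
    a = shape.hemisphere_row_frac * grid.n_rows
    b = shape.hemisphere_col_frac * grid.n_cols
    rho = np.sqrt(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2)
    return rr, cc, r0, c0, rho


def build_atlas(
    grid: GridSpec | None = None,
    shape: AtlasShape | None = None,
    laterality: str = "neurological: image left is anatomical left",
) -> TerritoryAtlas:
    """Construct the parametric territory atlas.

    Deterministic for fixed inputs. Raises :class:`GeometryError` when the
    parameters yield a degenerate geometry (empty hemisphere, MCA or AChA
    mask, or an MCA sector that fails to span cortex and subcortex).
    """
    grid = grid or GridSpec()
    shape = shape or AtlasShape()
    rr, cc, r0, c0, rho = _radial_fields(grid, shape)

    brain2d = rho <= 1.0
    half = grid.n_cols // 2
    left2d = brain2d & (cc < half)
    right2d = brain2d & (cc >= half)
    cortex2d = brain2d & (rho >= shape.cortex_inner_frac)
    subcortex2d = brain2d & (rho < shape.cortex_inner_frac)

    # Lateral sector, symmetric in |c - c0| so the two sides mirror exactly.
    theta = np.degrees(np.arctan2(rr - r0, np.abs(cc - c0)))
    mca2d = (
        brain2d
        & (np.abs(theta) <= shape.mca_half_angle_deg)
        & (rho >= shape.mca_inner_frac)
    )

    # Medial subcortical AChA blob; carved out of the MCA sector so the two
    # territories stay disjoint (they receive distinct perfusion effects).
    dr = shape.acha_row_offset_frac * grid.n_rows
    dc = shape.acha_col_offset_frac * grid.n_cols
    rad = shape.acha_radius_frac * grid.n_cols
    blob2d = ((rr - (r0 + dr)) ** 2 + (np.abs(cc - c0) - dc) ** 2) <= rad**2
    acha2d = blob2d & subcortex2d & ~mca2d

    if not left2d.any() or not right2d.any():
        raise GeometryError("degenerate geometry: empty hemisphere mask")
    if not mca2d.any():
        raise GeometryError("degenerate geometry: empty MCA territory")
    if not (mca2d & cortex2d).any() or not (mca2d & subcortex2d).any():
        raise GeometryError("MCA territory must span cortex and subcortex")
    if not acha2d.any():
        raise GeometryError("degenerate geometry: empty AChA territory")

    L = grid.n_levels
    stack = lambda m: np.repeat(m[None, :, :], L, axis=0)  # noqa: E731
    acha = np.zeros((L, grid.n_rows, grid.n_cols), dtype=bool)
    acha[L - 1] = acha2d  # caudal slice only

    masks = {
        "left_hemisphere": stack(left2d),
        "right_hemisphere": stack(right2d),
        "cortex": stack(cortex2d),
        "subcortex": stack(subcortex2d),
        "mca_territory": stack(mca2d),
        "acha_territory": acha,
    }
    return TerritoryAtlas(grid=grid, masks=masks, laterality=laterality, shape_params=shape)


def mask_volume(mask: np.ndarray, grid: GridSpec) -> float:
    """Volume of a binary mask in mm^3.

    ``mask`` may be 2D (one slice) or 3D (slices stacked on axis 0); the
    in-plane shape must match the grid. Volume is voxel count x pixel
    area x slice thickness, summed over slices.
    """
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    if mask.ndim != 3 or mask.shape[1:] != grid.shape:
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match grid {grid.shape}"
        )
    return float(mask.astype(bool).sum()) * grid.voxel_volume


# ---------------------------------------------------------------------------
# serialization: multi-page TIFF label stack + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_atlas(atlas: TerritoryAtlas, path: str | Path) -> Path:
    """Write the atlas as a multi-page TIFF plus a JSON sidecar.

    Pages are ordered mask-major: for each mask name in :data:`MASK_NAMES`,
    one page per bregma level. The sidecar records the grid geometry, the
    page layout, and the laterality convention.
    """
    path = Path(path)
    pages = np.concatenate(
        [atlas.masks[name].astype(np.uint8) for name in MASK_NAMES], axis=0
    )
    tifffile.imwrite(path, pages)
    sidecar = {
        "format": "achastroke-territory-atlas",
        "grid": asdict(atlas.grid),
        "mask_order": list(MASK_NAMES),
        "laterality": atlas.laterality,
        "shape_params": asdict(atlas.shape_params),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_atlas(path: str | Path) -> TerritoryAtlas:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    g = sidecar["grid"]
    grid = GridSpec(
        n_rows=g["n_rows"],
        n_cols=g["n_cols"],
        pixel_size=g["pixel_size"],
        slice_thickness=g["slice_thickness"],
        bregma_levels=tuple(g["bregma_levels"]),
    )
    pages = tifffile.imread(path).astype(bool)
    L = grid.n_levels
    masks = {}
    for i, name in enumerate(sidecar["mask_order"]):
        masks[name] = pages[i * L : (i + 1) * L]
    shape = AtlasShape(**sidecar.get("shape_params", {}))
    return TerritoryAtlas(
        grid=grid,
        masks=masks,
        laterality=sidecar["laterality"],
        shape_params=shape,
    )
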