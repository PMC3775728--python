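"""Infarct volumetry from serial coronal traces, with edema correction.

Histological infarct quantification in the rodent MCAo model integrates
traced per-section infarct areas over the section spacing, then removes the
bias from ipsilateral edema swelling by rescaling with the hemisphere-volume
ratio:

    corrected volume = raw volume * (contralateral / ipsilateral)

The cortical/subcortical partition intersects each section's infarct mask
with the atlas cortex and subcortex masks. Infarct probability maps give, per
voxel, the fraction of animals whose infarct covers it; the classic rendering
stacks each animal's trace at fixed opacity, so a voxel covered by k of n
animals has composited intensity 1 - (1 - opacity)^k, monotone in k. The
fraction map is the quantitative object; the rendering is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import GridMismatchError, TerritoryAtlas

__all__ = [
    "InfarctTraceSet",
    "VolumeReport",
    "InfeasibleVolumeError",
    "volume_from_traces",
    "edema_correct",
    "split_cortical_subcortical",
    "probability_map",
    "overlay_intensity",
    "render_probability_map",
    "volume_report",
    "DEFAULT_OVERLAY_OPACITY",
]

#: Per-layer opacity used for the stacked-trace rendering.
DEFAULT_OVERLAY_OPACITY = 0.24


class InfeasibleVolumeError(ValueError):
    """A requested volume exceeds the available territory area."""


@dataclass
class InfarctTraceSet:
    """Binary infarct traces and hemisphere outlines for one animal.

    All arrays have shape ``(n_sections, n_rows, n_cols)``. ``positions`` are
    section positions in mm from bregma, strictly decreasing (rostral to
    caudal); ``spacing`` is the represented inter-section distance in mm and
    ``pixel_size`` the in-plane voxel edge in mm.
    """

    infarct: np.ndarray
    ipsilateral: np.ndarray
    contralateral: np.ndarray
    positions: tuple[float, ...]
    spacing: float
    pixel_size: float
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.infarct = np.asarray(self.infarct, dtype=bool)
        self.ipsilateral = np.asarray(self.ipsilateral, dtype=bool)
        self.contralateral = np.asarray(self.contralateral, dtype=bool)
        shapes = {a.shape for a in (self.infarct, self.ipsilateral, self.contralateral)}
        if len(shapes) != 1 or self.infarct.ndim != 3:
            raise GridMismatchError("trace mask stacks must share one 3D shape")
        self.positions = tuple(float(p) for p in self.positions)
        if len(self.positions) != self.infarct.shape[0]:
            raise ValueError("one position per section is required")
        if any(
            self.positions[i] <= self.positions[i + 1]
            for i in range(len(self.positions) - 1)
        ):
            raise ValueError("section positions must be strictly decreasing")
        if self.spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("spacing and pixel_size must be > 0")
        if np.any(self.infarct & ~self.ipsilateral):
            raise ValueError("infarct must lie within the ipsilateral hemisphere")

    @property
    def n_sections(self) -> int:
        return self.infarct.shape[0]

    @property
    def voxel_volume(self) -> float:
        return self.pixel_size**2 * self.spacing


_ROLES = {"infarct", "ipsi", "contra"}


def volume_from_traces(traces: InfarctTraceSet, mask_role: str = "infarct") -> float:
    """Volume in mm^3 of one mask role: sum of section areas x spacing."""
    if mask_role not in _ROLES:
        raise ValueError(f"mask_role must be one of {sorted(_ROLES)}")
    stack = {
        "infarct": traces.infarct,
        "ipsi": traces.ipsilateral,
        "contra": traces.contralateral,
    }[mask_role]
    return float(stack.sum()) * traces.voxel_volume


def edema_correct(raw: float, contra: float, ipsi: float) -> float:
    """Edema-corrected infarct volume: raw x (contralateral / ipsilateral).

    Swelling (ipsi > contra) shrinks the estimate; shrinkage inflates it.
    """
    if raw < 0:
        raise ValueError("raw infarct volume must be non-negative")
    if contra <= 0 or ipsi <= 0:
        raise ValueError("hemisphere volumes must be positive")
    return raw * (contra / ipsi)


def split_cortical_subcortical(
    traces: InfarctTraceSet, atlas: TerritoryAtlas
) -> tuple[float, float]:
    """Partition the infarct volume into (cortical, subcortical) mm^3.

    Each section uses the atlas cortex/subcortex masks of the nearest bregma
    level; the two volumes sum to the total infarct volume exactly because
    cortex and subcortex partition the brain.
    """
    if traces.infarct.shape[1:] != atlas.grid.shape:
        raise GridMismatchError("traces are not on the atlas grid")
    cortical_vox = 0
    subcortical_vox = 0
    for s, pos in enumerate(traces.positions):
        lvl = atlas.grid.nearest_level_index(pos)
        cortical_vox += int((traces.infarct[s] & atlas.masks["cortex"][lvl]).sum())
        subcortical_vox += int(
            (traces.infarct[s] & atlas.masks["subcortex"][lvl]).sum()
        )
    vv = traces.voxel_volume
    return cortical_vox * vv, subcortical_vox * vv


@dataclass
class VolumeReport:
    """Per-animal volumetry summary, all volumes in mm^3."""

    animal_id: str
    raw_infarct: float
    corrected_infarct: float
    cortical_corrected: float
    subcortical_corrected: float
    contralateral_hemisphere: float
    ipsilateral_hemisphere: float


def volume_report(traces: InfarctTraceSet, atlas: TerritoryAtlas) -> VolumeReport:
    """Full volumetry for one animal's trace set.

    Cortical and subcortical volumes receive the same edema scale factor as
    the total, so the partition still sums to the corrected total.
    """
    raw = volume_from_traces(traces, "infarct")
    contra = volume_from_traces(traces, "contra")
    ipsi = volume_from_traces(traces, "ipsi")
    corrected = edema_correct(raw, contra, ipsi)
    cort, subc = split_cortical_subcortical(traces, atlas)
    scale = contra / ipsi
    return VolumeReport(
        animal_id=traces.animal_id,
        raw_infarct=raw,
        corrected_infarct=corrected,
        cortical_corrected=cort * scale,
        subcortical_corrected=subc * scale,
        contralateral_hemisphere=contra,
        ipsilateral_hemisphere=ipsi,
    )


def probability_map(mask_stack: np.ndarray) -> np.ndarray:
    """Per-voxel infarct fraction k/n over a stack of n binary masks."""
    mask_stack = np.asarray(mask_stack, dtype=bool)
    if mask_stack.ndim != 3 or mask_stack.shape[0] < 1:
        raise ValueError("mask_stack must be (n >= 1, rows, cols)")
    return mask_stack.mean(axis=0)


def overlay_intensity(
    fraction: np.ndarray, n: int, opacity: float = DEFAULT_OVERLAY_OPACITY
) -> np.ndarray:
    """Composited intensity of n stacked traces at fixed layer opacity.

    A voxel covered by k of the n layers composites to 1 - (1 - opacity)^k;
    strictly increasing in k, so commonly infarcted regions render lighter.
    """
    if not 0 < opacity <= 1:
        raise ValueError("opacity must be in (0, 1]")
    k = np.asarray(fraction, dtype=float) * n
    return 1.0 - (1.0 - opacity) ** k


def render_probability_map(
    fraction: np.ndarray,
    n: int,
    path: str | Path,
    opacity: float = DEFAULT_OVERLAY_OPACITY,
    title: str | None = None,
) -> Path:
    """Write a PNG of the stacked-trace rendering (grey on black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = overlay_intensity(fraction, n, opacity)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img, cmap="gray", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
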