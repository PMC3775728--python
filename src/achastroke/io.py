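"""File I/O for CBV maps and infarct trace sets.

Images travel as multi-page TIFF with a JSON sidecar carrying the geometry
and metadata; one file pair per animal. CBV maps are float32 in ml/100 g;
trace masks are uint8 {0,1}. The sidecar is the source of truth for grid
geometry, bregma levels / section positions and laterality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .classification import CBVMap
from .geometry import GridSpec
from .volumetry import InfarctTraceSet

__all__ = [
    "save_cbv_maps",
    "load_cbv_maps",
    "save_traces",
    "load_traces",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _grid_to_dict(grid: GridSpec) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "pixel_size": grid.pixel_size,
        "slice_thickness": grid.slice_thickness,
        "bregma_levels": list(grid.bregma_levels),
    }


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(
        n_rows=d["n_rows"],
        n_cols=d["n_cols"],
        pixel_size=d["pixel_size"],
        slice_thickness=d["slice_thickness"],
        bregma_levels=tuple(d["bregma_levels"]),
    )


def save_cbv_maps(maps: list[CBVMap], path: str | Path) -> Path:
    """Write one animal's CBV maps (one TIFF page per bregma level)."""
    if not maps:
        raise ValueError("no maps to save")
    path = Path(path)
    stack = np.stack([m.values for m in maps]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {
        "format": "achastroke-cbv-maps",
        "animal_id": maps[0].animal_id,
        "occluded_side": maps[0].occluded_side,
        "bregma_levels": [m.bregma_level for m in maps],
        "units": "ml/100g",
        "grid": _grid_to_dict(maps[0].grid),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_cbv_maps(path: str | Path) -> list[CBVMap]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    grid = _grid_from_dict(meta["grid"])
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    return [
        CBVMap(
            values=stack[i],
            grid=grid,
            bregma_level=b,
            animal_id=meta["animal_id"],
            occluded_side=meta["occluded_side"],
        )
        for i, b in enumerate(meta["bregma_levels"])
    ]


def save_traces(traces: InfarctTraceSet, path: str | Path) -> Path:
    """Write one animal's trace set (pages: infarct, ipsi, contra stacks)."""
    path = Path(path)
    stack = np.concatenate(
        [traces.infarct, traces.ipsilateral, traces.contralateral]
    ).astype(np.uint8)
    tifffile.imwrite(path, stack)
    meta = {
        "format": "achastroke-infarct-traces",
        "animal_id": traces.animal_id,
        "positions_mm": list(traces.positions),
        "spacing_mm": traces.spacing,
        "pixel_size_mm": traces.pixel_size,
        "page_order": ["infarct", "ipsilateral", "contralateral"],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_traces(path: str | Path) -> InfarctTraceSet:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = np.asarray(tifffile.imread(path)).astype(bool)
    n = len(meta["positions_mm"])
    if stack.shape[0] != 3 * n:
        raise ValueError("trace file page count does not match sidecar")
    return InfarctTraceSet(
        infarct=stack[:n],
        ipsilateral=stack[n : 2 * n],
        contralateral=stack[2 * n :],
        positions=tuple(meta["positions_mm"]),
        spacing=meta["spacing_mm"],
        pixel_size=meta["pixel_size_mm"],
        animal_id=meta["animal_id"],
    )
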