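"""Synthetic cohort, CBV-map and histology-trace generator.

Stands in for the study's raw data with the statistical structure the
analysis assumes. A cohort of outbred rats undergoes permanent (n=13), 1 h
(n=8) or 2 h (n=7) intraluminal MCA occlusion; the occluding thread
inadvertently blocks the anterior choroidal artery (AChA) in 7, 2 and 1
animals per group respectively (10 of 28 overall).

Edema-corrected infarct volumes are drawn per stratum (occlusion group x
AChA status) from normal distributions truncated at zero. The permanent-group
strata use the published summaries (42.7 +/- 27.62 mm^3 without AChAo,
144.5 +/- 11.72 mm^3 with). The 1 h / 2 h strata have no published per-group
summaries; their default means are recovered from the published pooled and
permanent-group summaries (15.55 and 94.83 mm^3), with the pooled SD of the
matching AChA class, and are overridable. The cortical share of each infarct
follows the published permanent-group cortical/subcortical ratios per AChA
class. Body weight is uniform on 300-500 g and independent of volume,
matching the null weight finding.

CBV maps place a hypoperfused ipsilateral MCA territory (residual fraction of
the contralateral baseline), an AChA territory that is either silenced
(occluded) or kept above baseline (patent), planted high-CBV large-vessel
voxels in both hemispheres, and additive Gaussian voxel noise. Histology
traces are binary infarct masks grown deterministically inside the atlas
compartments to match each record's volumes, with the ipsilateral hemisphere
outline dilated to model edema swelling.

All randomness flows from a single seed, expanded into per-animal,
per-product substreams by stable hashing of (seed, animal id), so cohorts
are reproducible under reordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .classification import CBVMap
from .geometry import GridSpec, TerritoryAtlas
from .volumetry import InfarctTraceSet, InfeasibleVolumeError

__all__ = [
    "ConfigError",
    "StratumParams",
    "CohortConfig",
    "AnimalRecord",
    "generate_cohort",
    "generate_cbv_maps",
    "generate_infarct_traces",
    "GROUP_ORDER",
]

GROUP_ORDER = ("1h", "2h", "permanent")

# Published permanent-group strata (mean, SD; mm^3).
PMCAO_NO_ACHAO = (42.7, 27.62)
PMCAO_ACHAO = (144.5, 11.72)
# Published pooled strata across all groups (mean, SD; mm^3).
POOLED_NO_ACHAO = (24.6, 23.38)
POOLED_ACHAO = (129.6, 41.58)

# Temporary-occlusion strata recovered from the pooled and permanent-group
# summaries: pooled counts are 18 non-AChAo (12 temporary) and 10 AChAo
# (3 temporary).
TEMP_NO_ACHAO_MEAN = (18 * POOLED_NO_ACHAO[0] - 6 * PMCAO_NO_ACHAO[0]) / 12  # 15.55
TEMP_ACHAO_MEAN = (10 * POOLED_ACHAO[0] - 7 * PMCAO_ACHAO[0]) / 3  # 94.833...

# Published permanent-group cortical/subcortical means (mm^3) fix the default
# cortical share of the infarct per AChA class.
CORTICAL_FRACTION_ACHAO = 85.2 / 144.5
CORTICAL_FRACTION_NO_ACHAO = 14.2 / 42.7


class ConfigError(ValueError):
    """Inconsistent cohort configuration."""


@dataclass(frozen=True)
class StratumParams:
    """Truncated-normal volume distribution for one stratum (mm^3)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("stratum SD must be non-negative")


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort: group sizes 13/8/7 for
    permanent/1 h/2 h occlusion with 7/2/1 AChA occlusions, published or
    derived stratum volume distributions, weights uniform on 300-500 g, 10%
    ipsilateral edema swelling, and a CBV field with contralateral baseline
    ~4 ml/100 g, 30% MCA residual, 10% AChA residual when occluded, five
    planted large-vessel voxels (15 ml/100 g) per hemisphere and 0.4 ml/100 g
    voxel noise.
    """

    # group composition
    n_permanent: int = 13
    n_1h: int = 8
    n_2h: int = 7
    achao_permanent: int = 7
    achao_1h: int = 2
    achao_2h: int = 1

    # stratum volume distributions, mm^3
    pmcao_no_achao: StratumParams = field(
        default_factory=lambda: StratumParams(*PMCAO_NO_ACHAO)
    )
    pmcao_achao: StratumParams = field(
        default_factory=lambda: StratumParams(*PMCAO_ACHAO)
    )
    temp_no_achao: StratumParams = field(
        default_factory=lambda: StratumParams(TEMP_NO_ACHAO_MEAN, POOLED_NO_ACHAO[1])
    )
    temp_achao: StratumParams = field(
        default_factory=lambda: StratumParams(TEMP_ACHAO_MEAN, POOLED_ACHAO[1])
    )

    # cortical/subcortical split
    cortical_fraction_achao: float = CORTICAL_FRACTION_ACHAO
    cortical_fraction_no_achao: float = CORTICAL_FRACTION_NO_ACHAO
    cortical_fraction_sd: float = 0.05

    # animal-level attributes
    weight_range_g: tuple[float, float] = (300.0, 500.0)
    swelling_fraction: float = 0.10
    hemisphere_volume_mm3: float = 600.0
    occluded_side: str = "right"

    # CBV field, ml/100 g
    baseline_cbv_mean: float = 4.0
    baseline_cbv_sd: float = 0.3
    mca_residual_fraction: float = 0.30
    acha_residual_fraction: float = 0.10
    acha_patent_factor: float = 1.2
    vessel_count: int = 5
    vessel_value: float = 15.0
    noise_sd: float = 0.4

    # histology sections
    section_positions: tuple[float, ...] = (
        5.7, 3.7, 1.7, -0.3, -2.3, -4.3, -6.3, -8.3,
    )
    section_spacing_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_permanent", "n_1h", "n_2h",
                     "achao_permanent", "achao_1h", "achao_2h"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for grp, n_name, a_name in (
            ("permanent", "n_permanent", "achao_permanent"),
            ("1h", "n_1h", "achao_1h"),
            ("2h", "n_2h", "achao_2h"),
        ):
            if getattr(self, a_name) > getattr(self, n_name):
                raise ConfigError(
                    f"AChAo count exceeds group size in the {grp} group"
                )
        for name in ("mca_residual_fraction", "acha_residual_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("cortical_fraction_achao", "cortical_fraction_no_achao"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.vessel_value <= 10.0:
            raise ConfigError(
                "vessel_value must exceed the 10 ml/100 g large-vessel threshold"
            )
        if self.noise_sd < 0 or self.baseline_cbv_sd < 0 or self.cortical_fraction_sd < 0:
            raise ConfigError("noise and SD parameters must be non-negative")
        if self.swelling_fraction < 0:
            raise ConfigError("swelling_fraction must be non-negative")
        if self.acha_patent_factor < 1.0:
            raise ConfigError("acha_patent_factor must be >= 1 (at/above baseline)")
        if self.occluded_side not in ("left", "right"):
            raise ConfigError("occluded_side must be 'left' or 'right'")
        lo, hi = self.weight_range_g
        if not lo < hi or lo <= 0:
            raise ConfigError("weight_range_g must be a positive increasing pair")
        self.section_positions = tuple(float(p) for p in self.section_positions)
        if any(
            self.section_positions[i] <= self.section_positions[i + 1]
            for i in range(len(self.section_positions) - 1)
        ):
            raise ConfigError("section_positions must be strictly decreasing")
        if self.section_spacing_mm <= 0:
            raise ConfigError("section_spacing_mm must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_permanent + self.n_1h + self.n_2h

    def group_sizes(self) -> dict[str, int]:
        return {"1h": self.n_1h, "2h": self.n_2h, "permanent": self.n_permanent}

    def achao_counts(self) -> dict[str, int]:
        return {"1h": self.achao_1h, "2h": self.achao_2h, "permanent": self.achao_permanent}

    def stratum(self, group: str, achao: bool) -> StratumParams:
        if group == "permanent":
            return self.pmcao_achao if achao else self.pmcao_no_achao
        return self.temp_achao if achao else self.temp_no_achao

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("pmcao_no_achao", "pmcao_achao", "temp_no_achao", "temp_achao"):
            if key in d and isinstance(d[key], dict):
                d[key] = StratumParams(**d[key])
        for key in ("weight_range_g", "section_positions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class AnimalRecord:
    """Ground-truth attributes of one synthetic animal."""

    animal_id: str
    occlusion_group: str  # '1h' | '2h' | 'permanent'
    acha_occluded: bool
    weight_g: float
    infarct_volume_total: float
    infarct_volume_cortical: float
    infarct_volume_subcortical: float
    contralateral_hemisphere_volume: float
    ipsilateral_hemisphere_volume: float

    def __post_init__(self) -> None:
        if self.occlusion_group not in GROUP_ORDER:
            raise ConfigError(f"unknown occlusion group {self.occlusion_group!r}")
        vols = (
            self.infarct_volume_total,
            self.infarct_volume_cortical,
            self.infarct_volume_subcortical,
        )
        if any(v < 0 for v in vols):
            raise ValueError("infarct volumes must be non-negative")
        if abs(vols[0] - vols[1] - vols[2]) > 1e-6 * max(1.0, vols[0]):
            raise ValueError("total infarct volume must equal cortical + subcortical")


def _animal_rng(seed: int, animal_id: str, stream: int) -> np.random.Generator:
    """Per-animal, per-product substream from a stable hash of the id."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(animal_id.encode()), stream]
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero, by rejection sampling."""
    if sd == 0:
        return max(mean, 0.0)
    while True:
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return float(x)


def generate_cohort(config: CohortConfig, seed: int) -> list[AnimalRecord]:
    """Draw a cohort of animal records; deterministic for a fixed seed.

    Animals are ordered 1 h, 2 h, permanent; within each group the first
    ``achao_<group>`` animals carry the AChA occlusion. Volumes are drawn per
    stratum from normal distributions truncated at zero; weights are uniform
    and independent of volume.
    """
    records: list[AnimalRecord] = []
    sizes = config.group_sizes()
    achao_counts = config.achao_counts()
    idx = 0
    contra = config.hemisphere_volume_mm3
    ipsi = contra * (1.0 + config.swelling_fraction)
    for group in GROUP_ORDER:
        for j in range(sizes[group]):
            idx += 1
            animal_id = f"A{idx:02d}"
            achao = j < achao_counts[group]
            rng = _animal_rng(seed, animal_id, stream=0)
            params = config.stratum(group, achao)
            total = _truncated_normal(rng, params.mean, params.sd)
            frac_mean = (
                config.cortical_fraction_achao
                if achao
                else config.cortical_fraction_no_achao
            )
            frac = float(
                np.clip(rng.normal(frac_mean, config.cortical_fraction_sd), 0.0, 1.0)
            )
            weight = float(rng.uniform(*config.weight_range_g))
            records.append(
                AnimalRecord(
                    animal_id=animal_id,
                    occlusion_group=group,
                    acha_occluded=achao,
                    weight_g=weight,
                    infarct_volume_total=total,
                    infarct_volume_cortical=total * frac,
                    infarct_volume_subcortical=total * (1.0 - frac),
                    contralateral_hemisphere_volume=contra,
                    ipsilateral_hemisphere_volume=ipsi,
                )
            )
    return records


def generate_cbv_maps(
    record: AnimalRecord,
    atlas: TerritoryAtlas,
    config: CohortConfig,
    seed: int,
) -> list[CBVMap]:
    """Synthesize one CBV map per atlas bregma level for an animal.

    Contralateral brain sits at the animal's baseline; the ipsilateral MCA
    territory is scaled by the MCA residual fraction; the ipsilateral AChA
    territory is scaled by the AChA residual fraction when occluded and
    raised above baseline (patent factor) otherwise. ``vessel_count`` voxels
    per hemisphere, outside both territories, are planted above the
    large-vessel threshold. Gaussian voxel noise is added last and values are
    clipped at zero.
    """
    rng = _animal_rng(seed, record.animal_id, stream=1)
    grid = atlas.grid
    side = config.occluded_side
    other = "left" if side == "right" else "right"
    baseline = max(float(rng.normal(config.baseline_cbv_mean, config.baseline_cbv_sd)), 0.1)

    maps: list[CBVMap] = []
    for lvl, bregma in enumerate(grid.bregma_levels):
        values = np.zeros(grid.shape, dtype=float)
        brain = atlas.brain[lvl]
        values[brain] = baseline

        mca_ipsi = atlas.side_mask("mca_territory", side)[lvl]
        values[mca_ipsi] = baseline * config.mca_residual_fraction

        acha_ipsi = atlas.side_mask("acha_territory", side)[lvl]
        if acha_ipsi.any():
            factor = (
                config.acha_residual_fraction
                if record.acha_occluded
                else config.acha_patent_factor
            )
            values[acha_ipsi] = baseline * factor

        # Planted large vessels, clear of both territories on either side.
        for hemi_side in (side, other):
            eligible = (
                atlas.hemisphere(hemi_side)[lvl]
                & ~atlas.masks["mca_territory"][lvl]
                & ~atlas.masks["acha_territory"][lvl]
            )
            coords = np.argwhere(eligible)
            if config.vessel_count > len(coords):
                raise ConfigError("vessel_count exceeds eligible voxels")
            pick = rng.choice(len(coords), size=config.vessel_count, replace=False)
            for r, c in coords[pick]:
                values[r, c] = config.vessel_value

        if config.noise_sd > 0:
            values[brain] += rng.normal(0.0, config.noise_sd, size=int(brain.sum()))
        np.clip(values, 0.0, None, out=values)
        maps.append(
            CBVMap(
                values=values,
                grid=grid,
                bregma_level=bregma,
                animal_id=record.animal_id,
                occluded_side=side,
            )
        )
    return maps


def _allocate(total: int, capacities: Sequence[int]) -> np.ndarray:
    """Split ``total`` voxels over sections proportionally to capacity.

    Largest-remainder apportionment, deterministic; raises
    :class:`InfeasibleVolumeError` when the capacities cannot hold the total.
    """
    caps = np.asarray(capacities, dtype=int)
    if total > caps.sum():
        raise InfeasibleVolumeError(
            f"requested {total} voxels exceed available territory area {caps.sum()}"
        )
    if total == 0 or caps.sum() == 0:
        return np.zeros(len(caps), dtype=int)
    exact = total * caps / caps.sum()
    alloc = np.floor(exact).astype(int)
    remainder = total - alloc.sum()
    frac = exact - alloc
    order = np.lexsort((np.arange(len(caps)), -frac))
    for i in order:
        if remainder == 0:
            break
        if alloc[i] < caps[i]:
            alloc[i] += 1
            remainder -= 1
    # spill any residue into sections with spare capacity
    i = 0
    while remainder > 0:
        if alloc[i] < caps[i]:
            alloc[i] += 1
            remainder -= 1
        i = (i + 1) % len(caps)
    return alloc


def _grow_region(region: np.ndarray, seed_point: tuple[float, float], count: int) -> np.ndarray:
    """Deterministically pick the ``count`` region voxels nearest a seed."""
    out = np.zeros_like(region, dtype=bool)
    if count == 0:
        return out
    coords = np.argwhere(region)
    d = (coords[:, 0] - seed_point[0]) ** 2 + (coords[:, 1] - seed_point[1]) ** 2
    order = np.lexsort((coords[:, 1], coords[:, 0], d))
    chosen = coords[order[:count]]
    out[chosen[:, 0], chosen[:, 1]] = True
    return out


def _dilate_to_count(base: np.ndarray, allowed: np.ndarray, target: int) -> np.ndarray:
    """Grow ``base`` outward by nearest allowed voxels until it has ``target``."""
    extra = target - int(base.sum())
    if extra <= 0:
        return base.copy()
    candidates = allowed & ~base
    if extra > int(candidates.sum()):
        raise InfeasibleVolumeError("not enough room to dilate the hemisphere")
    dist = distance_transform_edt(~base)
    coords = np.argwhere(candidates)
    d = dist[candidates]
    order = np.lexsort((coords[:, 1], coords[:, 0], d))
    out = base.copy()
    chosen = coords[order[:extra]]
    out[chosen[:, 0], chosen[:, 1]] = True
    return out


def generate_infarct_traces(
    record: AnimalRecord,
    atlas: TerritoryAtlas,
    config: CohortConfig,
    seed: int = 0,
) -> InfarctTraceSet:
    """Build per-section infarct and hemisphere masks for one animal.

    The infarct is grown inside the ipsilateral cortex and subcortex (seeded
    at the MCA-territory centroid of each compartment, so larger infarcts of
    different animals nest spatially) until the summed mask volumes match the
    record's cortical and subcortical volumes to within one voxel volume
    each. The ipsilateral hemisphere outline is dilated outward so that its
    traced volume equals the contralateral volume times the record's
    swelling ratio. Entirely deterministic given (record, atlas, config).
    """
    grid = atlas.grid
    side = config.occluded_side
    positions = config.section_positions
    spacing = config.section_spacing_mm
    n_sec = len(positions)
    vv = grid.pixel_size**2 * spacing

    ratio = record.ipsilateral_hemisphere_volume / record.contralateral_hemisphere_volume
    if ratio < 1.0:
        raise ValueError("hemisphere swelling ratio must be >= 1")

    level_of = [grid.nearest_level_index(p) for p in positions]
    half = grid.n_cols // 2
    cc = np.arange(grid.n_cols)[None, :]
    side_half = (
        np.broadcast_to(cc >= half, grid.shape)
        if side == "right"
        else np.broadcast_to(cc < half, grid.shape)
    )

    infarct = np.zeros((n_sec, *grid.shape), dtype=bool)
    ipsi = np.zeros_like(infarct)
    contra = np.zeros_like(infarct)

    targets = {
        "cortex": int(round(record.infarct_volume_cortical / vv)),
        "subcortex": int(round(record.infarct_volume_subcortical / vv)),
    }
    for comp, m_total in targets.items():
        regions, seeds, caps = [], [], []
        for s in range(n_sec):
            lvl = level_of[s]
            region = atlas.side_mask(comp, side)[lvl]
            core = region & atlas.masks["mca_territory"][lvl]
            anchor = core if core.any() else region
            centroid = np.argwhere(anchor).mean(axis=0)
            regions.append(region)
            seeds.append((float(centroid[0]), float(centroid[1])))
            caps.append(int(region.sum()))
        alloc = _allocate(m_total, caps)
        for s in range(n_sec):
            infarct[s] |= _grow_region(regions[s], seeds[s], int(alloc[s]))

    base_count = None
    for s in range(n_sec):
        lvl = level_of[s]
        contra_side = "left" if side == "right" else "right"
        contra[s] = atlas.hemisphere(contra_side)[lvl]
        base = atlas.hemisphere(side)[lvl]
        if base_count is None or int(contra[s].sum()) != base_count:
            base_count = int(contra[s].sum())
        target = int(round(base_count * ratio))
        ipsi[s] = _dilate_to_count(base, side_half, target)

    return InfarctTraceSet(
        infarct=infarct,
        ipsilateral=ipsi,
        contralateral=contra,
        positions=positions,
        spacing=spacing,
        pixel_size=grid.pixel_size,
        animal_id=record.animal_id,
    )
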