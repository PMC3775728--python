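"""Cohort generator: determinism, stratum moments, CBV fields, traces."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from achastroke import (
    CohortConfig,
    ConfigError,
    InfeasibleVolumeError,
    StratumParams,
    generate_cbv_maps,
    generate_cohort,
    generate_infarct_traces,
    mask_volume,
    split_cortical_subcortical,
    volume_from_traces,
)
from achastroke.synthetic import _truncated_normal


class TestCohortConfig:
    def test_defaults_match_study_composition(self, config):
        assert config.n_total == 28
        assert config.group_sizes() == {"1h": 8, "2h": 7, "permanent": 13}
        assert config.achao_counts() == {"1h": 2, "2h": 1, "permanent": 7}
        assert config.stratum("permanent", True) == StratumParams(144.5, 11.72)
        assert config.stratum("permanent", False) == StratumParams(42.7, 27.62)
        # temporary strata recovered from the pooled and permanent summaries
        assert config.stratum("1h", False).mean == pytest.approx(15.55)
        assert config.stratum("2h", True).mean == pytest.approx(94.8333, abs=1e-3)

    def test_achao_count_exceeding_group_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(achao_2h=8)

    def test_vessel_value_must_exceed_exclusion_threshold(self):
        with pytest.raises(ConfigError):
            CohortConfig(vessel_value=9.0)

    def test_round_trips_through_dict(self, config):
        back = CohortConfig.from_dict(config.to_dict())
        assert back == config


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self, config):
        a = generate_cohort(config, 42)
        b = generate_cohort(config, 42)
        assert a == b

    def test_different_seed_changes_realizations(self, config):
        a = generate_cohort(config, 42)
        b = generate_cohort(config, 43)
        assert [r.infarct_volume_total for r in a] != [
            r.infarct_volume_total for r in b
        ]

    def test_default_cohort_counts(self, cohort):
        assert len(cohort) == 28
        assert sum(r.acha_occluded for r in cohort) == 10

    def test_record_invariants(self, cohort):
        for r in cohort:
            assert r.infarct_volume_total == pytest.approx(
                r.infarct_volume_cortical + r.infarct_volume_subcortical
            )
            assert r.infarct_volume_total >= 0
            assert (
                r.ipsilateral_hemisphere_volume >= r.contralateral_hemisphere_volume
            )
            assert 300 <= r.weight_g <= 500

    def test_pmcao_achao_stratum_mean_converges(self):
        """10,000 draws from the permanent+AChAo stratum (144.5 +/- 11.72,
        truncation negligible at 12 SD from zero) land within 1% of 144.5."""
        rng = np.random.default_rng(0)
        draws = [_truncated_normal(rng, 144.5, 11.72) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(144.5, rel=0.01)

    @pytest.mark.parametrize("mean,sd", [(144.5, 11.72), (15.55, 23.38)])
    def test_stratum_moments_match_truncnorm_oracle(self, mean, sd):
        """Sample moments converge (3 SE at 10^4 draws) to the zero-truncated
        normal moments computed with an independent scipy.stats.truncnorm
        oracle; the low-mean stratum is strongly affected by truncation."""
        rng = np.random.default_rng(1)
        draws = np.array([_truncated_normal(rng, mean, sd) for _ in range(10_000)])
        dist = sps.truncnorm(a=-mean / sd, b=np.inf, loc=mean, scale=sd)
        se = dist.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - dist.mean()) < 3 * se
        assert draws.min() >= 0.0

    def test_weight_independent_of_volume(self, config):
        """The generator draws weight independently: across many cohorts the
        weight-volume correlation stays near zero."""
        vols, weights = [], []
        for seed in range(40):
            for r in generate_cohort(config, seed):
                vols.append(r.infarct_volume_total)
                weights.append(r.weight_g)
        r, _ = sps.pearsonr(weights, vols)
        assert abs(r) < 0.08


class TestGenerateCbvMaps:
    def test_one_map_per_bregma_level(self, atlas, quiet_config, cohort):
        maps = generate_cbv_maps(cohort[0], atlas, quiet_config, 1)
        assert [m.bregma_level for m in maps] == [0.0, -2.4]

    def test_zero_noise_patent_acha_at_or_above_contralateral(self, atlas, quiet_config):
        rec = next(r for r in generate_cohort(quiet_config, 2) if not r.acha_occluded)
        maps = generate_cbv_maps(rec, atlas, quiet_config, 2)
        caudal = next(m for m in maps if m.bregma_level == -2.4)
        lvl = atlas.grid.level_index(-2.4)
        acha = atlas.side_mask("acha_territory", "right")[lvl]
        contra = atlas.hemisphere("left")[lvl]
        vessel_free = caudal.values <= 10.0
        contra_mean = caudal.values[contra & vessel_free].mean()
        assert (caudal.values[acha] >= contra_mean).all()

    def test_zero_noise_occluded_acha_suppressed(self, atlas, quiet_config):
        rec = next(r for r in generate_cohort(quiet_config, 2) if r.acha_occluded)
        maps = generate_cbv_maps(rec, atlas, quiet_config, 2)
        caudal = next(m for m in maps if m.bregma_level == -2.4)
        lvl = atlas.grid.level_index(-2.4)
        acha = atlas.side_mask("acha_territory", "right")[lvl]
        assert (
            caudal.values[acha]
            == pytest.approx(4.0 * quiet_config.acha_residual_fraction)
        )

    def test_values_non_negative_with_noise(self, atlas, config, cohort):
        for m in generate_cbv_maps(cohort[0], atlas, config, 1):
            assert (m.values >= 0).all()

    def test_maps_deterministic_for_fixed_seed(self, atlas, config, cohort):
        a = generate_cbv_maps(cohort[3], atlas, config, 5)
        b = generate_cbv_maps(cohort[3], atlas, config, 5)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.values, mb.values)


class TestGenerateInfarctTraces:
    def test_volumes_match_record_within_one_voxel(self, atlas, config, cohort):
        for rec in cohort[:6]:
            traces = generate_infarct_traces(rec, atlas, config, 1)
            vv = traces.voxel_volume
            assert abs(
                volume_from_traces(traces, "infarct") - rec.infarct_volume_total
            ) <= 2 * vv
            cort, subc = split_cortical_subcortical(traces, atlas)
            assert abs(cort - rec.infarct_volume_cortical) <= vv
            assert abs(subc - rec.infarct_volume_subcortical) <= vv

    def test_mask_volume_oracle_agreement(self, atlas, config, cohort):
        """Per-section grid volume agrees with the geometry-module oracle
        computed slice by slice at the trace spacing."""
        traces = generate_infarct_traces(cohort[0], atlas, config, 1)
        total = sum(
            traces.infarct[s].sum() * traces.pixel_size**2 * traces.spacing
            for s in range(traces.n_sections)
        )
        assert volume_from_traces(traces, "infarct") == pytest.approx(total)

    def test_infarct_confined_to_ipsilateral_hemisphere(self, atlas, config, cohort):
        traces = generate_infarct_traces(cohort[0], atlas, config, 1)
        assert not (traces.infarct & ~traces.ipsilateral).any()

    def test_swelling_ratio_matches_record(self, atlas, config, cohort):
        traces = generate_infarct_traces(cohort[0], atlas, config, 1)
        ratio = volume_from_traces(traces, "ipsi") / volume_from_traces(traces, "contra")
        assert ratio == pytest.approx(1.10, abs=1e-3)

    def test_zero_volume_record_gives_empty_masks(self, atlas, config, cohort):
        rec = dataclasses.replace(
            cohort[0],
            infarct_volume_total=0.0,
            infarct_volume_cortical=0.0,
            infarct_volume_subcortical=0.0,
        )
        traces = generate_infarct_traces(rec, atlas, config, 1)
        assert traces.infarct.sum() == 0

    def test_infeasible_volume_rejected(self, atlas, config, cohort):
        rec = dataclasses.replace(
            cohort[0],
            infarct_volume_total=20_000.0,
            infarct_volume_cortical=10_000.0,
            infarct_volume_subcortical=10_000.0,
        )
        with pytest.raises(InfeasibleVolumeError):
            generate_infarct_traces(rec, atlas, config, 1)

    def test_traces_deterministic(self, atlas, config, cohort):
        a = generate_infarct_traces(cohort[1], atlas, config, 1)
        b = generate_infarct_traces(cohort[1], atlas, config, 1)
        assert np.array_equal(a.infarct, b.infarct)
        assert np.array_equal(a.ipsilateral, b.ipsilateral)
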