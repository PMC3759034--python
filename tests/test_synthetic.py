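"""Phantom geometry, artifact footprints, motion simulation, and the
additive signal model with its ground-truth sidecar."""

import numpy as np
import pytest
from scipy import ndimage

from icarank import (
    ArtifactSpec,
    ActivationSpec,
    PhantomSpec,
    build_block_regressor,
    make_artifact_map,
    make_phantom_geometry,
    simulate_motion_params,
    simulate_patient,
    simulate_run,
)


@pytest.fixture(scope="module")
def geometry(default_spec):
    return make_phantom_geometry(default_spec)


class TestGeometry:
    def test_construction_invariants(self, geometry):
        brain, vent, regions = geometry
        assert brain.any()
        assert (vent <= brain).all()
        names = list(regions)
        for i, a in enumerate(names):
            assert regions[a].any()
            assert (regions[a] <= brain).all()
            assert not (regions[a] & vent).any()
            for b in names[i + 1 :]:
                assert not (regions[a] & regions[b]).any()

    def test_rejects_degenerate_region_radius(self, default_spec):
        with pytest.raises(ValueError):
            make_phantom_geometry(default_spec, region_radius_frac=0.0)

    def test_rejects_small_grid(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(4, 32, 16))

    def test_deterministic(self, default_spec, geometry):
        brain2, vent2, regions2 = make_phantom_geometry(default_spec)
        np.testing.assert_array_equal(geometry[0], brain2)
        np.testing.assert_array_equal(geometry[1], vent2)


class TestArtifactMaps:
    def test_edge_rim_excludes_eroded_brain(self, geometry):
        brain, vent, _ = geometry
        rim = make_artifact_map("edge_rim", brain, vent)
        eroded = ndimage.binary_erosion(brain)
        assert not ((rim > 0) & eroded).any()
        assert (rim > 0).any()

    def test_ghost_is_half_fov_shift_of_brain(self, geometry):
        """N/2 ghost geometry: exact circular shift along the phase-encode axis."""
        brain, vent, _ = geometry
        ghost = make_artifact_map("nyquist_ghost", brain, vent)
        shift = brain.shape[1] // 2
        np.testing.assert_array_equal(ghost > 0, np.roll(brain, shift, axis=1))

    def test_ventricle_outline_count_matches_morphology_oracle(self, geometry):
        """Brute-force face-neighbour dilation oracle on the small grid."""
        brain, vent, _ = geometry
        outline = make_artifact_map("ventricle_outline", brain, vent) > 0
        dilated = np.zeros_like(vent)
        idx = np.argwhere(vent)
        for dx, dy, dz in [(1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1),(0,0,0)]:
            shifted = idx + [dx, dy, dz]
            ok = np.all((shifted >= 0) & (shifted < vent.shape), axis=1)
            dilated[tuple(shifted[ok].T)] = True
        oracle = dilated & ~vent
        assert outline.sum() == oracle.sum()
        np.testing.assert_array_equal(outline, oracle)

    def test_rejects_unknown_kind(self, geometry):
        brain, vent, _ = geometry
        with pytest.raises(ValueError):
            make_artifact_map("spaceship", brain, vent)


class TestMotionParams:
    def test_random_walk_uncorrelated_with_task(self):
        box = np.tile(build_block_regressor(4, 3, 8, 2.5).values, 10)
        table = simulate_motion_params(560, "random_walk", seed=0)
        r = np.corrcoef(table[:, 0], box)[0, 1]
        assert abs(r) < 0.35  # random walks wander; no systematic coupling

    def test_stimulus_locked_hits_target_correlation(self):
        box = np.tile(build_block_regressor(4, 3, 8, 2.5).values, 4)
        table = simulate_motion_params(
            224, "stimulus_locked", 0.8, seed=1, task=box
        )
        for col in range(6):
            r = np.corrcoef(table[:, col], box)[0, 1]
            assert 0.7 < r < 0.9

    def test_zero_amplitudes_give_zero_table(self):
        box = build_block_regressor(4, 3, 8, 2.5).values
        table = simulate_motion_params(
            56, "stimulus_locked", 0.8, seed=2, task=box,
            translation_mm=0.0, rotation_rad=0.0,
        )
        assert np.all(table == 0)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            simulate_motion_params(56, "random_walk", 1.5)


class TestSimulateRun:
    def test_noise_free_percent_signal_change(self):
        """Configured psc is exact at the response plateau without noise."""
        spec = PhantomSpec(
            noise_sd=0.0,
            drift_amplitude=0.0,
            artifact_specs=[],
            activation_regions=[ActivationSpec("motor_left", 2.0)],
            seed=5,
        )
        vol, truth = simulate_run(spec)
        mask = truth.activation_masks["motor_left"]
        peak = vol.data[mask].max()
        assert abs(peak - 1.02 * spec.baseline) < 1e-6

    def test_default_run_is_56_volumes(self):
        vol, _ = simulate_run(PhantomSpec(seed=6))
        assert vol.n_volumes == 56

    def test_deterministic_under_seed(self):
        spec = PhantomSpec(seed=7)
        v1, t1 = simulate_run(spec)
        v2, t2 = simulate_run(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(t1.motion_params, t2.motion_params)

    def test_artifact_course_correlation_with_task(self):
        spec = PhantomSpec(
            n_rest_phases=16, n_task_phases=15, seed=8,
            artifact_specs=[ArtifactSpec("edge_rim", 15.0, "stimulus_locked", 0.8)],
        )
        vol, truth = simulate_run(spec)
        assert vol.n_volumes == 248
        box = build_block_regressor(16, 15, 8, 2.5).values
        r = np.corrcoef(truth.artifact_timecourses["edge_rim"], box)[0, 1]
        assert abs(r - 0.8) < 0.1

    def test_rejects_invalid_artifact_spec(self):
        with pytest.raises(ValueError):
            ArtifactSpec("edge_rim", correlation_with_task=1.2)


class TestSimulatePatient:
    def test_twelve_runs_give_672_volumes(self):
        spec = PhantomSpec(n_runs=12, noise_sd=0.0, drift_amplitude=0.0,
                           artifact_specs=[], seed=9)
        vol, truth, boundaries = simulate_patient(spec)
        assert vol.n_volumes == 672
        assert boundaries == list(range(0, 672, 56))
        assert truth.motion_params.shape == (672, 6)

    def test_zero_per_run_amplitudes_remove_activation(self):
        spec = PhantomSpec(
            n_runs=2, noise_sd=0.0, drift_amplitude=0.0, artifact_specs=[],
            activation_regions=[
                ActivationSpec("motor_left", 2.0, per_run_amplitudes=(0.0, 0.0))
            ],
            seed=10,
        )
        vol, truth, _ = simulate_patient(spec)
        mask = truth.activation_masks["motor_left"]
        np.testing.assert_allclose(vol.data[mask], spec.baseline)

    def test_single_run_equals_simulate_run(self):
        spec = PhantomSpec(n_runs=1, seed=12)
        v1, t1, _ = simulate_patient(spec)
        v2, t2 = simulate_run(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
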