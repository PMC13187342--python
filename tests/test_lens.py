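"""Transducer placement, phase-conjugate lens design and focal metrics."""

import numpy as np
import pytest

from tuslab.errors import ValidationError
from tuslab.lens import (
    LensMaterial,
    design_lens,
    focal_metrics,
    forward_verify,
    place_transducer,
    wrap_thickness,
)
from tuslab.protocol import PulseProtocol
from tuslab.solver import (
    AcousticMedium,
    ComplexField,
    ReceiverField,
    point_source_backward,
)


def make_receiver(amplitude, phase=None, spacing=0.5, plane_coordinate=56.0):
    amplitude = np.asarray(amplitude, float)
    if phase is None:
        phase = np.zeros_like(amplitude)
    coords = (np.arange(amplitude.size) * spacing,)
    return ReceiverField(
        amplitude=amplitude, phase=np.asarray(phase), coords=coords,
        plane_axis=1, plane_coordinate=plane_coordinate, spacing=spacing,
        frequency=500e3,
    )


class TestPlaceTransducer:
    def test_matches_brute_force_objective(self):
        rng = np.random.default_rng(0)
        amp = rng.uniform(0.1, 1.0, size=129)
        recv = make_receiver(amp)
        pose = place_transducer(recv, aperture_diameter=20.0)
        half = int(20.0 / 2 / 0.5)
        best, best_i = -np.inf, None
        offsets = np.arange(-half, half + 1)
        footprint = np.abs(offsets) <= 20.0 / 2 / 0.5
        for i in range(half, amp.size - half):
            mean = amp[i + offsets[footprint]].mean()
            if mean > best + 1e-15:
                best, best_i = mean, i
        assert pose.centre[0] == pytest.approx(recv.coords[0][best_i])

    def test_symmetric_peak_centred(self):
        x = np.arange(129) * 0.5
        amp = np.exp(-((x - 32.0) ** 2) / 50.0)
        pose = place_transducer(make_receiver(amp), aperture_diameter=20.0)
        assert pose.centre[0] == pytest.approx(32.0)
        assert not pose.tie
        assert pose.normal[1] == -1.0  # points into the head

    def test_uniform_amplitude_ties_flagged_first_index_chosen(self):
        recv = make_receiver(np.ones(101))
        pose = place_transducer(recv, aperture_diameter=10.0)
        assert pose.tie
        half = int(10.0 / 2 / 0.5)
        assert pose.centre[0] == pytest.approx(recv.coords[0][half])

    def test_aperture_larger_than_plane_rejected(self):
        with pytest.raises(ValidationError, match="aperture"):
            place_transducer(make_receiver(np.ones(32)), aperture_diameter=64.0)


class TestDesignLens:
    def test_wrap_thickness_pdms_in_water(self):
        t = wrap_thickness(LensMaterial(sound_speed=1030.0), 500e3, 1482.0)
        oracle = 1.0 / (500e3 * (1.0 / 1030.0 - 1.0 / 1482.0)) * 1e3
        assert t == pytest.approx(oracle)
        assert t == pytest.approx(6.754, abs=1e-3)

    def test_uniform_phase_gives_base_thickness(self):
        recv = make_receiver(np.ones(129), np.full(129, 0.7))
        pose = place_transducer(recv, aperture_diameter=20.0)
        design = design_lens(recv, pose)
        assert np.allclose(design.thickness_map, design.base_thickness)
        assert np.allclose(design.phase_map, 0.0)

    def test_matched_sound_speed_rejected(self):
        recv = make_receiver(np.ones(129))
        pose = place_transducer(recv, aperture_diameter=20.0)
        with pytest.raises(ValidationError, match="sound speed"):
            design_lens(recv, pose, LensMaterial(sound_speed=1482.0), 500e3,
                        medium_speed=1482.0)

    def test_homogeneous_medium_focus_lands_on_target(self):
        medium = AcousticMedium.homogeneous((192, 160), 0.5)
        target = [48.0, 30.0]
        brain = np.zeros((192, 160), bool)
        brain[20:172, 10:100] = True
        recv = point_source_backward(medium, target, 1, 72.0)
        pose = place_transducer(recv, 64.0)
        design = design_lens(recv, pose)
        # Fresnel-like annuli: thickness map has multiple wrap discontinuities
        jumps = np.abs(np.diff(design.thickness_map))
        assert (jumps > 0.5 * design.t_2pi).sum() >= 2
        _, metrics = forward_verify(
            medium, pose, design, PulseProtocol(), brain, target
        )
        assert metrics.targeting_error <= 0.5  # within one voxel


class TestForwardVerify:
    def test_scaled_peak_equals_protocol_pressure(self, planned_default_phantoms):
        run = planned_default_phantoms[1]
        brain = run["volume"].mask("brain")
        peak = np.where(brain, run["field"].amplitude, 0.0).max()
        assert peak == pytest.approx(600e3, rel=1e-9)
        assert run["field"].scaled

    def test_lens_beats_no_lens_through_aberrating_skull(self, small_aberrated_runs):
        # per unit aperture drive, the phase-conjugate lens must deliver at
        # least the unlensed pressure at the target on every phantom
        for run in small_aberrated_runs:
            idx = run["field"].world_to_index(run["annotations"]["target_gpi"])
            p_lens = run["field"].amplitude[idx] / run["metrics"].drive_scale
            p_flat = (
                run["field_unlensed"].amplitude[idx]
                / run["metrics_unlensed"].drive_scale
            )
            assert p_lens >= p_flat
        errors_lens = [r["metrics"].targeting_error for r in small_aberrated_runs]
        errors_flat = [r["metrics_unlensed"].targeting_error for r in small_aberrated_runs]
        assert np.median(errors_lens) <= np.median(errors_flat)

    def test_empty_brain_mask_rejected(self, planned_default_phantoms):
        run = planned_default_phantoms[1]
        with pytest.raises(ValidationError, match="brain"):
            forward_verify(
                run["medium"], run["pose"], run["design"], run["protocol"],
                np.zeros_like(run["volume"].labels, bool),
                run["annotations"]["target_gpi"],
            )

    def test_lens_idempotence(self, planned_default_phantoms):
        """A backward run from the achieved focus reproduces the lens design
        to within a small fraction of the wrap thickness."""
        run = planned_default_phantoms[1]
        recv2 = point_source_backward(
            run["medium"], run["metrics"].peak_location, 1,
            run["annotations"]["receiver_coordinate"],
            frequency=run["protocol"].fundamental_frequency,
        )
        design2 = design_lens(recv2, run["pose"])
        dphi = np.angle(np.exp(1j * (design2.phase_map - run["design"].phase_map)))
        rms = np.sqrt(np.mean(dphi**2))
        assert rms < np.pi / 4  # << one wrap quantum


class TestFocalMetrics:
    def _field(self, amp, spacing=0.5):
        return ComplexField(
            pressure=amp.astype(complex), spacing=spacing,
            origin=np.zeros(amp.ndim), frequency=500e3, scaled=True,
        )

    def test_single_voxel_field(self):
        amp = np.zeros((40, 40))
        amp[10, 12] = 1.0
        f = self._field(amp)
        m = focal_metrics(f, np.ones((40, 40), bool), [5.0, 6.0])
        assert m.targeting_error == 0.0
        assert m.focal_region.sum() == 1

    def test_offset_blob_error_is_grid_distance(self):
        amp = np.zeros((40, 40))
        amp[12, 12] = 1.0  # 2 voxels = 1.0 mm from the target voxel (10, 12)
        m = focal_metrics(self._field(amp), np.ones((40, 40), bool), [5.0, 6.0])
        assert m.targeting_error == pytest.approx(1.0)

    def test_gaussian_minus6db_area_matches_level_set(self):
        n, spacing = 120, 0.5
        x = np.arange(n) * spacing
        X, Y = np.meshgrid(x, x, indexing="ij")
        sigma = 3.0  # mm
        amp = np.exp(-((X - 30) ** 2 + (Y - 30) ** 2) / (2 * sigma**2))
        m = focal_metrics(self._field(amp), np.ones((n, n), bool), [30.0, 30.0])
        analytic = 2 * np.pi * np.log(2) * sigma**2
        assert m.focal_extent == pytest.approx(analytic, rel=0.05)

    def test_electrode_clearance_distance(self):
        amp = np.zeros((40, 40))
        amp[10, 10] = 1.0
        electrode = np.zeros((40, 40), bool)
        electrode[10, 30] = True  # 20 voxels = 10 mm away
        m = focal_metrics(
            self._field(amp), np.ones((40, 40), bool), [5.0, 5.0], electrode
        )
        assert m.electrode_clearance == pytest.approx(10.0)

    def test_zero_field_rejected(self):
        amp = np.zeros((20, 20))
        with pytest.raises(ValidationError, match="zero"):
            focal_metrics(self._field(amp), np.ones((20, 20), bool), [5.0, 5.0])
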