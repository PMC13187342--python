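"""Shared fixtures.

The expensive artefacts — planned phantoms with verified forward fields —
are computed once per test session and shared, since targeting, safety
and lens-benefit checks all consume the same runs.
"""

from __future__ import annotations

import pytest

from tuslab.lens import design_lens, forward_verify, place_transducer
from tuslab.materials import default_materials
from tuslab.phantom import PhantomSpec, generate_head_phantom, property_maps
from tuslab.protocol import PulseProtocol
from tuslab.solver import AcousticMedium, SolverConfig, point_source_backward


def plan_phantom(spec: PhantomSpec, aperture: float = 64.0,
                 config: SolverConfig = SolverConfig(),
                 with_unlensed: bool = False):
    """Full planning chain on one phantom; returns a result bundle."""
    volume, ann = generate_head_phantom(spec)
    maps = property_maps(volume, default_materials())
    medium = AcousticMedium.from_property_maps(maps)
    protocol = PulseProtocol()
    receiver = point_source_backward(
        medium, ann["target_gpi"], plane_axis=volume.labels.ndim - 1,
        plane_coordinate=ann["receiver_coordinate"], config=config,
        frequency=protocol.fundamental_frequency,
        brain_mask=volume.mask("brain"),
    )
    pose = place_transducer(receiver, aperture)
    design = design_lens(receiver, pose)
    field_, metrics = forward_verify(
        medium, pose, design, protocol, volume.mask("brain"),
        ann["target_gpi"], volume.mask("electrode"), config=config,
    )
    out = {
        "spec": spec, "volume": volume, "annotations": ann, "maps": maps,
        "medium": medium, "protocol": protocol, "receiver": receiver,
        "pose": pose, "design": design, "field": field_, "metrics": metrics,
    }
    if with_unlensed:
        field_flat, metrics_flat = forward_verify(
            medium, pose, design, protocol, volume.mask("brain"),
            ann["target_gpi"], volume.mask("electrode"), config=config,
            apply_lens=False,
        )
        out["field_unlensed"] = field_flat
        out["metrics_unlensed"] = metrics_flat
    return out


@pytest.fixture(scope="session")
def planned_default_phantoms():
    """Planning runs on the default phantom geometry, seeds 1-4."""
    return {
        seed: plan_phantom(PhantomSpec(seed=seed)) for seed in (1, 2, 3, 4)
    }


SMALL_PHANTOM_KW = dict(
    grid_shape=(160, 144),
    head_centre=(40.0, 32.0),
    outer_radius=24.0,
    electrode_position=(44.0, 28.0),
    target_gpi=(37.0, 27.0),
    target_ventricle=(43.0, 34.0),
)


@pytest.fixture(scope="session")
def small_aberrated_runs():
    """Lens-vs-no-lens planning runs on five small aberrated phantoms."""
    runs = []
    for seed in range(5, 10):
        spec = PhantomSpec(seed=seed, skull_aberration_amplitude=1.5,
                           **SMALL_PHANTOM_KW)
        runs.append(plan_phantom(spec, with_unlensed=True))
    return runs


@pytest.fixture(scope="session")
def homogeneous_point_field():
    """Point-source field in a homogeneous lossless water box."""
    from tuslab.solver import SourceSpec, simulate_field

    medium = AcousticMedium.homogeneous((160, 160), 0.5)
    source = SourceSpec(kind="point", positions=[40.0, 40.0], frequency=500e3)
    return simulate_field(medium, source)
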