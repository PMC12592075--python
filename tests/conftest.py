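import logging

import numpy as np
import pytest

from cordmorph.synthetic import (
    CanalImageSpec,
    CellFieldSpec,
    CellSpec,
    generate_canal_stack,
    generate_cell_stack,
)

# constant-slice warnings from empty z planes are expected with noise-free
# cell channels and would swamp test output
logging.getLogger("cordmorph.cell_mapping").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_canal_spec() -> CanalImageSpec:
    """Noise-free canal: planted outer contour 18 x 42 um at 30 deg."""
    return CanalImageSpec(
        image_shape=(220, 220),
        n_slices=2,
        d_min_um=18.0,
        d_max_um=42.0,
        orientation_deg=30.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_canal_stack(clean_canal_spec):
    return generate_canal_stack(clean_canal_spec)


@pytest.fixture(scope="session")
def small_cell_field():
    """16-slice field with three supra-threshold cells and one distractor."""
    canal = CanalImageSpec(image_shape=(300, 300), n_slices=16, noise_sd=0.0, seed=5)
    cells = (
        CellSpec(radial_distance_um=30, polar_angle_deg=0, z_slice=8, volume_voxels=7000),
        CellSpec(radial_distance_um=30, polar_angle_deg=120, z_slice=8, volume_voxels=6000),
        CellSpec(radial_distance_um=30, polar_angle_deg=240, z_slice=8, volume_voxels=6500),
        CellSpec(radial_distance_um=40, polar_angle_deg=60, z_slice=8, volume_voxels=500),
    )
    spec = CellFieldSpec(canal=canal, cells=cells, seed=6)
    stack, truth = generate_cell_stack(spec)
    return spec, stack, truth


def ring_image(
    shape=(200, 200),
    center_um=None,
    d_min=18.0,
    d_max=42.0,
    orientation=0.0,
    thickness=3.0,
    pixel_size=0.31,
    gap_deg: float | None = None,
    fg=0.9,
    bg=0.1,
):
    """Hand-built ring intensity image; ``gap_deg`` cuts a wedge out of it."""
    from cordmorph.synthetic import _ellipse_mask

    if center_um is None:
        center_um = (
            (shape[1] - 1) / 2 * pixel_size,
            (shape[0] - 1) / 2 * pixel_size,
        )
    outer = _ellipse_mask(shape, pixel_size, center_um, d_min, d_max, orientation)
    inner = _ellipse_mask(
        shape, pixel_size, center_um, d_min - 2 * thickness, d_max - 2 * thickness, orientation
    )
    ring = outer & ~inner
    if gap_deg is not None:
        y = np.arange(shape[0])[:, None] * pixel_size - center_um[1]
        x = np.arange(shape[1])[None, :] * pixel_size - center_um[0]
        ang = np.degrees(np.arctan2(y, x)) % 360.0
        ring &= ~(ang < gap_deg)
    img = np.full(shape, bg)
    img[ring] = fg
    return img
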