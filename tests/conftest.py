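"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

from bronchowall.airway import CrossSection, _plane_basis
from bronchowall.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, undeformed standard phantom (96^3, 0.625 mm)."""
    spec = PhantomSpec(seed=3, noise_sigma=0.0, deformation_amplitude=0.0)
    ct, ute, t2, truth = generate_phantom(spec)
    return {"spec": spec, "ct": ct, "ute": ute, "t2": t2, "truth": truth}


@pytest.fixture(scope="session")
def plugged_phantom():
    """Noise-free phantom with the RUL path mucus-plugged."""
    spec = PhantomSpec(
        seed=4, noise_sigma=0.0, deformation_amplitude=0.0, mucus_plug_paths=("RUL",)
    )
    ct, ute, t2, truth = generate_phantom(spec)
    return {"spec": spec, "ct": ct, "ute": ute, "t2": t2, "truth": truth}


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Single straight tube (trachea only), no bifurcations."""
    spec = PhantomSpec(
        seed=5,
        grid_shape=(48, 48, 64),
        tree_depth=0,
        lumen_radius_by_generation=(3.0,),
        wall_thickness_by_generation=(2.0,),
        noise_sigma=0.0,
        deformation_amplitude=0.0,
    )
    ct, ute, t2, truth = generate_phantom(spec)
    return {"spec": spec, "ct": ct, "ute": ute, "t2": t2, "truth": truth}


@pytest.fixture(scope="session")
def clean_lumen_tree(clean_phantom):
    """Segmented lumen + centerline tree of the clean phantom."""
    from bronchowall.airway import extract_centerline, segment_lumen

    ct = clean_phantom["ct"]
    truth = clean_phantom["truth"]
    lumen = segment_lumen(ct, truth.trachea_seed_mm)
    tree = extract_centerline(lumen, ct.affine, truth.trachea_seed_mm)
    return {"lumen": lumen, "tree": tree}


def make_annulus_section(
    r_in=2.0,
    r_out=4.0,
    spacing=0.3,
    size=16.0,
    noise=0.0,
    seed=0,
    lumen=-1000.0,
    wall=0.0,
    parenchyma=-850.0,
):
    """Analytic annulus cross-section (the wall-measurement oracle input)."""
    n = int(size / spacing) + 1
    c = (n - 1) / 2
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(yy - c, xx - c) * spacing
    img = np.full((n, n), parenchyma, dtype=float)
    img[r <= r_out] = wall
    img[r <= r_in] = lumen
    if noise > 0:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    normal = np.array([0.0, 0.0, 1.0])
    return CrossSection(
        image=img,
        spacing_mm=spacing,
        center_mm=np.zeros(3),
        normal=normal,
        axes=_plane_basis(normal),
    )


@pytest.fixture
def annulus_section():
    return make_annulus_section
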