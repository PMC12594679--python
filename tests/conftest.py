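"""Shared fixtures: fast small-geometry phantoms.

The default phantom geometry matches the target acquisition conditions (512x512
in-plane, capillary ~1.1 µm radius); unit tests use a scaled-down
capillary in a 256x256 field so each stack generates and analyses in a
fraction of a second.  Feature prototypes are shrunk accordingly (peg
penetration and tubule radius must fit the thinner endothelium).
"""

from __future__ import annotations

import numpy as np
import pytest

from nvumorph import DetachmentSpec, PegSpec, PhantomSpec, TubuleSpec, generate_phantom

SMALL_GEOMETRY = dict(
    shape_yx=(256, 256),
    lumen_radius_nm=200.0,
    endothelium_thickness_nm=130.0,
    bm_base_nm=60.0,
    pericyte_thickness_nm=90.0,
    macroglia_thickness_nm=90.0,
)


def small_spec(n_slices: int = 20, **overrides) -> PhantomSpec:
    kwargs = {**SMALL_GEOMETRY, "n_slices": n_slices}
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def small_peg(z_center: int, theta: float, **kw) -> PegSpec:
    kw.setdefault("depth_nm", 80.0)
    return PegSpec(z_center=z_center, theta=theta, **kw)


def small_tubule(z_center: int, theta: float, **kw) -> TubuleSpec:
    kw.setdefault("radius_nm", 30.0)
    return TubuleSpec(z_center=z_center, theta=theta, **kw)


def small_detachment(target: str, z_center: int, theta: float, **kw) -> DetachmentSpec:
    return DetachmentSpec(target, z_center=z_center, theta=theta, **kw)


@pytest.fixture(scope="session")
def plain_phantom():
    """Feature-free small capillary (session-cached)."""
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def featured_phantom():
    """Small capillary with one feature of every family (session-cached)."""
    spec = small_spec(
        n_slices=40,
        pegs=(
            small_peg(8, 0.2),
            small_peg(20, -1.0, state="partially_detached", gap_nm=30.0),
        ),
        detachments=(
            small_detachment("endothelium", 14, -2.4),
            small_detachment("pericyte", 30, 1.1, arc_rad=0.5),
            small_detachment("macroglia", 33, 2.6, arc_rad=0.5),
        ),
        tubules=(
            small_tubule(12, 2.0, opening="closed"),
            small_tubule(26, -1.8, opening="luminal"),
            small_tubule(34, -2.9, opening="abluminal"),
        ),
        rng_seed=3,
    )
    return spec, *generate_phantom(spec)


def random_blob_mask(rng: np.random.Generator, size: int = 64, q: float = 0.8) -> np.ndarray:
    """A random smooth blob mask for oracle comparisons."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.normal(size=(size, size)), 5)
    mask = noise > np.quantile(noise, q)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    return mask
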