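"""Vascular basement-membrane thickness from 2D local thickness.

Thickness is measured per serial section, not in 3D: with 100 nm
sections against 6 nm in-plane pixels, 3D inscribed spheres would be
dominated by the axial anisotropy.  Within a slice the local thickness
at a pixel is the diameter of the largest disc fully inscribed in the
BM mask that covers the pixel (the 2D Hildebrand–Rüegsegger
definition), and thickness samples are taken at the medial-axis
pixels (maximal-disc centres) so that thick regions are not
over-weighted by area.

Disc convention
---------------
Discs are centred on pixel centres with integer radius ``rho``; a disc
of radius ``rho`` covers the pixels whose centres lie within Euclidean
distance ``rho`` and has odd pixel diameter ``2*rho + 1``.  ``rho`` is
the largest integer strictly below the Euclidean distance-transform
value, so for a disc that exactly fits (integer EDT) the diameter is
``2*EDT - 1``: a 5x5 solid square has centre thickness 5, a one-pixel
bar thickness 1.  :func:`brute_force_local_thickness` recomputes the
same quantity by exhaustive disc search without the distance transform
and serves as the validation oracle for the fast path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from .io import LabelVolume, RoleMap, role_mask

logger = logging.getLogger("nvumorph")


class EmptySliceError(ValueError):
    """Raised when a slice contains no basement-membrane voxels."""


# ---------------------------------------------------------------------------
# Fast path
# ---------------------------------------------------------------------------

def _exact_sq_edt(mask: np.ndarray) -> np.ndarray:
    """Exact squared Euclidean distance (integer) from each mask pixel to
    the nearest background pixel centre.  Pixels beyond the image border
    count as background (matching the exhaustive oracle); background
    pixels get 0."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int64)
    pad = np.pad(mask, 1, constant_values=False)
    idx = ndimage.distance_transform_edt(pad, return_distances=False, return_indices=True)
    ii, jj = np.indices(pad.shape)
    d2 = (ii - idx[0]) ** 2 + (jj - idx[1]) ** 2
    return d2[1:-1, 1:-1].astype(np.int64)


def _isqrt(m: np.ndarray) -> np.ndarray:
    """Exact floor(sqrt(m)) for a non-negative integer array."""
    r = np.floor(np.sqrt(m.astype(np.float64))).astype(np.int64)
    r = np.where((r + 1) ** 2 <= m, r + 1, r)
    r = np.where(r**2 > m, r - 1, r)
    return r


def inscribed_radius_map(mask: np.ndarray) -> np.ndarray:
    """Largest integer disc radius centred at each mask pixel that stays
    inside the mask (0 outside the mask and for single-pixel clearance)."""
    mask = np.asarray(mask, dtype=bool)
    d2 = _exact_sq_edt(mask)
    rho = np.zeros(mask.shape, dtype=np.int64)
    inside = mask & (d2 >= 1)
    # rho = max integer k with k^2 < d2  <=>  k = isqrt(d2 - 1)
    rho[inside] = _isqrt(d2[inside] - 1)
    return rho


def _disc(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius**2


def local_thickness_map(mask: np.ndarray) -> np.ndarray:
    """Per-pixel local thickness in pixels (odd integers; 0 off-mask).

    Paints inscribed discs in decreasing radius order: each pixel's
    thickness is the diameter ``2*rho + 1`` of the largest inscribed
    disc covering it.  Disc coverage is evaluated with a distance
    transform (distance to the nearest disc centre of the current
    radius), which is equivalent to dilation by the Euclidean disc.
    """
    mask = np.asarray(mask, dtype=bool)
    rho = inscribed_radius_map(mask)
    out = np.zeros(mask.shape, dtype=np.int64)
    for r in np.unique(rho[mask])[::-1]:
        centres = rho == r
        if r > 0:
            cov = ndimage.distance_transform_edt(~centres) <= r
        else:
            cov = centres
        np.copyto(out, 2 * int(r) + 1, where=cov & mask & (out == 0))
    return out


def medial_samples(mask: np.ndarray) -> np.ndarray:
    """Boolean map of thickness-sampling pixels: maximal-disc centres.

    A pixel is sampled iff the largest disc covering it is the one
    centred on it (``local thickness == 2*rho + 1``) — the discrete
    medial axis as the locus of maximal inscribed discs.  Unlike
    thinning-based skeletons this rule is invariant under translation,
    90° rotations and flips, and it discards pixels whose own disc is
    swallowed by a neighbouring ridge disc (rasterisation bumps along
    the boundary), which would otherwise bias the mean low.
    """
    mask = np.asarray(mask, dtype=bool)
    rho = inscribed_radius_map(mask)
    return mask & (local_thickness_map(mask) == 2 * rho + 1)


def slice_local_thickness(bm_mask: np.ndarray, in_plane_voxel_nm: float) -> np.ndarray:
    """Thickness samples (nm) at the medial-axis pixels of a 2D BM mask.

    Samples are the diameters of the maximal inscribed discs at the
    pixels selected by :func:`medial_samples`, converted to nm.

    Raises :class:`EmptySliceError` for an empty mask; the caller
    decides whether to skip the slice or abort.  Fragmented masks are
    handled naturally: inscribed discs respect component boundaries,
    and samples are pooled across components.
    """
    if in_plane_voxel_nm <= 0:
        raise ValueError("in-plane voxel size must be positive")
    bm_mask = np.asarray(bm_mask, dtype=bool)
    if not bm_mask.any():
        raise EmptySliceError("no BM in slice")
    rho = inscribed_radius_map(bm_mask)
    keep = bm_mask & (local_thickness_map(bm_mask) == 2 * rho + 1)
    return (2 * rho[keep] + 1) * float(in_plane_voxel_nm)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_local_thickness(bm_mask: np.ndarray, max_area: int = 20000) -> np.ndarray:
    """Exhaustive-search local thickness map in pixels.

    For every mask pixel the largest inscribed odd-diameter disc is
    found by direct window tests (no distance transform), then painted.
    Deliberately independent of the fast path; quadratic-ish, so the
    mask area is capped.
    """
    mask = np.asarray(bm_mask, dtype=bool)
    area = int(mask.sum())
    if area > max_area:
        raise ValueError(f"mask area {area} exceeds oracle cap {max_area}")
    H, W = mask.shape
    ys, xs = np.nonzero(mask)

    discs: dict[int, np.ndarray] = {}

    def disc(r: int) -> np.ndarray:
        if r not in discs:
            discs[r] = _disc(r)
        return discs[r]

    def fits(y: int, x: int, r: int) -> bool:
        if y - r < 0 or x - r < 0 or y + r >= H or x + r >= W:
            # pixels outside the image count as background
            return False
        win = mask[y - r : y + r + 1, x - r : x + r + 1]
        return bool(np.all(win[disc(r)]))

    rho = np.zeros((H, W), dtype=np.int64)
    for y, x in zip(ys, xs):
        r = 0
        while fits(y, x, r + 1):
            r += 1
        rho[y, x] = r

    out = np.zeros((H, W), dtype=np.int64)
    for y, x in zip(ys, xs):
        r = int(rho[y, x])
        d = 2 * r + 1
        sl = (slice(y - r, y + r + 1), slice(x - r, x + r + 1))
        region = out[sl]
        np.copyto(region, d, where=disc(r) & (region < d))
    return np.where(mask, out, 0)


# ---------------------------------------------------------------------------
# Stack aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceThickness:
    z: int
    samples_nm: np.ndarray
    slice_mean_nm: float
    slice_max_nm: float


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-slice and aggregate BM thickness of one stack.

    ``aggregate_mean_nm`` is the sample-count-weighted mean of slice
    means (equivalently the mean over all pooled samples);
    ``aggregate_max_nm`` is the global maximum sample.  Slices with an
    empty BM mask contribute nothing and are listed in ``skipped_z``.
    """

    per_slice: tuple[SliceThickness, ...]
    skipped_z: tuple[int, ...]
    aggregate_mean_nm: float
    aggregate_max_nm: float
    n_samples_total: int

    def __post_init__(self):
        if not 0 < self.aggregate_mean_nm <= self.aggregate_max_nm:
            raise ValueError("need 0 < aggregate mean <= aggregate max")


def stack_thickness(volume: LabelVolume, role_map: RoleMap) -> ThicknessProfile:
    """Measure BM thickness slice by slice and aggregate.

    Raises ``ValueError`` if no basement membrane is labelled anywhere;
    empty slices are skipped with a warning.
    """
    bm = role_mask(volume, role_map, "basement_membrane")
    if not bm.any():
        raise ValueError("no basement membrane labeled")
    nm = volume.in_plane_nm
    per_slice: list[SliceThickness] = []
    skipped: list[int] = []
    for z in range(volume.n_slices):
        try:
            samples = slice_local_thickness(bm[z], nm)
        except EmptySliceError:
            skipped.append(z)
            continue
        per_slice.append(
            SliceThickness(z, samples, float(samples.mean()), float(samples.max()))
        )
    if skipped:
        logger.warning("skipped %d slice(s) with empty BM mask: %s", len(skipped), skipped[:10])
    pooled = np.concatenate([s.samples_nm for s in per_slice])
    return ThicknessProfile(
        per_slice=tuple(per_slice),
        skipped_z=tuple(skipped),
        aggregate_mean_nm=float(pooled.mean()),
        aggregate_max_nm=float(pooled.max()),
        n_samples_total=int(pooled.size),
    )
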