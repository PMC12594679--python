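"""Detection of NVU ultrastructural features in labelled stacks.

Three detectors operate on role masks derived from a segmentation:

* **peg-and-socket formations** — 3D connected components of pericyte
  voxels lying inside the *endothelial envelope* and connected, through
  the BM, to pericyte material outside it.  The envelope is computed per
  slice as the hole-filled morphological closing of the capillary wall
  (endothelium, lumen and BM together): the closing seals the narrow
  BM-crossing mouth of each socket and the fill recovers the enclosed
  interior, so peg tips and any lucent socket space are inside the
  envelope while the pericyte body stays outside.  A peg whose adjacent
  intra-socket lucent (background) shell reaches the configured in-plane
  width is classified partially detached, otherwise attached.
* **cell–BM detachments** — 3D connected components of electron-lucent
  (background) voxels sandwiched between the BM and a target cell role:
  candidates lie within a bounded in-plane search distance of both
  masks, the component must touch both within one in-plane step, and its
  in-plane width must reach the configured minimum.  Lucent voxels
  already claimed by a peg's socket are excluded so nothing is counted
  twice.
* **endothelial tubules** — 3D connected components of tubule voxels,
  classified by in-plane face adjacency: luminal (touching the lumen),
  abluminal (touching the BM), transendothelial (both), closed
  (neither).

Components use 26-connectivity on the anisotropic voxel grid (z
neighbours are 100 nm apart versus 6 nm in-plane; features persist
across sections, and face-only connectivity fragments thin pegs).
Adjacency tests for openings and gaps are strictly in-plane.  One 3D
component is one event regardless of its z extent: formations are
counted, not slices.  Events touching the first or last section are
counted and flagged ``at_boundary``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import LabelVolume, RoleMap, role_mask
from .phantom import DETACH_TARGETS, TUBULE_OPENINGS

logger = logging.getLogger("nvumorph")

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_CROSS_2D = ndimage.generate_binary_structure(2, 1)  # in-plane face adjacency


@dataclass(frozen=True)
class DetectorParams:
    """Inclusion/exclusion thresholds for all three detectors.

    Values are declared defaults of this package (exposed in config),
    in physical units where applicable: 12 nm equals two in-plane
    voxels at the default 6 nm pixel pitch.
    """

    min_voxels: int = 20
    min_z_slices: int = 2
    min_gap_width_nm: float = 12.0
    lucent_gap_threshold_nm: float = 12.0
    max_gap_search_nm: float = 60.0
    closing_radius_px: int = 5

    def __post_init__(self):
        if self.min_voxels < 1 or self.min_z_slices < 1:
            raise ValueError("min_voxels and min_z_slices must be >= 1")
        if min(self.min_gap_width_nm, self.lucent_gap_threshold_nm, self.max_gap_search_nm) <= 0:
            raise ValueError("gap thresholds must be > 0")
        if self.closing_radius_px < 1:
            raise ValueError("closing_radius_px must be >= 1")


@dataclass(frozen=True)
class FeatureEvent:
    """One detected ultrastructural feature."""

    feature_type: str  # peg_socket | detachment | tubule
    z_start: int
    z_end: int
    voxel_count: int
    centroid: tuple[float, float, float]
    target_role: str | None = None  # detachment only
    attachment_state: str | None = None  # peg_socket only
    opening_class: str | None = None  # tubule only
    max_gap_nm: float = 0.0
    at_boundary: bool = False

    def __post_init__(self):
        if self.z_start > self.z_end:
            raise ValueError("z_start must be <= z_end")


@dataclass(frozen=True)
class CapillaryMetrics:
    """Counts and per-10-µm frequencies for one capillary stack."""

    depth_um: float
    counts: dict[str, int] = field(default_factory=dict)
    frequency_per_10um: dict[str, float] = field(default_factory=dict)
    events: tuple[FeatureEvent, ...] = ()


def frequency_per_10um(count: int, n_slices: int, dz_nm: float) -> float:
    """Normalise a feature count to events per 10 µm capillary depth."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if dz_nm <= 0:
        raise ValueError("dz_nm must be > 0")
    return count * 10_000.0 / (n_slices * dz_nm)


def _disc2d(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius**2


def _bbox3d(mask: np.ndarray):
    zz = np.flatnonzero(mask.any(axis=(1, 2)))
    yy = np.flatnonzero(mask.any(axis=(0, 2)))
    xx = np.flatnonzero(mask.any(axis=(0, 1)))
    return (
        slice(zz[0], zz[-1] + 1),
        slice(yy[0], yy[-1] + 1),
        slice(xx[0], xx[-1] + 1),
    )


def _components(mask: np.ndarray):
    """26-connected 3D labelling, restricted to the mask's bounding box."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32), 0
    bb = _bbox3d(mask)
    lab = np.zeros(mask.shape, dtype=np.int32)
    lab[bb], n = ndimage.label(mask[bb], structure=_STRUCT_26)
    return lab, n


def _in_plane_px(volume: LabelVolume) -> float:
    return volume.in_plane_nm


def endothelial_envelope(
    volume: LabelVolume,
    role_map: RoleMap,
    closing_radius_px: int = 5,
    _masks: dict | None = None,
) -> np.ndarray:
    """Per-slice hole-filled closing of the capillary wall
    (endothelium ∪ lumen ∪ BM): the region enclosed by the endothelium,
    including socket interiors."""
    def _mask(role):
        if _masks is not None:
            return _masks[role]
        return role_mask(volume, role_map, role)

    wall = _mask("endothelium") | _mask("lumen") | _mask("basement_membrane")
    r = closing_radius_px
    env = np.zeros_like(wall)
    for z in range(wall.shape[0]):
        # closing with a Euclidean disc via two distance transforms:
        # dilation = {dist to wall <= r}, then erosion = {dist to the
        # dilation's complement > r}
        dil = ndimage.distance_transform_edt(~wall[z]) <= r
        closed = ndimage.distance_transform_edt(dil) > r
        env[z] = ndimage.binary_fill_holes(closed)
    return env


def _event_extent_ok(zs: np.ndarray, count: int, params: DetectorParams) -> bool:
    return count >= params.min_voxels and (zs.max() - zs.min() + 1) >= params.min_z_slices


def _make_event(feature_type: str, coords, n_slices: int, **kw) -> FeatureEvent:
    zs, ys, xs = coords
    return FeatureEvent(
        feature_type=feature_type,
        z_start=int(zs.min()),
        z_end=int(zs.max()),
        voxel_count=int(zs.size),
        centroid=(float(zs.mean()), float(ys.mean()), float(xs.mean())),
        at_boundary=bool(zs.min() == 0 or zs.max() == n_slices - 1),
        **kw,
    )


# ---------------------------------------------------------------------------
# Peg-and-socket formations
# ---------------------------------------------------------------------------

def detect_peg_sockets(
    volume: LabelVolume,
    role_map: RoleMap,
    params: DetectorParams = DetectorParams(),
    return_claimed: bool = False,
    _masks: dict | None = None,
):
    """Detect pericyte pegs inserted into endothelial sockets.

    Returns the list of events; with ``return_claimed=True`` also
    returns the boolean mask of lucent socket voxels belonging to
    detected pegs (for exclusion from detachment counting).
    """
    for role in ("pericyte", "endothelium"):
        if not role_map.labels_for(role):
            raise ValueError(f"role map lacks required role {role!r}")

    def _mask(role):
        if _masks is not None:
            return _masks[role]
        return role_mask(volume, role_map, role)

    peri = _mask("pericyte")
    claimed = np.zeros(volume.voxels.shape, dtype=bool)
    if not peri.any():
        logger.warning("pericyte role maps to no voxels; no peg-and-socket analysis")
        return ([], claimed) if return_claimed else []

    env = endothelial_envelope(volume, role_map, params.closing_radius_px, _masks=_masks)
    bg = _mask("background")
    px_nm = _in_plane_px(volume)

    candidates = peri & env
    cand_lab, n_cand = _components(candidates)

    events: list[FeatureEvent] = []
    for obj_idx, sl in enumerate(ndimage.find_objects(cand_lab), start=1):
        if sl is None:
            continue
        comp = cand_lab[sl] == obj_idx
        zs, ys, xs = np.nonzero(comp)
        if not _event_extent_ok(zs + sl[0].start, int(comp.sum()), params):
            continue
        # must cross the BM: connected, through the envelope boundary, to
        # pericyte material outside it (the pericyte body).  comp is a
        # maximal component of peri & env, so it crosses iff some voxel is
        # 26-adjacent to a pericyte voxel outside the envelope.
        grow = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                     for s, dim in zip(sl, volume.voxels.shape))
        comp_g = np.zeros(tuple(s.stop - s.start for s in grow), dtype=bool)
        off = tuple(s.start - g.start for s, g in zip(sl, grow))
        comp_g[off[0]:off[0] + comp.shape[0],
               off[1]:off[1] + comp.shape[1],
               off[2]:off[2] + comp.shape[2]] = comp
        halo = ndimage.binary_dilation(comp_g, structure=_STRUCT_26)
        if not np.any(halo & peri[grow] & ~env[grow]):
            continue

        # lucent shell inside the socket, in-plane-adjacent to the peg
        gap_nm, shell = _socket_gap(
            comp, sl, bg & env & ~claimed, px_nm, params.max_gap_search_nm
        )
        state = (
            "partially_detached" if gap_nm >= params.lucent_gap_threshold_nm else "attached"
        )
        claimed |= shell
        events.append(
            _make_event(
                "peg_socket",
                (zs + sl[0].start, ys + sl[1].start, xs + sl[2].start),
                volume.n_slices,
                attachment_state=state,
                max_gap_nm=float(gap_nm),
            )
        )
    events.sort(key=lambda e: (e.z_start, e.centroid))
    return (events, claimed) if return_claimed else events


def _socket_gap(comp, sl, lucent, px_nm, search_nm):
    """Width (nm) of the lucent shell around a peg component and the full
    mask of its shell voxels.  Width is the maximum in-plane distance of
    shell voxels from the peg surface."""
    pad = int(math.ceil(search_nm / px_nm)) + 1
    zsl, ysl, xsl = sl
    shape = lucent.shape
    ysl = slice(max(ysl.start - pad, 0), min(ysl.stop + pad, shape[1]))
    xsl = slice(max(xsl.start - pad, 0), min(xsl.stop + pad, shape[2]))
    win = (zsl, ysl, xsl)
    comp_w = np.zeros((zsl.stop - zsl.start, ysl.stop - ysl.start, xsl.stop - xsl.start), bool)
    oy = sl[1].start - ysl.start
    ox = sl[2].start - xsl.start
    comp_w[:, oy : oy + comp.shape[1], ox : ox + comp.shape[2]] = comp
    luc_w = lucent[win]

    shell = np.zeros(shape, dtype=bool)
    max_gap_px = 0.0
    # connected lucent region touching the peg, grown slice-wise
    touch = np.zeros_like(luc_w)
    for k in range(comp_w.shape[0]):
        if not comp_w[k].any() or not luc_w[k].any():
            continue
        dist = ndimage.distance_transform_edt(~comp_w[k])
        luc_lab, n = ndimage.label(luc_w[k], structure=_CROSS_2D)
        for li in range(1, n + 1):
            m = luc_lab == li
            if dist[m].min() <= 1.0:  # face-adjacent to the peg
                reach = dist[m].max()
                if reach <= search_nm / px_nm + 1:
                    touch[k] |= m
                    max_gap_px = max(max_gap_px, float(reach))
    shell[win] = touch
    return max_gap_px * px_nm, shell


# ---------------------------------------------------------------------------
# Cell–BM detachments
# ---------------------------------------------------------------------------

def detect_detachments(
    volume: LabelVolume,
    role_map: RoleMap,
    target_role: str,
    params: DetectorParams = DetectorParams(),
    exclude_mask: np.ndarray | None = None,
    _d_bm: np.ndarray | None = None,
    _masks: dict | None = None,
) -> list[FeatureEvent]:
    """Detect electron-lucent gaps between ``target_role`` and the BM.

    ``_d_bm`` optionally supplies the precomputed per-slice in-plane
    distance map to the BM (shared across target roles by
    :func:`summarize_capillary`).
    """
    if target_role not in DETACH_TARGETS:
        raise ValueError(f"target_role must be one of {DETACH_TARGETS}")
    for role in (target_role, "basement_membrane"):
        if not role_map.labels_for(role):
            raise ValueError(f"role map lacks required role {role!r}")
    def _mask(role):
        if _masks is not None:
            return _masks[role]
        return role_mask(volume, role_map, role)

    target = _mask(target_role)
    bm = _mask("basement_membrane")
    if not target.any():
        logger.warning("%s role maps to no voxels; no detachment analysis", target_role)
        return []
    bg = _mask("background")
    if exclude_mask is not None:
        bg = bg & ~exclude_mask
    px_nm = _in_plane_px(volume)
    search_px = math.ceil(params.max_gap_search_nm / px_nm)

    # per-slice distances to BM and to the target (in-plane, pixels)
    if _d_bm is not None:
        d_bm = _d_bm
    else:
        d_bm = np.empty(bg.shape, dtype=np.float32)
        for z in range(bg.shape[0]):
            d_bm[z] = ndimage.distance_transform_edt(~bm[z])
    near_bm = bg & (d_bm <= search_px)
    # target distance is only needed on slices with lucent near-BM voxels
    d_tg = np.zeros(bg.shape, dtype=np.float32)
    candidates = np.zeros_like(near_bm)
    for z in np.flatnonzero(near_bm.any(axis=(1, 2))):
        d_tg[z] = ndimage.distance_transform_edt(~target[z])
        candidates[z] = near_bm[z] & (d_tg[z] <= search_px)
    lab, n = _components(candidates)
    events: list[FeatureEvent] = []
    for idx, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None:
            continue
        comp = lab[sl] == idx
        db = d_bm[sl][comp]
        dt = d_tg[sl][comp]
        # the component must actually touch both surfaces (face adjacency)
        if db.min() > 1.0 or dt.min() > 1.0:
            continue
        # in-plane gap width: a lucent corridor of width g between the two
        # surfaces satisfies max(d_bm + d_target - 1) = g over its pixels
        width_px = float((db + dt).max() - 1.0)
        if width_px * px_nm < params.min_gap_width_nm:
            continue
        zs, ys, xs = np.nonzero(comp)
        if not _event_extent_ok(zs + sl[0].start, int(comp.sum()), params):
            continue
        events.append(
            _make_event(
                "detachment",
                (zs + sl[0].start, ys + sl[1].start, xs + sl[2].start),
                volume.n_slices,
                target_role=target_role,
                max_gap_nm=width_px * px_nm,
            )
        )
    events.sort(key=lambda e: (e.z_start, e.centroid))
    return events


# ---------------------------------------------------------------------------
# Endothelial tubules
# ---------------------------------------------------------------------------

def detect_tubules(
    volume: LabelVolume,
    role_map: RoleMap,
    params: DetectorParams = DetectorParams(),
    _masks: dict | None = None,
) -> list[FeatureEvent]:
    """Detect intracytoplasmic tubules and classify their openings.

    A component is luminal if any voxel is in-plane face-adjacent to the
    lumen, abluminal if adjacent to the BM, transendothelial iff both,
    closed if neither.
    """
    for role in ("tubule", "endothelium", "lumen"):
        if not role_map.labels_for(role):
            raise ValueError(f"role map lacks required role {role!r}")

    def _mask(role):
        if _masks is not None:
            return _masks[role]
        return role_mask(volume, role_map, role)

    tub = _mask("tubule")
    if not tub.any():
        return []
    lum = _mask("lumen")
    bm = _mask("basement_membrane")

    # in-plane one-step dilations of the surfaces, on tubule-bearing slices
    lum_adj = np.zeros_like(lum)
    bm_adj = np.zeros_like(bm)
    for z in np.flatnonzero(tub.any(axis=(1, 2))):
        lum_adj[z] = ndimage.binary_dilation(lum[z], structure=_CROSS_2D)
        bm_adj[z] = ndimage.binary_dilation(bm[z], structure=_CROSS_2D)

    lab, n = _components(tub)
    events: list[FeatureEvent] = []
    for idx, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None:
            continue
        comp = lab[sl] == idx
        if int(comp.sum()) < params.min_voxels:
            continue
        zs, ys, xs = np.nonzero(comp)
        touches_lum = bool((comp & lum_adj[sl]).any())
        touches_bm = bool((comp & bm_adj[sl]).any())
        if touches_lum and touches_bm:
            cls = "transendothelial"
        elif touches_lum:
            cls = "luminal"
        elif touches_bm:
            cls = "abluminal"
        else:
            cls = "closed"
        events.append(
            _make_event(
                "tubule",
                (zs + sl[0].start, ys + sl[1].start, xs + sl[2].start),
                volume.n_slices,
                opening_class=cls,
            )
        )
    events.sort(key=lambda e: (e.z_start, e.centroid))
    return events


# ---------------------------------------------------------------------------
# Per-capillary summary
# ---------------------------------------------------------------------------

def summarize_capillary(
    volume: LabelVolume,
    role_map: RoleMap,
    params: DetectorParams = DetectorParams(),
) -> CapillaryMetrics:
    """Run all detectors and normalise counts per 10 µm capillary depth.

    The transendothelial tubule count is always reported explicitly,
    even when zero, so the absence of complete transendothelial channels
    is a single field of the result.
    """
    from .phantom import PEG_STATES  # canonical key order

    masks = {
        role: role_mask(volume, role_map, role)
        for role in ("background", "lumen", "endothelium", "pericyte",
                     "basement_membrane", "macroglia", "tubule")
    }
    peg_events, claimed = detect_peg_sockets(
        volume, role_map, params, return_claimed=True, _masks=masks
    )
    events: list[FeatureEvent] = list(peg_events)
    detach_roles = [r for r in DETACH_TARGETS if role_map.labels_for(r)]
    if detach_roles:
        bm = masks["basement_membrane"]
        d_bm = np.empty(bm.shape, dtype=np.float32)
        for z in range(bm.shape[0]):
            d_bm[z] = ndimage.distance_transform_edt(~bm[z])
        for role in detach_roles:
            events.extend(
                detect_detachments(
                    volume, role_map, role, params,
                    exclude_mask=claimed, _d_bm=d_bm, _masks=masks,
                )
            )
    if role_map.labels_for("tubule"):
        events.extend(detect_tubules(volume, role_map, params, _masks=masks))

    counts: dict[str, int] = {"peg_socket": 0, "detachment": 0, "tubule": 0}
    for s in PEG_STATES:
        counts[f"peg_socket_{s}"] = 0
    for r in DETACH_TARGETS:
        counts[f"detachment_{r}"] = 0
    for c in TUBULE_OPENINGS:
        counts[f"tubule_{c}"] = 0
    for e in events:
        counts[e.feature_type] += 1
        if e.feature_type == "peg_socket":
            counts[f"peg_socket_{e.attachment_state}"] += 1
        elif e.feature_type == "detachment":
            counts[f"detachment_{e.target_role}"] += 1
        else:
            counts[f"tubule_{e.opening_class}"] += 1

    freq = {
        k: frequency_per_10um(v, volume.n_slices, volume.dz_nm) for k, v in counts.items()
    }
    return CapillaryMetrics(
        depth_um=volume.depth_um,
        counts=counts,
        frequency_per_10um=freq,
        events=tuple(events),
    )
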