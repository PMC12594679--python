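"""Synthetic capillary phantoms with analytic ground truth.

A phantom emulates a segmented SBF-SEM stack of a retinal capillary
cross-section running along z: a lumen disc wrapped by an endothelial
annulus, a basement-membrane (BM) shell of controllable, optionally
sinusoidally modulated thickness, a pericyte arc and a macroglial sheath
outside the BM.  Ultrastructural features are planted with known
position, extent and class:

* **peg-and-socket formations** — pericyte protrusions crossing the BM
  into an endothelial invagination, either attached (membranes in
  contact) or partially detached (an electron-lucent shell of known
  width around the peg tip inside the socket);
* **cell–BM detachments** — electron-lucent gaps of known width between
  the BM and the endothelium, pericyte or macroglia;
* **endothelial tubules** — tubule-labelled tubes inside the endothelium
  that touch neither surface (closed), the luminal surface, the
  abluminal/BM surface, or both (transendothelial).

Geometry is defined in physical nanometres and sampled on the
anisotropic voxel grid by centre-sampling: a voxel belongs to a region
iff its centre lies in the analytic region.  All randomness is driven by
explicit seeds; regenerating with the same spec is bit-identical.

The radial BM thickness field is::

    w(theta, z) = base + amplitude * sin(lobes * theta
                                         + 2*pi*z / z_period_slices
                                         + phase)

and :func:`analytic_thickness_summary` evaluates its mean and maximum by
quadrature, independently of any rasterisation — this is the oracle the
thickness measurement is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import LabelVolume, RoleMap

# Canonical label assignment used by all phantoms.
PHANTOM_LABELS = {
    "background": 0,
    "lumen": 1,
    "endothelium": 2,
    "basement_membrane": 3,
    "pericyte": 4,
    "macroglia": 5,
    "tubule": 6,
}

PEG_STATES = ("attached", "partially_detached")
DETACH_TARGETS = ("endothelium", "pericyte", "macroglia")
TUBULE_OPENINGS = ("closed", "luminal", "abluminal", "transendothelial")


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is inconsistent."""


def _wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def _ang_dist(a, b):
    return np.abs(_wrap_angle(np.asarray(a) - b))


@dataclass(frozen=True)
class PegSpec:
    """A planted peg-and-socket formation at angle ``theta``."""

    z_center: int
    theta: float
    z_extent_slices: int = 5
    radius_nm: float = 24.0
    state: str = "attached"
    gap_nm: float = 30.0  # lucent-shell width when partially detached
    depth_nm: float = 150.0  # penetration of the tip into the endothelium

    def __post_init__(self):
        if self.state not in PEG_STATES:
            raise PhantomSpecError(f"peg state must be one of {PEG_STATES}, got {self.state!r}")
        if self.radius_nm <= 0 or self.z_extent_slices < 1 or self.depth_nm <= 0:
            raise PhantomSpecError("peg radius, depth and z extent must be positive")
        if self.state == "partially_detached" and self.gap_nm <= 0:
            raise PhantomSpecError("partially detached peg needs gap_nm > 0")


@dataclass(frozen=True)
class DetachmentSpec:
    """A planted electron-lucent gap between a cell and the BM."""

    target_role: str
    z_center: int
    theta: float
    z_extent_slices: int = 6
    arc_rad: float = 0.7
    gap_nm: float = 24.0

    def __post_init__(self):
        if self.target_role not in DETACH_TARGETS:
            raise PhantomSpecError(
                f"detachment target must be one of {DETACH_TARGETS}, got {self.target_role!r}"
            )
        if self.gap_nm <= 0 or self.arc_rad <= 0 or self.z_extent_slices < 1:
            raise PhantomSpecError("detachment gap, arc and z extent must be positive")


@dataclass(frozen=True)
class TubuleSpec:
    """A planted intracytoplasmic endothelial tubule."""

    z_center: int
    theta: float
    z_extent_slices: int = 4
    radius_nm: float = 42.0
    opening: str = "closed"

    def __post_init__(self):
        if self.opening not in TUBULE_OPENINGS:
            raise PhantomSpecError(
                f"tubule opening must be one of {TUBULE_OPENINGS}, got {self.opening!r}"
            )
        if self.radius_nm <= 0 or self.z_extent_slices < 1:
            raise PhantomSpecError("tubule radius and z extent must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic capillary stack.

    Defaults emulate typical acquisition conditions: 6 nm in-plane pixels, 100 nm
    serial sections, stacks of 130–300 sections (default 130), with a
    capillary sized to fit a 512x512 field of view.
    """

    n_slices: int = 130
    shape_yx: tuple[int, int] = (512, 512)
    voxel_size_nm: tuple[float, float, float] = (100.0, 6.0, 6.0)
    lumen_radius_nm: float | Sequence[float] = 550.0
    endothelium_thickness_nm: float = 280.0
    bm_base_nm: float = 102.0
    bm_amplitude_nm: float = 0.0
    bm_theta_lobes: int = 3
    bm_z_period_slices: float | None = None  # default: one period per stack
    bm_phase: float = 0.0
    pericyte_arc_center: float = 0.0
    pericyte_arc_extent: float = math.pi
    pericyte_thickness_nm: float = 180.0
    macroglia_present: bool = True
    macroglia_thickness_nm: float = 180.0
    pegs: tuple[PegSpec, ...] = ()
    detachments: tuple[DetachmentSpec, ...] = ()
    tubules: tuple[TubuleSpec, ...] = ()
    boundary_jitter_nm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pegs", tuple(self.pegs))
        object.__setattr__(self, "detachments", tuple(self.detachments))
        object.__setattr__(self, "tubules", tuple(self.tubules))
        self.validate()

    # -- derived geometry -------------------------------------------------
    @property
    def dz_nm(self) -> float:
        return float(self.voxel_size_nm[0])

    @property
    def dx_nm(self) -> float:
        return float(self.voxel_size_nm[2])

    @property
    def depth_um(self) -> float:
        return self.n_slices * self.dz_nm / 1000.0

    @property
    def z_period(self) -> float:
        return float(self.bm_z_period_slices) if self.bm_z_period_slices else float(self.n_slices)

    def lumen_radius_at(self, z: int) -> float:
        r = self.lumen_radius_nm
        if np.isscalar(r):
            return float(r)
        return float(r[z])

    def _max_lumen_radius(self) -> float:
        r = self.lumen_radius_nm
        return float(r) if np.isscalar(r) else float(max(r))

    def bm_width_nm(self, theta, z):
        """The analytic radial BM thickness field w(theta, z) in nm."""
        return self.bm_base_nm + self.bm_amplitude_nm * np.sin(
            self.bm_theta_lobes * np.asarray(theta)
            + 2 * np.pi * np.asarray(z) / self.z_period
            + self.bm_phase
        )

    def _mid_radius_nm(self) -> float:
        return self._max_lumen_radius() + self.endothelium_thickness_nm + self.bm_base_nm / 2

    # -- validation -------------------------------------------------------
    def _footprints(self):
        """(z0, z1, theta_center, angular half width, tag) per feature."""
        rmid = self._mid_radius_nm()
        margin_nm = 5 * self.dx_nm
        out = []
        for p in self.pegs:
            half = (p.radius_nm + (p.gap_nm if p.state == "partially_detached" else 0) + margin_nm) / rmid
            out.append((*_z_range(p.z_center, p.z_extent_slices), p.theta, half, f"peg@{p.theta:.2f}"))
        for d in self.detachments:
            half = d.arc_rad / 2 + margin_nm / rmid
            out.append((*_z_range(d.z_center, d.z_extent_slices), d.theta, half, f"detach@{d.theta:.2f}"))
        for t in self.tubules:
            half = (t.radius_nm + margin_nm) / rmid
            out.append((*_z_range(t.z_center, t.z_extent_slices), t.theta, half, f"tubule@{t.theta:.2f}"))
        return out

    def validate(self) -> None:
        dz, dy, dx = self.voxel_size_nm
        if dz <= 0 or dy <= 0 or dx <= 0:
            raise PhantomSpecError("voxel sizes must be positive")
        if not 1 <= self.n_slices <= 10_000:
            raise PhantomSpecError(f"n_slices must be in [1, 10000], got {self.n_slices}")
        if self.bm_base_nm - abs(self.bm_amplitude_nm) < 2 * dx:
            raise PhantomSpecError(
                "BM shell may vanish: base - amplitude must be >= 2 in-plane voxels "
                f"({2 * dx:g} nm)"
            )
        if self.endothelium_thickness_nm <= 0 or self.pericyte_thickness_nm <= 0:
            raise PhantomSpecError("layer thicknesses must be positive")
        if not 0 < self.pericyte_arc_extent <= 2 * math.pi:
            raise PhantomSpecError("pericyte arc extent must be in (0, 2*pi]")
        r = self.lumen_radius_nm
        if not np.isscalar(r) and len(r) != self.n_slices:
            raise PhantomSpecError("per-slice lumen radius profile must have n_slices entries")

        # Outer extent must fit inside the field of view.
        outer = (
            self._max_lumen_radius()
            + self.endothelium_thickness_nm
            + self.bm_base_nm
            + abs(self.bm_amplitude_nm)
            + self.pericyte_thickness_nm
            + (self.macroglia_thickness_nm if self.macroglia_present else 0)
            + abs(self.boundary_jitter_nm)
        )
        half_fov = min(self.shape_yx) / 2 * dx
        if outer + 3 * dx > half_fov:
            raise PhantomSpecError(
                f"capillary (outer radius {outer:.0f} nm) does not fit the field of view "
                f"(half extent {half_fov:.0f} nm)"
            )

        for p in self.pegs:
            if _ang_dist(p.theta, self.pericyte_arc_center) > self.pericyte_arc_extent / 2 - 0.05:
                raise PhantomSpecError(f"peg at theta={p.theta:.2f} lies outside the pericyte arc")
        for d in self.detachments:
            # the whole carved arc must sit on one side of the pericyte arc
            # boundary, else a single gap would touch two cell roles
            dist = float(_ang_dist(d.theta, self.pericyte_arc_center))
            if d.target_role == "pericyte" and dist + d.arc_rad / 2 > self.pericyte_arc_extent / 2:
                raise PhantomSpecError("pericyte detachment arc must lie fully within the pericyte arc")
            if d.target_role == "macroglia":
                if not self.macroglia_present:
                    raise PhantomSpecError("macroglia detachment requires macroglia_present")
                if dist - d.arc_rad / 2 < self.pericyte_arc_extent / 2:
                    raise PhantomSpecError(
                        "macroglia detachment arc must lie fully outside the pericyte arc "
                        "(macroglia touches the BM only there)"
                    )
        for t in self.tubules:
            if 2 * t.radius_nm + 6 * dx > self.endothelium_thickness_nm:
                raise PhantomSpecError("tubule diameter exceeds the endothelial thickness")

        fps = self._footprints()
        for z0, z1, *_ in fps:
            if z0 < 0 or z1 >= self.n_slices:
                raise PhantomSpecError(f"feature z range [{z0}, {z1}] exceeds the stack")
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                z0a, z1a, ca, ha, taga = fps[i]
                z0b, z1b, cb, hb, tagb = fps[j]
                if z0a <= z1b and z0b <= z1a and _ang_dist(ca, cb) < ha + hb:
                    raise PhantomSpecError(
                        f"planted features overlap in (z, arc): {taga} vs {tagb}"
                    )


def _z_range(z_center: int, z_extent: int) -> tuple[int, int]:
    z0 = z_center - (z_extent - 1) // 2
    return z0, z0 + z_extent - 1


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Analytic summary of a phantom: the acceptance oracle.

    ``counts`` and ``expected_frequency_per_10um`` are flat dictionaries
    keyed like ``peg_socket_attached``, ``detachment_endothelium``,
    ``tubule_closed`` … plus per-family totals ``peg_socket``,
    ``detachment``, ``tubule``.
    """

    analytic_mean_thickness_nm: float
    analytic_max_thickness_nm: float
    depth_um: float
    counts: dict[str, int] = field(default_factory=dict)
    expected_frequency_per_10um: dict[str, float] = field(default_factory=dict)
    tubule_opening_classes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.analytic_max_thickness_nm >= self.analytic_mean_thickness_nm > 0:
            raise ValueError("analytic max must be >= mean > 0")


def _count_keys() -> list[str]:
    keys = ["peg_socket"] + [f"peg_socket_{s}" for s in PEG_STATES]
    keys += ["detachment"] + [f"detachment_{r}" for r in DETACH_TARGETS]
    keys += ["tubule"] + [f"tubule_{c}" for c in TUBULE_OPENINGS]
    return keys


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    mean_nm, max_nm = analytic_thickness_summary(spec)
    counts = {k: 0 for k in _count_keys()}
    for p in spec.pegs:
        counts["peg_socket"] += 1
        counts[f"peg_socket_{p.state}"] += 1
    for d in spec.detachments:
        counts["detachment"] += 1
        counts[f"detachment_{d.target_role}"] += 1
    for t in spec.tubules:
        counts["tubule"] += 1
        counts[f"tubule_{t.opening}"] += 1
    depth = spec.depth_um
    freq = {k: v * 10.0 / depth for k, v in counts.items()}
    return GroundTruth(
        analytic_mean_thickness_nm=mean_nm,
        analytic_max_thickness_nm=max_nm,
        depth_um=depth,
        counts=counts,
        expected_frequency_per_10um=freq,
        tubule_opening_classes=tuple(t.opening for t in spec.tubules),
    )


def analytic_thickness_summary(spec: PhantomSpec, n_theta: int = 2048) -> tuple[float, float]:
    """Mean and maximum of the analytic BM thickness field, by quadrature.

    Integrates ``w(theta, z)`` over theta in [0, 2*pi) and the stack's
    slice indices, independently of any rasterisation.  For an
    integer-lobed sinusoid the mean equals the base thickness and the
    maximum approaches base + |amplitude| as the grid refines.
    """
    if spec.bm_amplitude_nm == 0:  # constant field: closed form
        return float(spec.bm_base_nm), float(spec.bm_base_nm)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.arange(spec.n_slices)
    w = spec.bm_width_nm(theta[None, :], z[:, None])
    wmax = float(w.max())
    # pairwise-summation rounding can push the mean of a constant field
    # a few ulp above its maximum
    return min(float(w.mean()), wmax), wmax


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def _segment_distance(py, px, ay, ax, by, bx):
    """Euclidean distance from points (py, px) to segment (a, b), in nm."""
    dy, dx = by - ay, bx - ax
    L2 = dy * dy + dx * dx
    if L2 == 0:
        return np.hypot(py - ay, px - ax)
    t = np.clip(((py - ay) * dy + (px - ax) * dx) / L2, 0.0, 1.0)
    return np.hypot(py - (ay + t * dy), px - (ax + t * dx))


def _jitter_profile(spec: PhantomSpec, rng: np.random.Generator):
    """Smooth per-slice angular boundary perturbations (default off)."""
    if spec.boundary_jitter_nm <= 0:
        return None
    harmonics = rng.integers(2, 6, size=(spec.n_slices, 3))
    phases = rng.uniform(0, 2 * np.pi, size=(spec.n_slices, 3))
    amps = rng.uniform(0.3, 1.0, size=(spec.n_slices, 3))
    amps *= spec.boundary_jitter_nm / amps.sum(axis=1, keepdims=True)
    return harmonics, phases, amps


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, RoleMap, GroundTruth]:
    """Rasterise a phantom onto the anisotropic grid.

    Returns the label volume, the role map of :data:`PHANTOM_LABELS` and
    the analytic :class:`GroundTruth`.  Deterministic given
    ``spec.rng_seed``.
    """
    spec.validate()
    H, W = spec.shape_yx
    dx = spec.dx_nm
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    py_nm = (yy - cy) * dx
    px_nm = (xx - cx) * dx
    r_nm = np.hypot(py_nm, px_nm)
    theta = np.arctan2(py_nm, px_nm)

    rng = np.random.default_rng(spec.rng_seed)
    jitter = _jitter_profile(spec, rng)

    L = PHANTOM_LABELS
    vol = np.zeros((spec.n_slices, H, W), dtype=np.uint8)
    peri_in_arc = _ang_dist(theta, spec.pericyte_arc_center) <= spec.pericyte_arc_extent / 2

    for z in range(spec.n_slices):
        r = r_nm
        if jitter is not None:
            harm, ph, amp = jitter
            delta = sum(
                amp[z, k] * np.sin(harm[z, k] * theta + ph[z, k]) for k in range(3)
            )
            r = r_nm + delta

        lab = vol[z]
        R_lum = spec.lumen_radius_at(z)
        R_eo = R_lum + spec.endothelium_thickness_nm
        w = spec.bm_width_nm(theta, z)
        R_bo = R_eo + w

        lab[r < R_lum] = L["lumen"]
        lab[(r >= R_lum) & (r < R_eo)] = L["endothelium"]
        lab[(r >= R_eo) & (r < R_bo)] = L["basement_membrane"]
        peri = peri_in_arc & (r >= R_bo) & (r < R_bo + spec.pericyte_thickness_nm)
        lab[peri] = L["pericyte"]
        if spec.macroglia_present:
            outer = R_bo + np.where(peri_in_arc, spec.pericyte_thickness_nm, 0.0)
            lab[(r >= outer) & (r < outer + spec.macroglia_thickness_nm)] = L["macroglia"]

        # --- planted features ---------------------------------------------
        for p in spec.pegs:
            z0, z1 = _z_range(p.z_center, p.z_extent_slices)
            if not z0 <= z <= z1:
                continue
            w_p = float(spec.bm_width_nm(p.theta, z))
            r0 = R_eo - p.depth_nm
            r1 = R_eo + w_p + spec.pericyte_thickness_nm / 2
            ay, ax = r0 * math.sin(p.theta), r0 * math.cos(p.theta)
            by, bx = r1 * math.sin(p.theta), r1 * math.cos(p.theta)
            dist = _segment_distance(py_nm, px_nm, ay, ax, by, bx)
            shaft = dist <= p.radius_nm
            lab[shaft & np.isin(lab, (L["endothelium"], L["basement_membrane"], L["pericyte"]))] = L["pericyte"]
            if p.state == "partially_detached":
                shell = (dist > p.radius_nm) & (dist <= p.radius_nm + p.gap_nm)
                lab[shell & (lab == L["endothelium"])] = L["background"]

        for d in spec.detachments:
            z0, z1 = _z_range(d.z_center, d.z_extent_slices)
            if not z0 <= z <= z1:
                continue
            in_arc = _ang_dist(theta, d.theta) <= d.arc_rad / 2
            if d.target_role == "endothelium":
                gap = in_arc & (r >= R_eo - d.gap_nm) & (r < R_eo)
            else:  # pericyte or macroglia sit directly on the BM outer face
                gap = in_arc & (r >= R_bo) & (r < R_bo + d.gap_nm)
            lab[gap] = L["background"]

        for t in spec.tubules:
            z0, z1 = _z_range(t.z_center, t.z_extent_slices)
            if not z0 <= z <= z1:
                continue
            if t.opening == "transendothelial":
                ay, ax = R_lum * math.sin(t.theta), R_lum * math.cos(t.theta)
                by, bx = R_eo * math.sin(t.theta), R_eo * math.cos(t.theta)
                dist = _segment_distance(py_nm, px_nm, ay, ax, by, bx)
                lab[(dist <= t.radius_nm) & (lab == L["endothelium"])] = L["tubule"]
            else:
                if t.opening == "luminal":
                    rc = R_lum + t.radius_nm - 2 * dx
                elif t.opening == "abluminal":
                    rc = R_eo - t.radius_nm + 2 * dx
                else:
                    rc = (R_lum + R_eo) / 2
                ty, tx = rc * math.sin(t.theta), rc * math.cos(t.theta)
                dist = np.hypot(py_nm - ty, px_nm - tx)
                lab[(dist <= t.radius_nm) & (lab == L["endothelium"])] = L["tubule"]

    volume = LabelVolume(vol, spec.voxel_size_nm)
    role_map = RoleMap({v: k for k, v in L.items()})
    return volume, role_map, _ground_truth(spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectMultipliers:
    """Group-level multipliers applied to a template's planted features.

    ``pegs``, ``detachments`` and ``tubules`` scale the Poisson mean
    feature count; ``gap`` scales lucent-gap widths.
    """

    pegs: float = 1.0
    detachments: float = 1.0
    tubules: float = 1.0
    gap: float = 1.0

    def __post_init__(self):
        if min(self.pegs, self.detachments, self.tubules, self.gap) < 0:
            raise ValueError("effect multipliers must be non-negative")


@dataclass(frozen=True)
class CohortMember:
    """One simulated capillary: its spec, ground truth and (optionally)
    the rasterised volume."""

    spec: PhantomSpec
    ground_truth: GroundTruth
    volume: LabelVolume | None = None
    role_map: RoleMap | None = None


def _place_features(
    template: PhantomSpec,
    effect: EffectMultipliers,
    rng: np.random.Generator,
    rmid: float | None = None,
    z_margin: int = 4,
    max_attempts: int = 200,
):
    """Draw Poisson feature counts and non-overlapping (z, arc) positions.

    ``rmid`` is the mid-BM radius used to convert physical footprints to
    angles; the caller passes the value of the final (jittered) spec so
    placement and validation agree.
    """
    n_slices = template.n_slices
    if rmid is None:
        rmid = template._mid_radius_nm()
    margin_nm = 5 * template.dx_nm
    placed: list[tuple[int, int, float, float]] = []

    def fits(z0, z1, c, h, margin=z_margin):
        if z0 < margin or z1 > n_slices - 1 - margin:
            return False
        for (pz0, pz1, pc, ph) in placed:
            if z0 <= pz1 and pz0 <= z1 and float(_ang_dist(c, pc)) < h + ph:
                return False
        return True

    def draw_theta(kind, proto):
        ext2 = template.pericyte_arc_extent / 2
        if kind == "peg":
            half = ext2 - 0.15
            return float(_wrap_angle(template.pericyte_arc_center + rng.uniform(-half, half)))
        if kind == "detach" and proto.target_role == "pericyte":
            half = max(ext2 - proto.arc_rad / 2 - 0.05, 0.01)
            return float(_wrap_angle(template.pericyte_arc_center + rng.uniform(-half, half)))
        if kind == "detach" and proto.target_role == "macroglia":
            # fully outside the pericyte arc
            free = 2 * math.pi - template.pericyte_arc_extent
            lo = proto.arc_rad / 2 + 0.05
            hi = max(free - proto.arc_rad / 2 - 0.05, lo + 0.01)
            off = rng.uniform(lo, hi)
            return float(_wrap_angle(template.pericyte_arc_center + ext2 + off))
        return float(rng.uniform(-math.pi, math.pi))

    pegs, detachments, tubules = [], [], []
    plan = [
        ("peg", template.pegs, effect.pegs, pegs),
        ("detach", template.detachments, effect.detachments, detachments),
        ("tubule", template.tubules, effect.tubules, tubules),
    ]
    for kind, protos, mult, out in plan:
        mean = len(protos) * mult
        n = int(rng.poisson(mean)) if mean > 0 else 0
        for _ in range(n):
            proto = protos[int(rng.integers(len(protos)))]
            ze = proto.z_extent_slices
            # shrink the boundary margin on short stacks; drop the
            # feature if it cannot fit at all
            margin = min(z_margin, (n_slices - ze) // 2)
            if margin < 0:
                continue
            lo = margin + (ze - 1) // 2
            hi = n_slices - margin - ze // 2  # exclusive
            if hi <= lo:
                hi = lo + 1
            for _attempt in range(max_attempts):
                zc = int(rng.integers(lo, hi))
                th = draw_theta(kind, proto)
                z0, z1 = _z_range(zc, ze)
                if kind == "peg":
                    half = (proto.radius_nm + (proto.gap_nm if proto.state == "partially_detached" else 0) + margin_nm) / rmid
                elif kind == "detach":
                    half = proto.arc_rad / 2 + margin_nm / rmid
                else:
                    half = (proto.radius_nm + margin_nm) / rmid
                if fits(z0, z1, th, half, margin):
                    placed.append((z0, z1, th, half))
                    if kind == "peg":
                        out.append(replace(proto, z_center=zc, theta=th,
                                           gap_nm=proto.gap_nm * effect.gap))
                    elif kind == "detach":
                        out.append(replace(proto, z_center=zc, theta=th,
                                           gap_nm=proto.gap_nm * effect.gap))
                    else:
                        out.append(replace(proto, z_center=zc, theta=th))
                    break
            # placement failure simply drops the feature; ground truth
            # counts only what was actually planted
    return tuple(pegs), tuple(detachments), tuple(tubules)


def make_cohort(
    template: PhantomSpec,
    n_stacks: int,
    effect: EffectMultipliers | None = None,
    rng_seed: int = 0,
    bm_base_sd_nm: float = 6.0,
    rasterise: bool = True,
) -> list[CohortMember]:
    """Simulate a cohort of capillaries from a template.

    Per-stack feature counts are Poisson with mean = template count x
    multiplier; feature parameters are drawn from the template's planted
    features (preserving e.g. the attached/detached mix) at fresh
    non-overlapping positions.  The BM base thickness receives a small
    per-capillary Gaussian jitter (``bm_base_sd_nm``), identical in law
    across groups, emulating biological between-capillary variation.
    Seeds derive deterministically from ``rng_seed``.

    With ``rasterise=False`` only specs and ground truths are returned
    (used for large statistical simulations where the detector-vs-manifest
    identity has been established separately).
    """
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    effect = effect or EffectMultipliers()
    ss = np.random.SeedSequence(rng_seed)
    members: list[CohortMember] = []
    for child in ss.spawn(n_stacks):
        rng = np.random.default_rng(child)
        base = template.bm_base_nm + float(rng.normal(0, bm_base_sd_nm))
        base = max(base, abs(template.bm_amplitude_nm) + 2 * template.dx_nm + 1.0)
        rmid = template._max_lumen_radius() + template.endothelium_thickness_nm + base / 2
        pegs, detachments, tubules = _place_features(template, effect, rng, rmid=rmid)
        spec = replace(
            template,
            bm_base_nm=base,
            pegs=pegs,
            detachments=detachments,
            tubules=tubules,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        if rasterise:
            volume, role_map, gt = generate_phantom(spec)
            members.append(CohortMember(spec, gt, volume, role_map))
        else:
            members.append(CohortMember(spec, _ground_truth(spec)))
    return members


# ---------------------------------------------------------------------------
# Study conditions
# ---------------------------------------------------------------------------

def study_template(n_slices: int = 300, **overrides) -> PhantomSpec:
    """The control-condition capillary template used for cohort simulation.

    Feature densities follow healthy retinal capillaries as this package
    models them: at the default 300 sections (30 µm of capillary depth)
    the template carries 9 peg-and-socket prototypes (one partially
    detached), i.e. 3.0 per 10 µm; one detachment prototype per target
    role (whose Poisson mean is scaled far below one by the control
    group multiplier — detachment is rare in health); and 6 tubule
    prototypes (4 closed, 1 luminal, 1 abluminal, no transendothelial),
    i.e. 2.0 per 10 µm.  :func:`make_cohort` redraws counts and
    positions per capillary, so the template's own layout only needs to
    be valid, not representative.
    """
    margin = 8
    n_feat = 18
    zs = [int(margin + (k + 0.5) * (n_slices - 2 * margin) / n_feat) for k in range(n_feat)]
    peg_thetas = [-1.44 + 0.27 * k for k in range(9)]
    pegs = tuple(
        PegSpec(z_center=zs[k], theta=peg_thetas[k],
                state="partially_detached" if k == 8 else "attached")
        for k in range(9)
    )
    detachments = (
        DetachmentSpec("endothelium", z_center=zs[9], theta=-2.0, arc_rad=0.5),
        DetachmentSpec("pericyte", z_center=zs[10], theta=1.15, arc_rad=0.5),
        DetachmentSpec("macroglia", z_center=zs[11], theta=2.5, arc_rad=0.5),
    )
    tubule_layout = [
        (1.60, "closed"), (1.85, "closed"), (2.05, "closed"),
        (-2.45, "closed"), (-2.65, "luminal"), (-2.85, "abluminal"),
    ]
    tubules = tuple(
        TubuleSpec(z_center=zs[12 + k], theta=th, opening=op)
        for k, (th, op) in enumerate(tubule_layout)
    )
    return PhantomSpec(
        n_slices=n_slices, pegs=pegs, detachments=detachments, tubules=tubules, **overrides
    )


def plant_census(
    n_attached_pegs: int = 0,
    n_detached_pegs: int = 0,
    detachments: Mapping[str, int] | None = None,
    tubules: Mapping[str, int] | None = None,
    n_slices: int = 80,
    **overrides,
) -> PhantomSpec:
    """Build a phantom carrying an exact census of features.

    Features are laid out deterministically on a (z-band, angular-slot)
    grid so that arbitrary mixes — up to the grid capacity — satisfy the
    pairwise non-overlap constraint: two features may share a z band
    only at different angular slots, and angular slots are sized for the
    widest feature.  Pegs and pericyte detachments draw from slots
    inside the pericyte arc; macroglial detachments from slots outside
    it; endothelial detachments and tubules from any slot.

    ``detachments`` maps target role to count, ``tubules`` maps opening
    class to count.  Extra keyword arguments override
    :class:`PhantomSpec` fields (geometry, voxel sizes, seed).
    """
    detachments = dict(detachments or {})
    tubules = dict(tubules or {})
    probe = PhantomSpec(n_slices=n_slices, **overrides)
    ext2 = probe.pericyte_arc_extent / 2
    centre = probe.pericyte_arc_center
    arc_rad = 0.5  # detachment arc length used throughout

    # angular slots, 0.6 rad apart (> two detachment half-footprints)
    pitch = 0.6
    n_in = max(int((2 * ext2 - 0.4) // pitch), 1)
    in_slots = [centre - ext2 + 0.3 + k * pitch for k in range(n_in)]
    free = 2 * math.pi - 2 * ext2
    n_out = max(int((free - 0.8) // pitch), 1)
    out_slots = [
        float(_wrap_angle(centre + ext2 + 0.4 + k * pitch)) for k in range(n_out)
    ]

    band_h = 8  # taller than any default feature z extent
    margin = 3
    n_bands = (n_slices - 2 * margin) // band_h
    if n_bands < 1:
        raise PhantomSpecError(f"stack of {n_slices} slices too short for census placement")
    all_slots = [(th, True) for th in in_slots] + [(th, False) for th in out_slots]
    used: set[tuple[int, int]] = set()  # (band, slot index)

    def next_slot(inside: bool | None):
        for band in range(n_bands):
            for si, (th, is_in) in enumerate(all_slots):
                if inside is not None and is_in != inside:
                    continue
                if (band, si) in used:
                    continue
                used.add((band, si))
                return margin + band * band_h + band_h // 2, th
        raise PhantomSpecError("census exceeds placement capacity; use more slices")

    pegs = []
    for k in range(n_attached_pegs + n_detached_pegs):
        z, th = next_slot(True)
        pegs.append(
            PegSpec(
                z_center=z, theta=th,
                state="partially_detached" if k >= n_attached_pegs else "attached",
            )
        )
    det = []
    for role, count in detachments.items():
        for _ in range(count):
            if role == "pericyte":
                z, th = next_slot(True)
            elif role == "macroglia":
                z, th = next_slot(False)
            else:
                z, th = next_slot(False)
            det.append(DetachmentSpec(role, z_center=z, theta=th, arc_rad=arc_rad))
    tub = []
    for opening, count in tubules.items():
        for _ in range(count):
            z, th = next_slot(False)
            tub.append(TubuleSpec(z_center=z, theta=th, opening=opening))
    return replace(probe, pegs=tuple(pegs), detachments=tuple(det), tubules=tuple(tub))


#: Group-level effect multipliers for cohort simulation.  The control
#: group keeps the template's peg and tubule densities and makes
#: detachment rare (Poisson mean 0.2 per role); the diabetic-like group
#: reduces peg frequency to 0.4x, raises detachment tenfold and tubules
#: 2.5x, while BM thickness statistics are identical in both groups.
STUDY_EFFECTS = {
    "non_diabetic": EffectMultipliers(pegs=1.0, detachments=0.2, tubules=1.0),
    "diabetic": EffectMultipliers(pegs=0.4, detachments=2.0, tubules=2.5),
}
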