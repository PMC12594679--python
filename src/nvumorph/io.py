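"""Label-volume input/output.

Segmentation stacks are exchanged as multi-page TIFF files (one page per
serial section, page ``k`` is slice ``z = k``) accompanied by a small
YAML/JSON *role map* sidecar that carries the physical voxel geometry and
the mapping from integer label ids to neurovascular-unit roles.  Voxel
sizes deliberately live in the sidecar, not in TIFF tags, to avoid
TIFF-dialect ambiguity; resolution tags present in the file are ignored
with a warning.

An HDF5 dialect (one ``labels`` dataset with a ``voxel_size_nm``
attribute) is supported as an alternative container.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import tifffile
import yaml

logger = logging.getLogger("nvumorph")

#: Recognised neurovascular-unit roles.  ``background`` doubles as
#: electron-lucent / unsegmented space; label 0 is always background.
ROLES = (
    "background",
    "lumen",
    "endothelium",
    "pericyte",
    "basement_membrane",
    "macroglia",
    "tubule",
)

#: Default voxel geometry (dz, dy, dx) in nanometres: 100 nm serial
#: sections at 6 nm/pixel in-plane.
DEFAULT_VOXEL_SIZE_NM = (100.0, 6.0, 6.0)


class RoleMapError(ValueError):
    """Raised for malformed role-map documents."""


@dataclass(frozen=True)
class LabelVolume:
    """An anisotropic 3D grid of non-negative integer segmentation labels.

    Parameters
    ----------
    voxels
        Integer array indexed ``(z, y, x)``; page order of the source
        TIFF is z order, 0-based, never flipped.
    voxel_size_nm
        Physical voxel extent ``(dz, dy, dx)`` in nanometres.  The axial
        step is independent of the in-plane sizes; the volume is never
        silently resampled to isotropy.
    """

    voxels: np.ndarray
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"voxels must be a non-empty 3D array, got shape {v.shape}")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError(f"voxels must be an integer array, got dtype {v.dtype}")
        if v.min() < 0:
            raise ValueError("labels must be non-negative")
        if len(self.voxel_size_nm) != 3 or any(s <= 0 for s in self.voxel_size_nm):
            raise ValueError(f"voxel sizes must be three positive numbers, got {self.voxel_size_nm}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "voxel_size_nm", tuple(float(s) for s in self.voxel_size_nm))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def dz_nm(self) -> float:
        return self.voxel_size_nm[0]

    @property
    def in_plane_nm(self) -> float:
        """In-plane pixel pitch in nm (dy and dx must agree for the
        isotropic-in-plane measurements used downstream)."""
        _, dy, dx = self.voxel_size_nm
        if not np.isclose(dy, dx):
            raise ValueError(f"in-plane voxel sizes differ (dy={dy}, dx={dx})")
        return dy

    @property
    def depth_um(self) -> float:
        """Capillary depth spanned by the stack, slices × dz, in µm."""
        return self.n_slices * self.dz_nm / 1000.0


@dataclass(frozen=True)
class RoleMap:
    """Mapping from integer label ids to neurovascular-unit roles."""

    entries: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ent = {int(k): str(v) for k, v in dict(self.entries).items()}
        for lbl, role in ent.items():
            if lbl < 0:
                raise RoleMapError(f"negative label id {lbl}")
            if role not in ROLES:
                raise RoleMapError(f"unknown role {role!r} for label {lbl}; expected one of {ROLES}")
        ent.setdefault(0, "background")
        if ent[0] != "background":
            raise RoleMapError("label 0 must map to background (electron-lucent space)")
        object.__setattr__(self, "entries", ent)

    def labels_for(self, role: str) -> list[int]:
        if role not in ROLES:
            raise RoleMapError(f"unknown role {role!r}; expected one of {ROLES}")
        return sorted(lbl for lbl, r in self.entries.items() if r == role)

    def role_of(self, label: int) -> str:
        return self.entries.get(int(label), "background")


def _parse_role_document(doc: Mapping) -> tuple[RoleMap, tuple[float, float, float]]:
    if not isinstance(doc, Mapping):
        raise RoleMapError("role map document must be a mapping")
    raw_roles = doc.get("roles", {})
    entries: dict[int, str] = {}
    for key, role in raw_roles.items():
        lbl = int(key)
        if lbl in entries:
            raise RoleMapError(f"duplicate label id {lbl} in role map")
        entries[lbl] = role
    if "voxel_size_nm" in doc:
        vs = tuple(float(s) for s in doc["voxel_size_nm"])
        if len(vs) != 3:
            raise RoleMapError("voxel_size_nm must have three entries (dz, dy, dx)")
    else:
        logger.warning("role map omits voxel_size_nm; falling back to default %s nm", DEFAULT_VOXEL_SIZE_NM)
        vs = DEFAULT_VOXEL_SIZE_NM
    return RoleMap(entries), vs


def read_role_map(path: str | Path) -> tuple[RoleMap, tuple[float, float, float]]:
    """Read a YAML or JSON role-map sidecar."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"role map not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return _parse_role_document(doc)


def write_role_map(role_map: RoleMap, voxel_size_nm: Iterable[float], path: str | Path) -> None:
    path = Path(path)
    doc = {
        "voxel_size_nm": [float(s) for s in voxel_size_nm],
        "roles": {str(k): v for k, v in sorted(role_map.entries.items())},
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_label_stack(stack_path: str | Path, role_map_path: str | Path) -> tuple[LabelVolume, RoleMap]:
    """Read a multi-page TIFF (or HDF5) label stack plus its role map.

    Pages are stacked in file order as z; voxel sizes come from the
    sidecar (TIFF resolution tags, if any, are ignored).
    """
    stack_path = Path(stack_path)
    if not stack_path.is_file():
        raise FileNotFoundError(f"label stack not found: {stack_path}")
    role_map, voxel_size = read_role_map(role_map_path)

    if stack_path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(stack_path, "r") as fh:
            voxels = np.asarray(fh["labels"])
    else:
        with tifffile.TiffFile(stack_path) as tif:
            pages = [p.asarray() for p in tif.pages]
            if any(p.shape != pages[0].shape for p in pages):
                raise ValueError(f"TIFF pages have unequal shapes in {stack_path}")
            res = tif.pages[0].tags.get("XResolution")
            if res is not None and res.value[0] != res.value[1]:
                warnings.warn(
                    "TIFF resolution tags present but ignored; voxel sizes come from the role map sidecar",
                    stacklevel=2,
                )
        voxels = np.stack(pages, axis=0)
    if not np.issubdtype(voxels.dtype, np.integer):
        raise ValueError(f"label stack must have an integer pixel type, got {voxels.dtype}")

    max_label = int(voxels.max())
    stray = [lbl for lbl in role_map.entries if lbl > max_label]
    if stray:
        raise RoleMapError(f"role map references labels absent from the stack (max {max_label}): {stray}")
    return LabelVolume(voxels, voxel_size), role_map


def write_label_stack(
    volume: LabelVolume,
    stack_path: str | Path,
    role_map: RoleMap,
    role_map_path: str | Path,
) -> None:
    """Write a volume as multi-page TIFF (or HDF5) plus role-map sidecar.

    Round-trips bit-exactly through :func:`read_label_stack`.  Labels
    above 255 are written at 16 bit; above 65535 at 32 bit.
    """
    stack_path = Path(stack_path)
    if not stack_path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {stack_path.parent}")
    max_label = int(volume.voxels.max())
    if max_label <= np.iinfo(np.uint8).max:
        dtype = np.uint8
    elif max_label <= np.iinfo(np.uint16).max:
        dtype = np.uint16
    else:
        dtype = np.uint32
    data = volume.voxels.astype(dtype)
    if stack_path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(stack_path, "w") as fh:
            ds = fh.create_dataset("labels", data=data, compression="gzip")
            ds.attrs["voxel_size_nm"] = list(volume.voxel_size_nm)
    else:
        # plain multi-page TIFF (ImageJ-readable), one page per section
        tifffile.imwrite(stack_path, data, photometric="minisblack")
    write_role_map(role_map, volume.voxel_size_nm, role_map_path)


def role_mask(volume: LabelVolume, role_map: RoleMap, role: str) -> np.ndarray:
    """Boolean mask, same shape as the volume, of voxels whose label maps
    to ``role``.  Labels absent from the role map count as background."""
    if role not in ROLES:
        raise RoleMapError(f"unknown role {role!r}; expected one of {ROLES}")
    # lookup table over label ids (labels absent from the map are background)
    n = int(volume.voxels.max()) + 1
    lut = np.zeros(n, dtype=bool)
    if role == "background":
        lut[:] = True
        for lbl, r in role_map.entries.items():
            if lbl < n and r != "background":
                lut[lbl] = False
    else:
        for lbl in role_map.labels_for(role):
            if lbl < n:
                lut[lbl] = True
    return lut[volume.voxels]
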