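"""Core spatial containers: voxel grids and 4D acquisitions.

Coordinates follow the NIfTI convention: voxel indices are 0-based, world
("mm") coordinates are obtained through an axis-aligned affine built from the
voxel size and the mm position of voxel (0, 0, 0). Oblique affines are not
modelled; phantom data are generated pre-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six task conditions: {spoken, written} presentation format crossed with
#: word meaning referring to auditory (AUD) or visual (VIS) features, plus
#: meaningless non-words (NON).
CONDITIONS: tuple[str, ...] = (
    "Spoken-AUD",
    "Spoken-VIS",
    "Spoken-NON",
    "Written-AUD",
    "Written-VIS",
    "Written-NON",
)

FORMATS = ("Spoken", "Written")
FEATURES = ("AUD", "VIS", "NON")


def condition_format(condition: str) -> str:
    """Presentation format ('Spoken' or 'Written') of a condition label."""
    fmt, _, _ = condition.partition("-")
    if fmt not in FORMATS:
        raise ValueError(f"unknown condition label: {condition!r}")
    return fmt


def condition_feature(condition: str) -> str:
    """Semantic feature type ('AUD', 'VIS') or 'NON' of a condition label."""
    _, _, feat = condition.partition("-")
    if feat not in FEATURES:
        raise ValueError(f"unknown condition label: {condition!r}")
    return feat


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape : triple of int
        Voxels per axis; each entry >= 1.
    voxel_size : triple of float, mm
        Grid spacing per axis; each entry > 0.
    origin : triple of float, mm
        World coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @classmethod
    def centered(cls, shape, voxel_size=(2.0, 2.0, 2.0)) -> "VolumeGrid":
        """Grid whose world origin sits at the volume center."""
        shape = tuple(int(s) for s in shape)
        voxel_size = tuple(float(v) for v in voxel_size)
        origin = tuple(-(s - 1) / 2.0 * v for s, v in zip(shape, voxel_size))
        return cls(shape=shape, voxel_size=voxel_size, origin=origin)

    @classmethod
    def from_affine(cls, affine: np.ndarray, shape) -> "VolumeGrid":
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.max(np.abs(off_diag)) > 1e-6:
            raise ValueError("oblique affines are not supported")
        diag = np.diag(rot)
        if np.any(diag <= 0):
            raise ValueError("affine must have positive diagonal (RAS-aligned)")
        return cls(shape=tuple(shape), voxel_size=tuple(diag), origin=tuple(affine[:3, 3]))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def mm_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def contains_mm(self, xyz) -> bool:
        ijk = self.mm_to_voxel(xyz)
        return bool(np.all(ijk >= -0.5) and np.all(ijk <= np.asarray(self.shape) - 0.5))

    def voxel_coords_mm(self) -> np.ndarray:
        """(X, Y, Z, 3) array of voxel-center world coordinates."""
        grids = np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij")
        ijk = np.stack(grids, axis=-1).astype(float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)


@dataclass
class BoldRun:
    """One 4D acquisition.

    ``data`` is (x, y, z, time); ``motion_params`` is (time, 6) with three
    translations in mm and three rotations in rad, used only as confound
    regressors (motion *correction* is out of scope for phantom data).
    """

    grid: VolumeGrid
    tr: float
    data: np.ndarray
    motion_params: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != tuple(self.grid.shape):
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid {self.grid.shape}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("time dimension must be >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.motion_params is None:
            self.motion_params = np.zeros((self.n_scans, 6))
        self.motion_params = np.asarray(self.motion_params, dtype=float)
        if self.motion_params.shape != (self.n_scans, 6):
            raise ValueError(
                f"motion_params must be ({self.n_scans}, 6), got {self.motion_params.shape}"
            )

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr
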