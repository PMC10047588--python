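"""Volume/mask data model, NIfTI I/O, rigid transforms, and mask propagation.

Physical coordinates are voxel *centers*; voxel indices are 0-based.  A grid's
world mapping is ``x = direction @ diag(spacing) @ index + origin`` (mm), i.e.
exactly the NIfTI affine split into an orthonormal direction matrix, strictly
positive spacings, and an origin.

Masks are propagated between grids by voxel-center containment only — target
image intensities are never resampled, so downstream measurements always read
original voxels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "BinaryMask",
    "RigidTransform",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "volume_cm3",
    "estimate_rigid",
    "propagate_mask",
]


@dataclass
class ImageGrid:
    """Geometry of a 3-D voxel lattice: shape, spacing (mm), origin (mm), direction."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.direction.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if not np.isclose(abs(np.linalg.det(self.direction)), 1.0, atol=1e-6):
            raise ValueError("direction matrix determinant must be +-1")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 homogeneous index -> world (mm) map."""
        A = np.eye(4)
        A[:3, :3] = self.direction @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        M = np.linalg.inv(self.direction @ np.diag(self.spacing))
        return (xyz - np.asarray(self.origin)) @ M.T

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class ScalarVolume:
    """One scalar per voxel on an :class:`ImageGrid`, with a units tag."""

    grid: ImageGrid
    values: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not self.units:
            raise ValueError("units label must be non-empty")


@dataclass
class BinaryMask:
    """Boolean voxel set on an :class:`ImageGrid`."""

    grid: ImageGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_cm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class RigidTransform:
    """Rigid map from moving-space to fixed-space physical coordinates (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = tuple(float(t) for t in self.translation)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        tinv = -Rinv @ np.asarray(self.translation)
        return RigidTransform(Rinv, tuple(tinv))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        t = self.rotation @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform(R, tuple(t))


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGrid:
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    return ImageGrid(tuple(shape), tuple(spacing), tuple(affine[:3, 3]), direction)


def read_volume(path, units: str = "arbitrary") -> ScalarVolume:
    """Read a 3-D scalar NIfTI-1 volume.

    Header scale/intercept are applied (and nothing else); grid geometry is
    taken from the affine.  Non-3-D payloads raise ``ValueError``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got shape {data.shape}")
    grid = _grid_from_affine(img.affine, data.shape)
    return ScalarVolume(grid, data, units=units)


def read_mask(path) -> BinaryMask:
    vol = read_volume(path, units="binary")
    return BinaryMask(vol.grid, vol.values > 0.5)


def write_volume(vol: ScalarVolume, path) -> str:
    """Write a volume as NIfTI-1 (float64 payload, lossless round-trip)."""
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), vol.grid.affine)
    nib.save(img, str(path))
    return str(path)


def write_mask(mask: BinaryMask, path) -> str:
    """Write a mask as uint8 0/1 NIfTI-1."""
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
    return str(path)


def volume_cm3(mask: BinaryMask) -> float:
    """Mask volume in cm^3: member count x voxel volume (mm^3) / 1000."""
    return mask.volume_cm3


def estimate_rigid(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    search_window_mm: float,
    roi: BinaryMask,
) -> RigidTransform:
    """Translation-only block matching of ``moving`` onto ``fixed`` inside ``roi``.

    Searches integer-voxel translations within ``search_window_mm`` along each
    axis, maximizing normalized cross-correlation over the ROI; rotation is
    fixed to identity.  Both volumes must share voxel spacing and shape (same
    scanner matrix), as in PET-to-PET tumor-centered registration.
    Deterministic: ties resolve to the smallest shift in lexicographic order.
    """
    if roi.count == 0:
        raise ValueError("estimate_rigid: empty ROI")
    if moving.values.shape != fixed.values.shape or not np.allclose(
        moving.grid.spacing, fixed.grid.spacing
    ):
        raise ValueError("estimate_rigid requires equal-shape, equal-spacing grids")
    spacing = np.asarray(fixed.grid.spacing)
    max_shift = np.floor(search_window_mm / spacing).astype(int)
    if np.all(max_shift < 1):
        raise ValueError("search window smaller than one voxel on every axis")

    mvals = moving.values
    sel = roi.membership
    idx = np.argwhere(sel)
    f_all = fixed.values[sel]
    shape = np.asarray(fixed.values.shape)

    best_key = (-np.inf, 0.0)
    best_d = (0, 0, 0)
    for di in range(-max_shift[0], max_shift[0] + 1):
        for dj in range(-max_shift[1], max_shift[1] + 1):
            for dk in range(-max_shift[2], max_shift[2] + 1):
                shifted = idx + np.array([di, dj, dk])
                ok = np.all((shifted >= 0) & (shifted < shape), axis=1)
                if ok.sum() < 2:
                    continue
                m = mvals[shifted[ok, 0], shifted[ok, 1], shifted[ok, 2]]
                f = f_all[ok]
                f = f - f.mean()
                m = m - m.mean()
                denom = np.sqrt((f**2).sum() * (m**2).sum())
                if denom <= 0:
                    continue
                ncc = float((f * m).sum() / denom)
                key = (round(ncc, 12), -float(abs(di) + abs(dj) + abs(dk)))
                if key > best_key:
                    best_key = key
                    best_d = (di, dj, dk)
    d = np.asarray(best_d, dtype=float)
    # moving[i + d] aligns with fixed[i]: a fixed-space point x corresponds to
    # moving-space point x + d*spacing, so moving->fixed subtracts d*spacing.
    translation = -(fixed.grid.direction @ (d * spacing))
    return RigidTransform(np.eye(3), tuple(translation))


def propagate_mask(
    mask: BinaryMask, transform: RigidTransform, target_grid: ImageGrid
) -> BinaryMask:
    """Carry a mask onto ``target_grid`` by voxel-center containment.

    A target voxel is a member iff its physical center, mapped through the
    *inverse* of ``transform`` (which maps mask/source space to target space),
    falls inside a member voxel of the source mask.  No intensity resampling
    takes place anywhere.  Disjoint extents yield an empty mask and a warning.
    """
    src = mask.grid
    tgt = target_grid
    # Compose: target index -> world -> (inverse transform) -> source world -> source index
    inv = transform.inverse()
    A_tgt = tgt.affine
    M = np.linalg.inv(src.affine) @ _to_h(inv) @ A_tgt
    ii, jj, kk = np.meshgrid(
        np.arange(tgt.shape[0]), np.arange(tgt.shape[1]), np.arange(tgt.shape[2]),
        indexing="ij",
    )
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    src_idx = pts @ M[:3, :3].T + M[:3, 3]
    src_idx = np.round(src_idx).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.asarray(src.shape)), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    sel = src_idx[inside]
    out[inside] = mask.membership[sel[:, 0], sel[:, 1], sel[:, 2]]
    result = BinaryMask(tgt, out.reshape(tgt.shape))
    if mask.count > 0 and result.count == 0:
        warnings.warn("propagate_mask: transformed mask does not overlap the target grid")
        logger.warning("propagate_mask produced an empty mask (disjoint extents)")
    return result


def _to_h(t: RigidTransform) -> np.ndarray:
    H = np.eye(4)
    H[:3, :3] = t.rotation
    H[:3, 3] = t.translation
    return H
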