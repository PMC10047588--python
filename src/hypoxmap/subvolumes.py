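"""Boolean tumor-volume / subvolume algebra and per-region parameter extraction.

Three tumor volumes (FDG-PET metabolic volume, MRI volume, and their Boolean
union) each split into a hypoxic subvolume (FMISO threshold at 1.4 x muscle
SUVmean) and its normoxic complement within the tumor.  All subvolume masks
live on the FMISO PET grid; quantitative-map extraction propagates masks onto
each map's grid without resampling intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import BinaryMask, RigidTransform, ScalarVolume, propagate_mask
from .pet import muscle_reference, segment_hypoxic, segment_mtv

__all__ = [
    "SubvolumeSet",
    "SubvolumeReport",
    "union",
    "exclude",
    "intersection",
    "build_subvolume_set",
    "dice",
    "jaccard",
    "overlap_fraction",
    "extract_report",
]


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if not a.grid.same_geometry(b.grid):
        raise ValueError("masks must live on the same grid (propagate first)")


def union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise OR."""
    _check_same_grid(a, b)
    return BinaryMask(a.grid, a.membership | b.membership)


def intersection(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_grid(a, b)
    return BinaryMask(a.grid, a.membership & b.membership)


def exclude(tv: BinaryMask, hsv: BinaryMask) -> BinaryMask:
    """Non-inclusion: tumor voxels not in the hypoxic subvolume (tv AND NOT hsv)."""
    _check_same_grid(tv, hsv)
    return BinaryMask(tv.grid, tv.membership & ~hsv.membership)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|)."""
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise ValueError("dice undefined for two empty masks")
    inter = int((a.membership & b.membership).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |A n B| / |A u B|."""
    _check_same_grid(a, b)
    un = int((a.membership | b.membership).sum())
    if un == 0:
        raise ValueError("jaccard undefined for two empty masks")
    inter = int((a.membership & b.membership).sum())
    return inter / un


def overlap_fraction(a: BinaryMask, b: BinaryMask) -> float:
    """Overlap coefficient |A n B| / min(|A|, |B|); 1 iff the smaller mask is
    contained in the larger."""
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na == 0 or nb == 0:
        raise ValueError("overlap_fraction requires two non-empty masks")
    inter = int((a.membership & b.membership).sum())
    return inter / min(na, nb)


@dataclass
class SubvolumeSet:
    """The nine masks of one patient, all on the FMISO PET grid."""

    tv_fdg: BinaryMask
    tv_mri: BinaryMask
    tv_union: BinaryMask
    hsv_fdg: BinaryMask
    hsv_mri: BinaryMask
    hsv_union: BinaryMask
    nsv_fdg: BinaryMask
    nsv_mri: BinaryMask
    nsv_union: BinaryMask
    muscle_suv_mean: Optional[float] = None

    def __post_init__(self) -> None:
        for tv, hsv, nsv in (
            (self.tv_fdg, self.hsv_fdg, self.nsv_fdg),
            (self.tv_mri, self.hsv_mri, self.nsv_mri),
            (self.tv_union, self.hsv_union, self.nsv_union),
        ):
            if np.any(hsv.membership & ~tv.membership):
                raise ValueError("hypoxic subvolume must be contained in its tumor volume")
            if np.any((hsv.membership | nsv.membership) != tv.membership) or np.any(
                hsv.membership & nsv.membership
            ):
                raise ValueError("hsv and nsv must partition the tumor volume")
        if np.any(self.tv_union.membership != (self.tv_fdg.membership | self.tv_mri.membership)):
            raise ValueError("tv_union must equal tv_fdg | tv_mri")

    def masks(self) -> dict[str, BinaryMask]:
        return {
            "tv_fdg": self.tv_fdg, "tv_mri": self.tv_mri, "tv_union": self.tv_union,
            "hsv_fdg": self.hsv_fdg, "hsv_mri": self.hsv_mri, "hsv_union": self.hsv_union,
            "nsv_fdg": self.nsv_fdg, "nsv_mri": self.nsv_mri, "nsv_union": self.nsv_union,
        }

    def volumes_cm3(self) -> dict[str, float]:
        return {name: m.volume_cm3 for name, m in self.masks().items()}


def build_subvolume_set(
    suv_fdg: ScalarVolume,
    suv_fmiso: ScalarVolume,
    mri_tumor: BinaryMask,
    muscle_roi: BinaryMask,
    fdg_search_roi: BinaryMask,
    fdg_to_fmiso: Optional[RigidTransform] = None,
    mri_to_fmiso: Optional[RigidTransform] = None,
    mtv_fraction: float = 0.40,
    hypoxia_factor: float = 1.4,
) -> SubvolumeSet:
    """Run the full subvolume procedure on the FMISO grid.

    Segments the metabolic tumor volume on the FDG SUV map, propagates it and
    the MRI tumor mask to the FMISO grid, forms the Boolean union, thresholds
    each tumor volume at ``hypoxia_factor`` x muscle SUVmean on the FMISO map,
    and completes each with its normoxic complement.
    """
    fdg_to_fmiso = fdg_to_fmiso or RigidTransform.identity()
    mri_to_fmiso = mri_to_fmiso or RigidTransform.identity()
    fmiso_grid = suv_fmiso.grid

    mtv = segment_mtv(suv_fdg, fdg_search_roi, fraction=mtv_fraction)
    tv_fdg = propagate_mask(mtv, fdg_to_fmiso, fmiso_grid)
    tv_mri = propagate_mask(mri_tumor, mri_to_fmiso, fmiso_grid)
    tv_un = union(tv_fdg, tv_mri)

    muscle_mean = muscle_reference(suv_fmiso, muscle_roi)
    out = {}
    for name, tv in (("fdg", tv_fdg), ("mri", tv_mri), ("union", tv_un)):
        if tv.count == 0:
            hsv = BinaryMask(fmiso_grid, np.zeros(fmiso_grid.shape, dtype=bool))
        else:
            hsv = segment_hypoxic(suv_fmiso, tv, muscle_mean, factor=hypoxia_factor)
        out[f"hsv_{name}"] = hsv
        out[f"nsv_{name}"] = exclude(tv, hsv)
    return SubvolumeSet(
        tv_fdg=tv_fdg, tv_mri=tv_mri, tv_union=tv_un,
        hsv_fdg=out["hsv_fdg"], hsv_mri=out["hsv_mri"], hsv_union=out["hsv_union"],
        nsv_fdg=out["nsv_fdg"], nsv_mri=out["nsv_mri"], nsv_union=out["nsv_union"],
        muscle_suv_mean=muscle_mean,
    )


@dataclass
class RegionStats:
    n_voxels: int
    mean: Optional[float]
    max: Optional[float]


@dataclass
class SubvolumeReport:
    """Per (sub)volume x quantitative map region statistics.

    ``stats[mask_name][map_name]`` is a :class:`RegionStats`; empty regions
    carry ``mean = max = None`` (absent, never zero-filled).
    """

    volumes_cm3: dict[str, float]
    stats: dict[str, dict[str, RegionStats]]

    def mean(self, mask_name: str, map_name: str) -> Optional[float]:
        return self.stats[mask_name][map_name].mean

    def max(self, mask_name: str, map_name: str) -> Optional[float]:
        return self.stats[mask_name][map_name].max


def extract_report(
    maps: Mapping[str, ScalarVolume],
    subvols: SubvolumeSet,
    valid: Optional[Mapping[str, BinaryMask]] = None,
    transforms: Optional[Mapping[str, RigidTransform]] = None,
) -> SubvolumeReport:
    """Extract mean and max of each quantitative map inside each (sub)volume.

    Masks are propagated from the FMISO grid onto each map's own grid
    (intensities untouched); per-map ``valid`` masks exclude failed fits.
    ``transforms[name]`` maps FMISO space to the named map's space.
    """
    stats: dict[str, dict[str, RegionStats]] = {}
    masks = subvols.masks()
    prop_cache: dict[tuple[str, int], BinaryMask] = {}
    for mask_name, mask in masks.items():
        stats[mask_name] = {}
        for map_name, vol in maps.items():
            t = None if transforms is None else transforms.get(map_name)
            if mask.grid.same_geometry(vol.grid) and t is None:
                local = mask
            else:
                key = (mask_name, id(vol.grid), id(t))
                if key not in prop_cache:
                    prop_cache[key] = propagate_mask(
                        mask, t or RigidTransform.identity(), vol.grid
                    )
                local = prop_cache[key]
            sel = local.membership
            if valid is not None and map_name in valid:
                sel = sel & valid[map_name].membership
            vals = vol.values[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                stats[mask_name][map_name] = RegionStats(0, None, None)
            else:
                stats[mask_name][map_name] = RegionStats(
                    int(vals.size), float(vals.mean()), float(vals.max())
                )
    return SubvolumeReport(volumes_cm3=subvols.volumes_cm3(), stats=stats)
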