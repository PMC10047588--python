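"""PET-derived quantities: SUV, metabolic tumor volume, TLG, muscle reference,
hypoxic-subvolume segmentation, tumor-to-muscle ratio, and SUVpeak.

Conventions
-----------
* SUV is body-weight normalized: ``SUV = activity[Bq/mL] / (dose[Bq] / weight[g])``
  with the injected dose assumed already decay-corrected to scan start.
* Both thresholding rules (40 % of SUVmax for the metabolic tumor volume, 1.4 x
  the contralateral-muscle SUVmean for the hypoxic subvolume) use a *closed*
  threshold (``>=``).
* The MTV keeps only the 26-connected component containing the SUVmax voxel:
  a single-lesion contract that prevents remote hot structures from inflating
  the volume.
* A lesion is classified hypoxic when TMR is *strictly* greater than 1.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ScalarVolume

__all__ = [
    "PetStudy",
    "PetMetrics",
    "compute_suv",
    "segment_mtv",
    "tlg",
    "muscle_reference",
    "segment_hypoxic",
    "tmr",
    "classify_hypoxic",
    "suv_peak",
    "pet_metrics",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PetStudy:
    """A reconstructed PET activity volume plus the injection bookkeeping."""

    activity: ScalarVolume  # Bq/mL
    injected_dose_bq: float  # decay-corrected to scan start
    body_weight_g: float
    tracer: str  # "FDG" | "FMISO"

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0:
            raise ValueError("injected dose must be strictly positive")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be strictly positive")
        if self.tracer not in ("FDG", "FMISO"):
            raise ValueError(f"tracer must be FDG or FMISO, got {self.tracer!r}")


@dataclass
class PetMetrics:
    suv_max: float
    suv_mean: float
    mtv_cm3: float
    tlg: float
    suv_peak: Optional[float] = None
    tmr: Optional[float] = None
    hypoxic: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.suv_mean > self.suv_max + 1e-9:
            raise ValueError("suv_mean cannot exceed suv_max")
        if self.suv_peak is not None and self.suv_peak > self.suv_max + 1e-9:
            raise ValueError("suv_peak cannot exceed suv_max")
        if abs(self.tlg - self.mtv_cm3 * self.suv_mean) > 1e-9 * max(1.0, self.tlg):
            raise ValueError("tlg must equal mtv_cm3 * suv_mean")


def compute_suv(study: PetStudy) -> ScalarVolume:
    """Body-weight SUV map: activity / (dose / weight)."""
    factor = study.body_weight_g / study.injected_dose_bq
    return ScalarVolume(study.activity.grid, study.activity.values * factor, units="SUV")


def segment_mtv(
    suv: ScalarVolume, search_roi: BinaryMask, fraction: float = 0.40
) -> BinaryMask:
    """Metabolic tumor volume: threshold at ``fraction`` x SUVmax within the ROI.

    SUVmax is taken inside ``search_roi``; the mask is the set of ROI voxels
    with SUV >= fraction * SUVmax, restricted to the 26-connected component
    containing the SUVmax voxel.  Never empty.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    roi = search_roi.membership
    if not roi.any():
        raise ValueError("segment_mtv: empty search ROI")
    vals = np.where(roi, suv.values, -np.inf)
    peak_idx = np.unravel_index(np.argmax(vals), vals.shape)
    suv_max = vals[peak_idx]
    if suv_max <= 0:
        raise ValueError("segment_mtv: SUV is non-positive everywhere in the ROI")
    above = roi & (suv.values >= fraction * suv_max)
    labels, _ = ndimage.label(above, structure=_CONN26)
    keep = labels == labels[peak_idx]
    return BinaryMask(suv.grid, keep)


def tlg(mtv_cm3: float, suv_mean: float) -> float:
    """Total lesion glycolysis: MTV (cm^3) x SUVmean."""
    if mtv_cm3 < 0 or suv_mean < 0:
        raise ValueError("tlg arguments must be non-negative")
    return float(mtv_cm3) * float(suv_mean)


def muscle_reference(suv: ScalarVolume, muscle_roi: BinaryMask) -> float:
    """Mean SUV over the contralateral-muscle reference ROI."""
    if muscle_roi.count == 0:
        raise ValueError("muscle_reference: empty ROI")
    return float(suv.values[muscle_roi.membership].mean())


def segment_hypoxic(
    fmiso_suv: ScalarVolume,
    tumor_volume: BinaryMask,
    muscle_suv_mean: float,
    factor: float = 1.4,
) -> BinaryMask:
    """Hypoxic subvolume: tumor voxels with FMISO SUV >= factor x muscle SUVmean.

    May legitimately be empty (lesions without measurable hypoxia).
    """
    if muscle_suv_mean <= 0:
        raise ValueError("muscle reference SUVmean must be strictly positive")
    if tumor_volume.count == 0:
        raise ValueError("segment_hypoxic: empty tumor volume")
    member = tumor_volume.membership & (fmiso_suv.values >= factor * muscle_suv_mean)
    return BinaryMask(fmiso_suv.grid, member)


def tmr(lesion_suv_max: float, muscle_suv_mean: float) -> float:
    """Tumor-to-muscle ratio: lesion SUVmax / muscle SUVmean."""
    if lesion_suv_max <= 0 or muscle_suv_mean <= 0:
        raise ValueError("tmr inputs must be strictly positive")
    return float(lesion_suv_max) / float(muscle_suv_mean)


def classify_hypoxic(tmr_value: float, cutoff: float = 1.25) -> bool:
    """True iff TMR is strictly greater than the cutoff."""
    if tmr_value <= 0:
        raise ValueError("tmr_value must be strictly positive")
    return tmr_value > cutoff


def _sphere_offsets(spacing: tuple[float, float, float], sphere_ml: float) -> np.ndarray:
    """Voxel-offset set whose centers lie within the radius of a sphere of
    ``sphere_ml`` milliliters; always contains at least the center voxel."""
    radius_mm = (3.0 * sphere_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sp = np.asarray(spacing)
    half = np.floor(radius_mm / sp).astype(int)
    ranges = [np.arange(-h, h + 1) for h in half]
    oi, oj, ok = np.meshgrid(*ranges, indexing="ij")
    offs = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(offs * sp, axis=1)
    offs = offs[dist <= radius_mm + 1e-12]
    if len(offs) == 0:
        offs = np.zeros((1, 3), dtype=int)
    return offs


def suv_peak(suv: ScalarVolume, roi: BinaryMask, sphere_ml: float = 1.0) -> float:
    """SUVpeak: max over ROI voxels of the mean SUV in a sphere centered there.

    EANM-style definition with a 1 mL sphere approximated by the voxel set
    whose centers lie within the sphere radius; spheres extending past the
    volume edge are averaged over in-volume voxels only.
    """
    if roi.count == 0:
        raise ValueError("suv_peak: empty ROI")
    offs = _sphere_offsets(suv.grid.spacing, sphere_ml)
    idx = np.argwhere(roi.membership)
    shape = np.asarray(suv.values.shape)
    # Accumulate sums and counts per ROI voxel over the sphere offsets.
    sums = np.zeros(len(idx))
    counts = np.zeros(len(idx))
    for off in offs:
        pos = idx + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        sums[ok] += suv.values[pos[ok, 0], pos[ok, 1], pos[ok, 2]]
        counts[ok] += 1
    means = sums / counts
    return float(means.max())


def pet_metrics(
    suv: ScalarVolume,
    lesion: BinaryMask,
    muscle_roi: Optional[BinaryMask] = None,
    tracer: str = "FDG",
    peak_sphere_ml: float = 1.0,
) -> PetMetrics:
    """Bundle the per-lesion PET metrics for one study."""
    vals = suv.values[lesion.membership]
    if vals.size == 0:
        raise ValueError("pet_metrics: empty lesion mask")
    suv_max = float(vals.max())
    suv_mean = float(vals.mean())
    mtv = lesion.volume_cm3
    peak = suv_peak(suv, lesion, peak_sphere_ml)
    ratio = hypox = None
    if tracer == "FMISO":
        if muscle_roi is None:
            raise ValueError("FMISO metrics require a muscle reference ROI")
        ratio = tmr(suv_max, muscle_reference(suv, muscle_roi))
        hypox = classify_hypoxic(ratio)
    return PetMetrics(
        suv_max=suv_max,
        suv_mean=suv_mean,
        mtv_cm3=mtv,
        tlg=tlg(mtv, suv_mean),
        suv_peak=peak,
        tmr=ratio,
        hypoxic=hypox,
    )
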