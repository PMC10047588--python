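"""Digital head-and-neck phantom: ground-truth tissue maps, masks, and
forward-simulated FDG PET, FMISO PET, DWI, VFA, multi-echo T2, and DCE series.

Geometry
--------
The phantom lives in a patient coordinate frame (mm): an FDG-avid tumor
ellipsoid, a (usually larger, slightly offset) MRI-visible tumor ellipsoid, an
optional hypoxic core ellipsoid concentric with the tumor, and a contralateral
muscle reference box in a uniform background.  Each acquisition session may
displace the patient by a rigid offset; voxel rasterization is by voxel-center
containment on each modality's own grid, so inter-modality geometry exercises
the same propagation machinery as real data.

Forward models are exactly the fitting models of :mod:`hypoxmap.relaxometry`
and :mod:`hypoxmap.dce` evaluated at the acquisition settings; noise is
additive Gaussian (PET noise scales with local intensity to mimic count
statistics).  Every simulated output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import BinaryMask, ImageGrid, RigidTransform, ScalarVolume, estimate_rigid
from .dce import DceSeries, extended_tofts_forward, parker_aif
from .pet import PetStudy
from .relaxometry import SignalSeries

__all__ = [
    "TissueParams",
    "PhantomConfig",
    "PhantomTruth",
    "default_config",
    "cohort_config",
    "build_phantom",
    "simulate_pet",
    "simulate_mri",
    "make_cohort",
]

MODALITIES = ("fdg", "fmiso", "dwi", "t1", "t2", "dce")

# Acquisition settings (MRI protocol constants)
DWI_B_VALUES = np.array([0.0, 500.0, 1000.0])  # s/mm^2
VFA_ANGLES_DEG = np.array([3.0, 10.0, 20.0, 30.0])
VFA_REPEATS = 4
VFA_TR_MS = 15.0
T2_ECHOES_MS = np.array([5.98, 11.96, 17.94, 23.92, 29.9, 35.88, 41.86, 47.84])
DCE_TR_MS = 8.4
DCE_FLIP_DEG = 25.0
DCE_N_FRAMES = 48
DCE_DT_S = 10.0
DCE_N_BASELINE = 5


@dataclass
class TissueParams:
    """Per-compartment ground-truth tissue parameters."""

    fdg_suv: float
    fmiso_suv: float
    adc: float  # mm^2/s
    t1_ms: float
    t2_ms: float
    ktrans: float  # min^-1
    ve: float
    vp: float
    m0: float = 1000.0


def _default_tissues() -> dict:
    # Hypoxic-core effect sizes relative to normoxic tumor: ADC +30 %,
    # T1 -15 %, T2 -20 %; DCE parameters carry a configured zero effect, and
    # are spatially uniform across tumor-adjacent tissue so that subvolume
    # masks straddling the tumor boundary at coarse voxel sizes cannot pick
    # up spurious perfusion contrast from partial-volume rims.
    return {
        "background": TissueParams(0.7, 0.7, 2.0e-3, 400.0, 80.0, 0.15, 0.30, 0.04, 800.0),
        "muscle": TissueParams(1.0, 1.0, 1.5e-3, 1000.0, 45.0, 0.06, 0.15, 0.02, 900.0),
        "tumor": TissueParams(8.0, 1.1, 1.0e-3, 1200.0, 90.0, 0.15, 0.30, 0.04, 1000.0),
        "core": TissueParams(8.0, 1.8, 1.3e-3, 1020.0, 72.0, 0.15, 0.30, 0.04, 1000.0),
    }


@dataclass
class PhantomConfig:
    """Everything needed to build and simulate one phantom patient."""

    seed: int
    grids: dict = field(default_factory=dict)  # modality -> (shape, spacing)
    tumor_center_mm: tuple = (20.0, 0.0, 0.0)
    tumor_radii_mm: tuple = (15.0, 12.0, 10.0)  # FDG-avid ellipsoid
    mri_tumor_radii_mm: tuple = (20.0, 16.0, 13.0)
    mri_tumor_offset_mm: tuple = (3.0, 1.0, 0.0)
    core_radii_mm: tuple = (6.0, 5.0, 4.0)  # zeros -> no hypoxic core
    muscle_center_mm: tuple = (-40.0, 0.0, 0.0)
    muscle_half_mm: tuple = (8.0, 8.0, 12.0)
    tissues: dict = field(default_factory=_default_tissues)
    session_offsets_mm: dict = field(
        default_factory=lambda: {"fdg": (2.7, -2.7, 0.0), "fmiso": (0.0, 0.0, 0.0), "mri": (0.0, 0.0, 0.0)}
    )
    pet_noise_frac: float = 0.05  # Gaussian SD as fraction of local truth activity
    mri_snr: float = 50.0  # max-signal / noise-SD per protocol
    dce_noise_frac: float = 0.02  # SD as fraction of peak enhancement
    fdg_dose_mbq_per_kg: float = 3.5
    fmiso_dose_mbq_per_kg: float = 4.0
    body_weight_kg: float = 75.0
    hematocrit: float = 0.42
    relaxivity: float = 3.6  # mM^-1 s^-1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not self.grids:
            self.grids = _default_grids()
        if any(r < 0 for r in self.core_radii_mm):
            raise ValueError("core radii must be non-negative")
        if any(c > t for c, t in zip(self.core_radii_mm, self.tumor_radii_mm)):
            raise ValueError("hypoxic core must be contained in the tumor")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be strictly positive")

    def session_of(self, modality: str) -> str:
        return modality if modality in ("fdg", "fmiso") else "mri"


def _default_grids() -> dict:
    # PET 128^3 at 2.7 mm; MRI matrices follow the acquisition-table geometry.
    return {
        "fdg": ((128, 128, 128), (2.7, 2.7, 2.7)),
        "fmiso": ((128, 128, 128), (2.7, 2.7, 2.7)),
        "dwi": ((256, 256, 24), (0.94, 0.94, 3.3)),
        "t1": ((128, 128, 24), (1.01, 1.0, 2.0)),
        "t2": ((128, 128, 24), (1.01, 1.01, 2.0)),
        "dce": ((256, 256, 16), (0.9, 0.9, 3.4)),
    }


def cohort_grids() -> dict:
    """Reduced grids used for cohort-scale simulation studies."""
    return {
        "fdg": ((48, 48, 32), (2.7, 2.7, 2.7)),
        "fmiso": ((48, 48, 32), (2.7, 2.7, 2.7)),
        "dwi": ((48, 48, 20), (2.0, 2.0, 3.3)),
        "t1": ((48, 48, 32), (2.0, 2.0, 2.0)),
        "t2": ((48, 48, 32), (2.0, 2.0, 2.0)),
        "dce": ((48, 48, 18), (2.0, 2.0, 3.4)),
    }


def default_config(seed: int = 0, **overrides) -> PhantomConfig:
    return PhantomConfig(seed=seed, **overrides)


def cohort_config(seed: int = 0, **overrides) -> PhantomConfig:
    overrides.setdefault("grids", cohort_grids())
    return PhantomConfig(seed=seed, **overrides)


def _centered_grid(shape, spacing, center=(0.0, 0.0, 0.0)) -> ImageGrid:
    origin = tuple(c - s * (n - 1) / 2.0 for n, s, c in zip(shape, spacing, center))
    return ImageGrid(tuple(shape), tuple(spacing), origin)


@dataclass
class PhantomTruth:
    """Ground-truth masks and parameter maps per modality grid (lazy, cached)."""

    config: PhantomConfig

    def __post_init__(self) -> None:
        # PET fields of view cover the whole neck (tumor + contralateral
        # muscle); MRI acquisitions are centered on the lesion.
        self._grids = {}
        for m, (shape, spacing) in self.config.grids.items():
            center = (0.0, 0.0, 0.0) if m in ("fdg", "fmiso") else self.config.tumor_center_mm
            self._grids[m] = _centered_grid(shape, spacing, center)
        self._label_cache: dict = {}

    def grid(self, modality: str) -> ImageGrid:
        return self._grids[modality]

    def session_offset(self, modality: str) -> np.ndarray:
        return np.asarray(
            self.config.session_offsets_mm[self.config.session_of(modality)], dtype=float
        )

    def _patient_coords(self, modality: str) -> np.ndarray:
        g = self.grid(modality)
        axes = [np.arange(n) * s + o for n, s, o in zip(g.shape, g.spacing, g.origin)]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        xyz = np.stack([ii, jj, kk], axis=-1)
        return xyz - self.session_offset(modality)

    def labels(self, modality: str) -> np.ndarray:
        """Compartment label map: 0 background, 1 muscle, 2 tumor, 3 hypoxic core."""
        if modality in self._label_cache:
            return self._label_cache[modality]
        cfg = self.config
        p = self._patient_coords(modality)
        lab = np.zeros(p.shape[:-1], dtype=np.int8)

        mus = np.all(
            np.abs(p - np.asarray(cfg.muscle_center_mm)) <= np.asarray(cfg.muscle_half_mm),
            axis=-1,
        )
        lab[mus] = 1

        def ellipsoid(center, radii):
            r = np.asarray(radii, dtype=float)
            if np.any(r <= 0):
                return np.zeros(p.shape[:-1], dtype=bool)
            d = (p - np.asarray(center)) / r
            return (d**2).sum(axis=-1) <= 1.0

        fdg_avid = ellipsoid(cfg.tumor_center_mm, cfg.tumor_radii_mm)
        mri_tum = ellipsoid(
            np.asarray(cfg.tumor_center_mm) + np.asarray(cfg.mri_tumor_offset_mm),
            cfg.mri_tumor_radii_mm,
        )
        core = ellipsoid(cfg.tumor_center_mm, cfg.core_radii_mm)
        lab[fdg_avid | mri_tum] = 2
        lab[core] = 3
        self._label_cache[modality] = lab
        self._mask_cache = getattr(self, "_mask_cache", {})
        self._mask_cache[modality] = {
            "tumor_fdg_avid": fdg_avid,
            "tumor_mri": mri_tum,
            "hypoxic_core": core,
            "muscle": mus,
        }
        return lab

    def masks(self, modality: str) -> dict[str, BinaryMask]:
        self.labels(modality)
        g = self.grid(modality)
        return {k: BinaryMask(g, v) for k, v in self._mask_cache[modality].items()}

    def parameter_map(self, modality: str, param: str) -> ScalarVolume:
        """Piecewise-constant truth map of one tissue parameter on one grid."""
        lab = self.labels(modality)
        cfg = self.config
        order = ("background", "muscle", "tumor", "core")
        lut = np.array([getattr(cfg.tissues[name], param) for name in order])
        vals = lut[lab]
        if param == "fdg_suv":
            # FDG avidity is confined to the FDG-avid ellipsoid: MRI-only tumor
            # tissue shows muscle-like glucose uptake.
            avid = self._mask_cache[modality]["tumor_fdg_avid"]
            outside = (lab >= 2) & ~avid
            vals = np.where(outside, cfg.tissues["muscle"].fdg_suv, vals)
        units = {
            "fdg_suv": "SUV", "fmiso_suv": "SUV", "adc": "mm^2/s", "t1_ms": "ms",
            "t2_ms": "ms", "ktrans": "min^-1", "ve": "fraction", "vp": "fraction",
            "m0": "arbitrary",
        }.get(param, "arbitrary")
        return ScalarVolume(self.grid(modality), vals, units=units)

    def inter_session_transform(self, from_mod: str, to_mod: str) -> RigidTransform:
        """Ground-truth rigid transform mapping one modality's scanner frame to
        another's (translation = offset difference)."""
        t = self.session_offset(to_mod) - self.session_offset(from_mod)
        return RigidTransform(np.eye(3), tuple(t))


def build_phantom(config: PhantomConfig) -> PhantomTruth:
    """Rasterize the configured compartments; deterministic per (config, seed)."""
    return PhantomTruth(config)


def simulate_pet(
    truth: PhantomTruth,
    tracer: str,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = None,
) -> PetStudy:
    """Forward-simulate a PET study: activity = SUV x (dose/weight) + noise.

    Noise is Gaussian with SD = ``noise_sd`` x the local noise-free activity
    (count-statistics-like scaling).  ``noise_sd`` = 0 makes ``compute_suv``
    an exact inverse.
    """
    if tracer not in ("FDG", "FMISO"):
        raise ValueError(f"unknown tracer {tracer!r}")
    cfg = truth.config
    modality = tracer.lower()
    suv = truth.parameter_map(modality, f"{modality}_suv")
    per_kg = cfg.fdg_dose_mbq_per_kg if tracer == "FDG" else cfg.fmiso_dose_mbq_per_kg
    dose_bq = per_kg * 1e6 * cfg.body_weight_kg
    weight_g = cfg.body_weight_kg * 1000.0
    factor = dose_bq / weight_g  # Bq/mL per SUV unit
    activity = suv.values * factor
    if noise_sd is None:
        noise_sd = cfg.pet_noise_frac
    if noise_sd > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        activity = activity + rng.normal(0.0, 1.0, activity.shape) * (noise_sd * np.abs(activity))
    return PetStudy(
        activity=ScalarVolume(suv.grid, activity, units="Bq/mL"),
        injected_dose_bq=dose_bq,
        body_weight_g=weight_g,
        tracer=tracer,
    )


def _spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(flip_deg)
    return m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def simulate_mri(
    truth: PhantomTruth,
    protocol: str,
    seed: Optional[int] = None,
    noise: Optional[float] = None,
):
    """Forward-simulate one MRI protocol from the truth maps.

    ``protocol`` is one of ``dwi``, ``vfa``, ``me_t2``, ``dce``; returns a
    :class:`SignalSeries` (or :class:`DceSeries`).  ``noise`` overrides the
    config noise level (SD in signal units for dwi/vfa/me_t2; fraction of peak
    enhancement for dce); 0 disables noise.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    if protocol == "dwi":
        grid = truth.grid("dwi")
        m0 = truth.parameter_map("dwi", "m0").values
        adc = truth.parameter_map("dwi", "adc").values
        frames, enc = [], DWI_B_VALUES
        sd = (m0.max() / cfg.mri_snr) if noise is None else noise
        for b in enc:
            sig = m0 * np.exp(-b * adc)
            if sd > 0:
                sig = sig + rng.normal(0.0, sd, sig.shape)
            frames.append(ScalarVolume(grid, sig, units="arbitrary"))
        return SignalSeries(frames, enc)

    if protocol == "vfa":
        grid = truth.grid("t1")
        m0 = truth.parameter_map("t1", "m0").values
        t1 = truth.parameter_map("t1", "t1_ms").values
        clean = {a: _spgr_signal(m0, t1, VFA_TR_MS, a) for a in VFA_ANGLES_DEG}
        peak = max(s.max() for s in clean.values())
        sd = (peak / cfg.mri_snr) if noise is None else noise
        frames, enc = [], []
        for a in VFA_ANGLES_DEG:
            for _rep in range(VFA_REPEATS):
                sig = clean[a]
                if sd > 0:
                    sig = sig + rng.normal(0.0, sd, sig.shape)
                frames.append(ScalarVolume(grid, sig, units="arbitrary"))
                enc.append(a)
        return SignalSeries(frames, np.asarray(enc), tr_ms=VFA_TR_MS)

    if protocol == "me_t2":
        grid = truth.grid("t2")
        m0 = truth.parameter_map("t2", "m0").values
        t2 = truth.parameter_map("t2", "t2_ms").values
        sd0 = m0.max()  # echo-1 signal is close to m0
        sd = (sd0 / cfg.mri_snr) if noise is None else noise
        frames = []
        for te in T2_ECHOES_MS:
            sig = m0 * np.exp(-te / t2)
            if sd > 0:
                sig = sig + rng.normal(0.0, sd, sig.shape)
            frames.append(ScalarVolume(grid, sig, units="arbitrary"))
        return SignalSeries(frames, T2_ECHOES_MS)

    if protocol == "dce":
        grid = truth.grid("dce")
        lab = truth.labels("dce")
        times = np.arange(DCE_N_FRAMES) * DCE_DT_S
        arrival = DCE_N_BASELINE * DCE_DT_S
        aif = parker_aif(times, arrival_s=arrival, hematocrit=cfg.hematocrit)
        order = ("background", "muscle", "tumor", "core")
        signal = np.zeros((DCE_N_FRAMES,) + lab.shape)
        for li, name in enumerate(order):
            tis = cfg.tissues[name]
            sel = lab == li
            if not sel.any():
                continue
            curve = extended_tofts_forward(aif, tis.ktrans, tis.ve, tis.vp, times)
            r1 = 1000.0 / tis.t1_ms + cfg.relaxivity * curve  # s^-1
            sig_curve = _spgr_signal(tis.m0, 1000.0 / r1, DCE_TR_MS, DCE_FLIP_DEG)
            signal[:, sel] = sig_curve[:, None]
        frac = cfg.dce_noise_frac if noise is None else noise
        if frac > 0:
            enhancement = signal.max() - signal[:DCE_N_BASELINE].mean()
            signal = signal + rng.normal(0.0, frac * max(enhancement, 1e-12), signal.shape)
        frames = [ScalarVolume(grid, signal[i], units="arbitrary") for i in range(DCE_N_FRAMES)]
        series = SignalSeries(frames, times)
        return DceSeries(series, n_baseline=DCE_N_BASELINE, temporal_resolution_s=DCE_DT_S)

    raise ValueError(f"unknown protocol {protocol!r}")


# --------------------------------------------------------------------------
# Cohort generation: full pipeline per synthetic patient
# --------------------------------------------------------------------------


def _sample_patient_config(rng: np.random.Generator, hypoxic: bool, seed: int) -> PhantomConfig:
    """Draw per-patient tumor geometry and tissue parameters."""
    r = float(np.clip(rng.lognormal(np.log(12.0), 0.3), 8.0, 18.0))
    radii = (r, 0.9 * r, 0.75 * r)
    mri_factor = float(rng.uniform(1.25, 1.4))
    mri_radii = tuple(mri_factor * x for x in radii)
    mri_off = tuple(rng.uniform(-2.5, 2.5, size=3))
    if hypoxic:
        u = float(rng.uniform(0.35, 0.55))
        core = tuple(u * x for x in radii)
    else:
        core = (0.0, 0.0, 0.0)
    tissues = _default_tissues()
    jitter = float(np.exp(rng.normal(0.0, 0.05)))
    for name in ("tumor", "core"):
        t = tissues[name]
        t.adc *= jitter
        t.t1_ms *= jitter
        t.t2_ms *= jitter
    fdg_level = float(rng.lognormal(np.log(9.0), 0.3))
    tissues["tumor"].fdg_suv = fdg_level
    tissues["core"].fdg_suv = fdg_level
    tissues["core"].fmiso_suv = float(rng.uniform(1.6, 2.0))
    tissues["tumor"].fmiso_suv = float(rng.uniform(1.05, 1.15))
    return cohort_config(
        seed=seed,
        tumor_radii_mm=radii,
        mri_tumor_radii_mm=mri_radii,
        mri_tumor_offset_mm=mri_off,
        core_radii_mm=core,
        tissues=tissues,
    )


def simulate_patient(config: PhantomConfig) -> dict:
    """Run the full measurement pipeline on one phantom patient.

    Returns the per-patient record (cohort-table schema) plus subvolume means
    and maxima of every quantitative map for the union-family subvolumes.
    """
    from scipy import ndimage

    from .dce import fit_extended_tofts, signal_to_concentration
    from .pet import compute_suv, muscle_reference, pet_metrics
    from .relaxometry import fit_adc, fit_t1_vfa, fit_t2
    from .subvolumes import build_subvolume_set, extract_report

    truth = build_phantom(config)
    rng = np.random.default_rng(config.seed)
    subseeds = rng.integers(0, 2**31 - 1, size=8)

    fdg = simulate_pet(truth, "FDG", seed=int(subseeds[0]))
    fmiso = simulate_pet(truth, "FMISO", seed=int(subseeds[1]))
    suv_fdg = compute_suv(fdg)
    suv_fmiso = compute_suv(fmiso)

    # Lesion search region: generous dilation of the known avid volume.
    fdg_masks = truth.masks("fdg")
    search = ndimage.binary_dilation(fdg_masks["tumor_fdg_avid"].membership, iterations=3)
    search_roi = BinaryMask(suv_fdg.grid, search)

    fmiso_masks = truth.masks("fmiso")
    muscle_roi = fmiso_masks["muscle"]

    # FDG -> FMISO registration by translation block matching around the tumor.
    reg_roi_arr = ndimage.binary_dilation(
        fmiso_masks["tumor_fdg_avid"].membership, iterations=4
    )
    reg_roi = BinaryMask(suv_fmiso.grid, reg_roi_arr)
    fdg_to_fmiso = estimate_rigid(suv_fdg, suv_fmiso, search_window_mm=6.0, roi=reg_roi)

    mri_tumor = truth.masks("t2")["tumor_mri"]
    mri_to_fmiso = truth.inter_session_transform("t2", "fmiso")

    subvols = build_subvolume_set(
        suv_fdg, suv_fmiso, mri_tumor, muscle_roi, search_roi,
        fdg_to_fmiso=fdg_to_fmiso, mri_to_fmiso=mri_to_fmiso,
    )

    # Quantitative MRI: simulate, fit inside a dilated tumor region.
    def fit_region(modality):
        m = truth.masks(modality)
        region = ndimage.binary_dilation(
            m["tumor_mri"].membership | m["tumor_fdg_avid"].membership, iterations=2
        )
        return BinaryMask(truth.grid(modality), region)

    dwi = simulate_mri(truth, "dwi", seed=int(subseeds[2]))
    adc_map = fit_adc(dwi, fit_region("dwi"))
    vfa = simulate_mri(truth, "vfa", seed=int(subseeds[3]))
    t1_map = fit_t1_vfa(vfa, VFA_TR_MS, fit_region("t1"))
    met2 = simulate_mri(truth, "me_t2", seed=int(subseeds[4]))
    t2_map = fit_t2(met2, fit_region("t2"))

    dce_series = simulate_mri(truth, "dce", seed=int(subseeds[5]))
    t10 = truth.parameter_map("dce", "t1_ms")
    conc = signal_to_concentration(
        dce_series, t10, relaxivity=config.relaxivity,
        tr_ms=DCE_TR_MS, flip_deg=DCE_FLIP_DEG, mask=fit_region("dce"),
    )
    aif = parker_aif(
        dce_series.times_s, arrival_s=DCE_N_BASELINE * DCE_DT_S, hematocrit=config.hematocrit
    )
    pk = fit_extended_tofts(conc, aif, fit_region("dce"))

    maps = {
        "adc": adc_map.parameter, "t1": t1_map.parameter, "t2": t2_map.parameter,
        "ktrans": pk.ktrans, "kep": pk.kep, "ve": pk.ve, "vp": pk.vp,
    }
    valid = {
        "adc": adc_map.valid, "t1": t1_map.valid, "t2": t2_map.valid,
        "ktrans": pk.valid, "kep": pk.valid, "ve": pk.valid, "vp": pk.valid,
    }
    transforms = {
        "adc": truth.inter_session_transform("fmiso", "dwi"),
        "t1": truth.inter_session_transform("fmiso", "t1"),
        "t2": truth.inter_session_transform("fmiso", "t2"),
        **{k: truth.inter_session_transform("fmiso", "dce") for k in ("ktrans", "kep", "ve", "vp")},
    }
    report = extract_report(maps, subvols, valid=valid, transforms=transforms)

    from .pet import segment_mtv

    mtv_mask = segment_mtv(suv_fdg, search_roi)
    fdg_metrics = pet_metrics(suv_fdg, mtv_mask)
    fmiso_suv_max = float(suv_fmiso.values[subvols.tv_union.membership].max())
    vols = subvols.volumes_cm3()
    record = {
        "fdg_suv_max": fdg_metrics.suv_max,
        "mtv_cm3": fdg_metrics.mtv_cm3,
        "tlg": fdg_metrics.tlg,
        "fmiso_suv_max": fmiso_suv_max,
        "hsv_fdg_cm3": vols["hsv_fdg"],
        "hsv_mri_cm3": vols["hsv_mri"],
        "hsv_union_cm3": vols["hsv_union"],
        "mri_volume_cm3": mri_tumor.volume_cm3,
        "tmr": fmiso_suv_max / subvols.muscle_suv_mean,
    }
    return {"record": record, "report": report, "subvolumes": subvols, "truth": truth}


def make_cohort(
    n_patients: int,
    hypoxic_fraction: float,
    seed: int,
    out_dir: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort end-to-end.

    Exactly ``round(n_patients * hypoxic_fraction)`` patients receive a
    non-zero hypoxic core.  Returns ``(records, region_stats)``: the cohort
    metrics table (one row per patient) and a long table of per-patient
    subvolume statistics (mask x map -> mean/max) for the union family.
    If ``out_dir`` is given, per-patient NIfTI volumes and masks are written
    beneath it.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not (0.0 <= hypoxic_fraction <= 1.0):
        raise ValueError("hypoxic_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_hyp = int(round(n_patients * hypoxic_fraction))
    flags = np.zeros(n_patients, dtype=bool)
    flags[rng.permutation(n_patients)[:n_hyp]] = True

    rec_rows, stat_rows = [], []
    for i in range(n_patients):
        pseed = int(rng.integers(0, 2**31 - 1))
        cfg = _sample_patient_config(rng, bool(flags[i]), pseed)
        result = simulate_patient(cfg)
        row = {"patient": i + 1, **result["record"]}
        rec_rows.append(row)
        report = result["report"]
        for mask_name in ("hsv_union", "nsv_union", "tv_union"):
            for map_name, st in report.stats[mask_name].items():
                stat_rows.append(
                    {
                        "patient": i + 1,
                        "mask": mask_name,
                        "map": map_name,
                        "n_voxels": st.n_voxels,
                        "mean": st.mean,
                        "max": st.max,
                    }
                )
        if out_dir is not None:
            _write_patient(out_dir, i + 1, result)
    return pd.DataFrame(rec_rows), pd.DataFrame(stat_rows)


def _write_patient(out_dir: str, patient: int, result: dict) -> None:
    import os

    from .core import write_mask

    pdir = os.path.join(str(out_dir), f"patient_{patient:02d}")
    os.makedirs(pdir, exist_ok=True)
    for name, m in result["subvolumes"].masks().items():
        write_mask(m, os.path.join(pdir, f"{name}.nii.gz"))
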