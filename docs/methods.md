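# Methods

`hypoxmap` implements a multimodal imaging pipeline for characterizing tumor
hypoxia in head-and-neck cancer: FDG PET defines the metabolic tumor volume,
FMISO PET defines hypoxic subvolumes against a contralateral-muscle
reference, an MRI tumor volume enters by Boolean algebra, and quantitative
MRI maps (ADC, T1, T2, extended-Tofts DCE) are compared between hypoxic and
normoxic subvolumes. A digital phantom generates every input, so the whole
chain runs and is tested without clinical data.

## Image model and mask propagation

Volumes live on an `ImageGrid` (shape, strictly positive spacings in mm,
origin, orthonormal direction matrix — exactly the NIfTI affine decomposed).
Voxel indices are 0-based; physical coordinates are voxel centers; masks are
closed voxel sets. Mask propagation between grids uses voxel-center
containment through a rigid transform: a target voxel belongs to the
propagated mask iff its center, mapped into the source frame, falls inside a
member source voxel. Intensities are never resampled — every measurement
reads original voxels of the target series, which avoids interpolation bias
at the cost of a one-voxel-layer uncertainty at mask surfaces (visible in the
tests as surface-layer tolerances).

Registration is translation-only block matching: integer-voxel shifts within
a search window are scored by normalized cross-correlation inside a tumor-
centered ROI; rotations are fixed to identity. This is the minimal bespoke
stand-in for workstation registration: the phantom generates known rigid
offsets, and exhaustive search recovers integer shifts exactly (tested
noise-free and at SNR 20). A user-supplied transform can override the
estimate, standing in for manual correction of registration defects. Full
6-DOF registration is out of scope.

## PET quantities

SUV is body-weight normalized, `SUV = activity[Bq/mL] / (dose[Bq] /
weight[g])`, with the injected dose assumed decay-corrected to scan start.
The metabolic tumor volume (MTV) thresholds at 40 % of SUVmax inside a
search ROI and keeps only the 26-connected component containing the SUVmax
voxel — a single-lesion contract that stops remote hot structures from
inflating the volume. The hypoxic subvolume (HsV) keeps tumor voxels with
FMISO SUV at or above 1.4 x the mean SUV of the contralateral
sternocleidomastoid muscle; it may legitimately be empty. Both thresholds
are closed (`>=`) — the choice is not observable on continuous data and is
configurable. TLG = MTV x SUVmean. The tumor-to-muscle ratio (TMR) is
lesion SUVmax over muscle SUVmean, with lesions classified hypoxic when TMR
is strictly greater than 1.25. SUVpeak uses a 1 mL sphere (EANM style)
approximated by the voxel set whose centers lie within the sphere radius,
averaged over in-volume voxels.

The lesion SUVmax entering the TMR is taken within the supplied tumor mask
(the union tumor volume in the cohort pipeline); which mask was used is part
of the call signature rather than hidden state.

## Quantitative MRI fitting

* **ADC**: mono-exponential `S(b) = S0 exp(-b ADC)` at b = 0/500/1000 s/mm²,
  log-linear least squares. Voxels with any non-positive signal are invalid.
  Bounds (0, 0.01] mm²/s.
* **T2**: `S(TE) = S0 exp(-TE/T2)` over the eight-echo train (5.98–47.84 ms),
  log-linear initialization refined by a damped Gauss–Newton iteration that
  runs vectorized over all masked voxels. Bounds (0, 5000] ms; non-decaying
  voxels hit the bound and are flagged invalid.
* **T1 (VFA/SPGR)**: `S(a) = M0 sin a (1-E1)/(1-E1 cos a)`, `E1 =
  exp(-TR/T1)`, TR 15 ms, angles 3/10/20/30 deg, four signal averages per
  angle (averaged before fitting). DESPOT1 linearization (S/sin a vs
  S/tan a; slope = E1) refined by vectorized Gauss–Newton on (M0, E1).
  Bounds (0, 10000] ms; flip-angle-invariant signals carry no T1 information
  and are invalid. No B1 correction is applied; a per-voxel flip-angle scale
  hook can be added without changing the interface.

Noise-free forward simulation followed by fitting recovers truth to 1e-6
relative or better on every in-mask voxel (the linearizations are exact in
the noise-free limit and Gauss–Newton cannot leave a zero-residual point).

## DCE pharmacokinetics

Signal is converted to concentration by inverting the SPGR steady-state
equation (TR 8.4 ms, flip 25 deg): the pre-contrast baseline average fixes
the effective M0 sin(a) scale per voxel given T10, each frame is solved for
E1(t) and hence R1(t), and `C(t) = (R1(t) - R1(0)) / r1` with relaxivity
r1 = 3.6 mM⁻¹s⁻¹ (gadoterate at 1.5 T; configurable).

The tissue model is extended Tofts — `Ct = vp Cp + Ktrans ∫ Cp(τ)
exp(-kep(t-τ)) dτ`, `kep = Ktrans/ve` — chosen because Vp is a reported
output and standard Tofts has none. The driving plasma curve is the Parker
population AIF divided by (1 - hematocrit), hematocrit 0.42; bolus arrival
is fixed at the end of the five-frame baseline (no per-voxel arrival
search). The convolution integrates the piecewise-linear Cp exactly per
segment (expm1-stable closed forms, recursive accumulation), so forward
curves are deterministic and grid-convergent; a Riemann-sum oracle at 0.1 s
resolution agrees within 0.5 %.

Fitting is deterministic variable projection rather than per-voxel
multi-start optimization: for each kep on a log-spaced grid (0 plus 28
points over 0.02–15 min⁻¹) the model is linear in (Ktrans, vp), solved by
non-negative 2x2 least squares simultaneously for all voxels; the best kep
per voxel is refined by a vectorized golden-section search between its grid
neighbors. This reaches the same bounded least-squares objective as
multi-start NLS but fits whole cohorts in seconds, and it is exactly
reproducible. Validity requires Ktrans, kep >= 0, ve and vp in [0, 1], and
fit RMS below a configurable ceiling; `kep = Ktrans/ve` holds identically on
valid voxels by construction. All-zero curves fit as Ktrans = vp = 0 and are
valid. No claim is made that these values match any vendor permeability
module numerically; the model and AIF are fully specified here instead.

## Subvolume algebra and extraction

All subvolume masks live on the FMISO PET grid. The three tumor volumes are
the propagated MTV, the propagated MRI tumor volume, and their voxelwise
union; each splits into HsV (1.4x-muscle threshold) and the normoxic
complement NsV = TV AND NOT HsV, so `|HsV| + |NsV| = |TV|` exactly.
Similarity indices: Dice `2|A∩B|/(|A|+|B|)`, Jaccard `|A∩B|/|A∪B|`, and
overlap fraction `|A∩B|/min(|A|,|B|)` — the min-denominator convention is
the only one under which a large Dice/overlap gap reads as "the smaller
volume is mostly contained in the larger", which is the intended use here;
intersection-over-A is available for sensitivity checks. Parameter
extraction propagates each mask onto each quantitative map's own grid,
excludes invalid-fit voxels, and reports mean (plus max for T1 and T2, where
regional maxima are the quantities of interest); empty regions report absent
values, never zeros.

## Cohort statistics

Quartiles interpolate linearly at positions 0.25(n-1) and 0.75(n-1) (numpy
default, R type 7); SDs use n-1; a single observation reports SD 0 by
convention. The packaged per-patient metrics table reproduces its printed
summary rows under this convention to printed precision, up to the source
table's own mixed rounding/truncation (documented in the regression test).

Wilcoxon signed-rank: zeros dropped, ties mid-ranked; exact two-sided p by
enumeration of all sign assignments for n <= 15 (half-integer mid-ranks are
doubled so the null distribution is an integer convolution), otherwise a
normal approximation with continuity and tie correction. Wilcoxon rank-sum:
exact null distribution by dynamic-programming enumeration of rank subsets
when min(n) <= 8 and no ties, otherwise normal approximation with tie
correction. Friedman: within-row mid-ranks, tie-corrected chi-square with
k-1 df (cross-checked against scipy). Bonferroni: `min(1, m p)`. Exact
paths are tested against brute-force enumeration oracles for all n <= 8.

Hypoxic-patient grouping uses `hsv_union > 0`; the TMR > 1.25
classification is computed independently and disagreements (possible at
high noise when a normoxic lesion's SUVmax fluctuates above 1.25 x muscle)
are reported, not silently reconciled.

## The phantom: what it emulates and what it does not

The phantom is an ellipsoidal construct in patient coordinates: an FDG-avid
tumor, a larger and slightly offset MRI-visible tumor (so the FDG volume is
only partially contained in the MRI volume, with realistic Dice/overlap
behaviour), an optional concentric hypoxic core, and a contralateral muscle
box in uniform background. Per-session rigid offsets displace the patient
between the FDG and the FMISO/MRI sessions, so the pipeline genuinely
exercises registration and cross-grid mask propagation.

Default tissue values (1.5 T-plausible): muscle T1 1000 / T2 45 ms, ADC
1.5e-3 mm²/s; tumor T1 1200 / T2 90 ms, ADC 1.0e-3, Ktrans 0.15 min⁻¹,
ve 0.30, vp 0.04. The hypoxic core carries the configured effect sizes
relative to normoxic tumor — ADC +30 %, T1 -15 %, T2 -20 % — chosen to make
direction tests decisive at phantom SNR; they are configuration, not claims
about biology. FMISO contrast is core = 1.8 x muscle (above the 1.4
segmentation factor) and normoxic tumor = 1.1 x muscle (below it, and below
the 1.25 TMR cutoff), so presets straddle both decision thresholds.
Perfusion parameters are spatially uniform across tumor-adjacent tissue:
with a configured zero DCE effect, any contrast a subvolume comparison found
could only come from partial-volume rims of coarse-grid masks, so the
phantom removes that confound by construction.

Noise is additive Gaussian everywhere: PET noise scales with local intensity
(count-statistics-like, 5 % default), MRI noise is white at SNR 50 relative
to the protocol's peak signal, DCE noise is 2 % of peak enhancement. A
Rician floor is not modelled — phantom signals stay an order of magnitude
above the noise SD, where the Gaussian approximation is accurate. There is
no point-spread-function blur by default (reconstruction is out of scope),
no anatomical texture, no intra-compartment heterogeneity, and no motion.
Passing tests therefore demonstrate correctness of the measurement chain
under known geometry and noise, not robustness to anatomical variability,
reconstruction artifacts, or delineation error.

Cohort simulation samples per-patient tumor radii (log-normal, clipped to
8–18 mm), an MRI-to-FDG volume factor of 1.25–1.4, hypoxic-core radii at
35–55 % of the tumor's (so HsV/MTV volume ratios land around 4–17 %), and
jitters tissue baselines patient-wise while keeping the core/tumor effect
ratios fixed. Exactly `round(n x hypoxic_fraction)` patients receive a
core. Cohort runs use reduced grids (PET 48x48x32 at 2.7 mm; MRI about
48x48x32 at 2 mm) — the problem size chosen so a 20-cohort direction study
is a routine computation; single-phantom work uses the full acquisition-
table geometry (PET 128³ at 2.7 mm, DWI/DCE 256² in-plane).

## Numerical choices and edge cases

* Threshold comparisons are closed; ties at the exact threshold are members.
* `segment_mtv` never returns an empty mask (it contains the SUVmax voxel);
  `segment_hypoxic` may be empty; empty regions propagate as absent
  statistics.
* Registration tie-breaks prefer the smallest translation (NCC rounded at
  1e-12 before comparison).
* Exact test p-values are two-sided as `2 min(P<=, P>=)`, capped at 1.
* Degenerate fits (flat VFA signal, non-decaying echoes, non-positive T10)
  are flagged invalid rather than clamped silently.
* All simulation outputs are pure functions of (config, seed); sub-seeds are
  drawn from a single generator per patient.

## Known limitations

Single-lesion assumption in MTV segmentation; translation-only
registration; population AIF only (no image-derived AIF); no partial-volume
correction, so subvolume means at PET resolution are diluted by a surface
voxel layer (quantified in the tests); exact statistics limited to the
small-sample regimes stated above; the phantom's geometric simplicity means
cohort-level numbers (volumes, SUVs) emulate the scale, not the
distribution, of clinical cohorts.
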