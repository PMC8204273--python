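# Methods

## Signal model

Each slice in an MS-IR-EPI acquisition is excited by its own 90° pulse once
per TR, at time TI after the non-selective inversion.  Taking the excitation
as a full saturation, the longitudinal magnetization recovers for TR − TI,
is inverted with efficiency e ∈ (0, 1] (M_z → −e·M_z), and recovers again
for TI, giving the steady-state signed signal

    S(TI) = S₀ [1 − (1 + e) e^(−TI/T1) + e e^(−TR/T1)],

which reduces to the familiar two-parameter form
S₀[1 − 2e^(−TI/T1) + e^(−TR/T1)] at e = 1.  Because the saturation resets
the magnetization every TR, this per-TI steady state is exact after a single
TR and is independent of the TI the slice had in the previous volume.  The
model deliberately excludes the EPI readout itself: no T2\* decay across the
echo train, no slice-profile imperfection, no off-resonance distortion.

Fat-suppression (SPIR) pulses — one per excitation slot, 19.2 s⁻¹ for a
96-slot, 5 s protocol — transfer magnetization from the macromolecular pool
and accelerate the apparent relaxation.  This is modelled linearly:

    R1,app(r) = R1,intr(r) · (1 + (b/a) · duty · FA · X(r)),

where FA is the nominal SPIR flip angle, X(r) the relative transmit field
and duty the fraction of excitations preceded by an FS pulse (0.5 for the
alternate-pulse scheme, which halves the MT increment exactly).  Only the
products a·m(r), b·m(r) and the ratio b/a are identifiable; the code never
represents a, b or m(r) separately.  No two-pool Bloch–McConnell dynamics
are simulated — the linearised rate is the model.

## TI scheduling

With n_slots = n_slices / SMS excitation slots per TR, slice s (group
g(s) = s mod n_slots; SMS partners are s ± k·n_slots, evenly distributed
over the volume) occupies slot (g(s) + offset_k) mod n_slots in acquisition
k, so TI[s, k] = TI_min + slot · TR/n_slots.  Slot duration is TR/n_slots —
this, not (TR − TI_min)/n_slots, reproduces an exactly 800 ms spacing for
the 24-slice, TR 3.2 s protocol with offsets {0, 6, 12, 18}.  The default
minimum TI is 44.5 ms (inversion pulse plus spoiler).  Non-equally-spaced
offsets are legal and produce a logged warning, not an error.  For
reduced-TI Monte-Carlo cells the default "respaced" policy uses fractional
offsets n_slots/k so each slice's k TIs stay equally spaced at TR/k; an
integer "subset" policy (first k of the given offsets) is selectable.

## Polarity restoration and fitting

The recovery changes sign at the null, so the complex phase is used to
restore polarity: per voxel, the acquisition with the longest TI (far from
any physiological null) defines the reference phase; a sample is positive
when its principal-value phase difference from the reference is below π/2
in magnitude, and the output is sign × magnitude.  All-zero voxels default
to +1 and are flagged.

The two-parameter fit is a damped Gauss–Newton (Levenberg–Marquardt)
iteration vectorised across voxels, with T1 bounds [1, 20000] ms enforced by
projection, relative tolerance 1e-8, and initialisation from the null-point
rule T1₀ = TI_null/ln 2 and S₀ = max|S|.  Because the sample nearest the
null carries the least reliable sign, each voxel is refit with that single
sample's sign flipped and the lower-residual solution kept (restricted to
voxels whose minimum |S| is within twice the noise floor when one is
supplied).  R² is computed against the mean-signal baseline.  A
dictionary/lookup fit (amplitude profiled out analytically over a T1 grid)
is provided as a fast path; tests cross-check the vectorised optimiser
against scipy's independent curve_fit.

Known property of the chain: the restored values are sign × Rician
magnitude, whose noise floor biases the fitted T1 by up to ~1% at SNR 10
with few TIs.  Monte-Carlo means therefore sit a few standard errors from
the target in the lowest-SNR cells even though the distribution is visually
centred; projecting the complex data onto the reference phase would remove
this bias but would no longer reproduce the modulus-based processing this
toolkit models.

## MT correction

R1 maps acquired across SPIR flip angles are regressed per voxel against
FA·X(r) by ordinary (unweighted) least squares, giving α = a·m, β = b·m and
b/a = β/α; voxels with α ≤ 0 are invalid, and at least two distinct flip
angles are required.  Correction divides: R1,corr = R1 / (1 + b/a·duty·FA·X).
The global variant fits a two-Gaussian mixture (EM, scikit-learn) to the
masked b/a values and uses the mode of the fitted mixture density — for
separated components this is the mode of the highest-peak Gaussian
(weight/σ√2π, not the heaviest weight); for overlapping components it avoids
the split-component artefact of reporting a single component's mean.
Degenerate fits fall back to the histogram mode with a warning.  The
voxel-wise variant smooths the b/a map with a mask-normalised 2 mm FWHM
Gaussian kernel by default (larger kernels bring no further variance
reduction).  When no calibration data exist the global b/a defaults to
0.0045 deg⁻¹, a typical adult-brain value that should be re-measured per
scanner, sequence and cohort.  Without a B1 map, X ≡ 1 with a logged
warning.  The half-rate scheme solves R1_full = R1₀(1 + q),
R1_half = R1₀(1 + q/2) in closed form: R1₀ = 2·R1_half − R1_full,
q = 2(R1_full − R1_half)/R1₀; voxels with R1_half > R1_full violate the
model's monotonicity and are flagged.

## MP2RAGE comparator

Every sequence element maps M_z affinely (M_z → A·M_z + B): inversion with
efficiency e, free recovery over the three inter-block gaps, and each GRE
train in closed form via the geometric sum of the per-excitation gain
cos(FA·X)·e^(−esp/T1).  The periodic steady state is the fixed point of the
composed map; block signals are sin(FA·X)·M_z at the central k-space line.
By default blocks are linear-ordered — the stated TI marks the middle
excitation of the train, as in the standard published MP2RAGE formulation —
with centric ordering (central line first) available as a configuration.
The combination Re(S₁S₂\*)/(|S₁|²+|S₂|²) is bounded in [−0.5, 0.5] and
guarded at zero input.

The combination is not globally invertible: where the two block signals
become equal it touches +0.5 and turns — at ≈535 ms for the 0.7 mm
whole-head protocol (TI 900/2757 ms, 5°/3°, 224 readouts, TR_shot 5 s) —
and it turns again at very long T1.  The lookup table therefore declares
the longest strictly monotonic branch that best overlaps the physiological
range 500–3000 ms ([550, 4845] ms for that protocol on a 5 ms grid) and
maps out-of-branch values to NaN.  B1 correction uses a bank of tables at
21 evenly spaced field levels on [0.5, 1.5] (nearest level per voxel).
Noise is not propagated analytically through the combination; comparisons
use Monte-Carlo.

## Synthetic phantoms

The sphere phantom embeds ten non-overlapping spheres per plate in an empty
background, with the T1-plate endpoints 1998 ms and 89 ms and the T2-plate
endpoints 3025 ms and 293 ms.  The eight intermediate values are synthetic
geometric interpolations (the calibrated intermediate values are not built
in), and the NiCl₂/MnCl₂ concentrations are synthesised from linear
relaxivity models (0.63 and 0.81 s⁻¹mM⁻¹, water R1 0.3 s⁻¹) so that
end-to-end relaxivity regressions have an exact known slope; users can
substitute the true calibration table via RegionSpec lists.  The brain
phantom is deliberately schematic: a GM ellipsoid shell around a WM core
(intrinsic T1 1699/1135 ms, uniform b/a 0.0045 deg⁻¹), a radially varying
transmit field normalised to 1.0 at the grid centre and clipped to
[0.7, 1.3], and a smooth seeded random phase.  Neither phantom models
anatomy, susceptibility, motion, partial volume or spatially varying MT, so
passing tests demonstrate algorithmic correctness and noise behaviour, not
robustness to those real-data effects.

## Evaluation choices

Monte-Carlo runs default to the whole-head conditions: TR 5 s, 96 slots,
target T1 1000 and 1800 ms, SNR 10 and 25 per complex channel (defined as
S₀_ref/σ with S₀_ref the mean amplitude over the support, since the level
is otherwise underspecified), 4/6/8/10 TIs and 1024 draws per cell, with
noise added to the complex signal before polarity restoration.  Scaled runs
use 12 slices chosen to span one 24-slot period of the 4-TI schedule so
across-slice banding is sampled; a run of that size completes in seconds.
The inversion-efficiency bias simulation uses the 8-TI schedule (44.5 ms
minimum, 625 ms spacing) by default and fits the e = 1 model to noiseless
e < 1 signals; under this faithful steady-state model the resulting error
at T1 = 2000 ms is ≈229 ms for e = 0.9 and ≈617 ms for e = 0.7 (any fit
with a free inversion-amplitude term absorbs the efficiency exactly and
returns zero error — the two-parameter mis-specified fit is the interesting
case).  SNR per unit time follows the literal subtraction recipe (ROI mean
over difference-map std, no √2 correction); CoV is the (n−1) sample std
over the mean; histogram peaks use 10 ms bins for T1 (1e-4 deg⁻¹ for b/a)
with FWHM by linear interpolation at half the modal height, floored at one
bin width.

## Numerical and degenerate-input conventions

Fits that do not converge, exceed the T1 bounds, or start from all-zero
data are invalid and carry NaN.  Guarded divisions protect the MP2RAGE
combination (0/0 → 0) and the MT correction (non-positive denominator →
invalid voxel).  Gaussian smoothing converts FWHM to σ per axis in mm and
renormalises over valid voxels so map edges are not pulled toward zero.
All random draws flow through numpy Generators with explicit seeds;
repeated runs are bit-identical.

## Limitations

Inversion efficiency is spatially uniform; B1 maps are consumed, never
estimated; the MP2RAGE k-space ordering of a specific product sequence may
differ from both implemented conventions; the MT model ignores iron and
assumes lipid-dominated relaxation, so the default global b/a does not
transfer to developmental, ageing or pathological cohorts without
re-calibration.
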