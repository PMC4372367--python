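# Methods

## Signal and kinetic model

DSC-MRI measures the T2*-weighted signal drop during the first pass of a
gadolinium bolus. The package uses the standard single-exponential
susceptibility relation

    S(t) = S0 · exp(−TE · k · C(t)),        k := 1 (arbitrary units)

so concentration is recovered as `C(t) = −ln(S(t)/S0)/(TE·k)` with S0 the
mean over a pre-bolus baseline window. The proportionality constant k is
unknowable without a relaxivity calibration and cancels from every
reported quantity (rCBF, rCBV, and calibrated maps), so it is fixed at 1.
Samples with nonpositive signal (noise excursions) are clipped to C = 0
and counted; negative concentrations are kept in the stored volume but
clipped to zero wherever tracer mass is integrated, because the
descriptors and the indicator-dilution integrals assume nonnegative mass.

The baseline window defaults to timepoints 0–7, shortened if the
global-mean signal drops 5% below its running mean earlier (the phantom's
bolus arrives at 12 s = timepoint 8 at TR 1.5 s, so the default holds
there). Peak ties resolve to the earliest timepoint, which favours
arterial-like early peaks and keeps the operation deterministic.

## Tissue forward model (phantom)

Tissue concentration follows indicator dilution,

    C_t(t) = (CBF/6000) · (AIF ∗ R)(t),

with CBF in ml/100 g/min (6000 converts to ml/g/s) and R the residue
function, R(0) = 1, nonincreasing. Ground truth always satisfies the
central volume theorem MTT [s] = 60·CBV/CBF.

On a TR-spaced grid a naively sampled exponential residue carries discrete
mass `dt·Σ exp(−k·dt/MTT) ≈ MTT + dt/2`, which at TR 1.5 s inflates CBV by
10–17% depending on MTT and would leak a spurious MTT-dependent bias into
every ratio. The generator therefore uses a geometric residue
`R[k] = (1 − dt/MTT)^k`, which has exactly unit height, monotone decay and
discrete mass MTT; for MTT ≤ dt it degenerates to a single fractional bin.
A boxcar residue (whole bins plus one fractional bin) is available as an
alternative.

The arterial input is a peak-normalised gamma variate
`amplitude·((t−t0)^α)·e^{−(t−t0)/β}` with t0 = 12 s, α = 3, β = 1.5 s,
amplitude 30 (arbitrary concentration), giving a first-pass FWHM of a few
seconds as in clinical bolus injections; recirculation is a second gamma
variate delayed 24 s, dispersed (β = 3 s) at 30% amplitude — enough mass
that AIF truncation has something real to remove. Bolus arrival and the
injection delay are free parameters of the phantom (no acquisition
protocol pins them); the defaults leave 8 baseline timepoints.

Arterial voxels carry the full undispersed AIF, so they dominate the Cmax
map by construction (tissue peaks are ~30× lower). The MR signal gets
voxel-wise Gaussian noise on the *signal* (not concentration), matching
magnitude MR at moderate SNR; the default σ = 2 on a baseline of 100 is
SNR 50.

## Phantom geometry and cohorts

The default head is a 48×48×12 ellipsoid: a CSF shell, a white-matter
interior, six bilateral subcortical box-shaped structures and two midline
arterial columns. Ground truth is literature-typical: WM 22 / 2.7
(CBF ml/100 g/min, CBV ml/100 g — the internal-standard presets), gray
matter structures 50–60 / 3.9–4.5. A compact 28×28×7 variant with the
same anatomy supports Monte-Carlo cohort studies at tractable cost; the
statistical behaviour under test (rank tests on VOI means) does not depend
on matrix size, only on VOI voxel counts, which stay ≥6 per structure.

Cohorts mirror a matched case-control design: `n_patients` (default 5)
each with `controls_per_patient` (default 3) controls. Patients have
CBF and CBV multiplied by `effect_fraction` (default 0.8) in the effect
regions (default: hippocampus, both sides). Between-subject physiology is
modelled as lognormal jitter on each region's truth values — 6% regional
CV plus a 10% whole-brain scale that cancels from all WM ratios. Without
such jitter every subject would yield identical regional means, all rank
tests would degenerate into ties, and the cohort simulation could not
exhibit the 5% type-I behaviour real cohorts show; 5–10% CV is the range
reported for regional perfusion in healthy adults. Per-subject seeds
derive deterministically from the design seed, so cohorts are bit-for-bit
reproducible.

What the phantom does **not** model: k-space/MR physics, motion, partial
volume, susceptibility artifacts, contrast leakage (no permeability term),
bolus delay/dispersion between artery and tissue, and anatomical
variability (the label map is shared across subjects). Passing tests
therefore demonstrate the correctness and statistical calibration of the
analysis chain, not robustness to those confounds.

## AIF selection

Candidates are ranked by composite score
`rank(−Cmax) + rank(TTP) + rank(fMTT)` (average ranks within the search
mask — the whole parenchyma including vessels, since the analysis has no
anatomical artery prior). Equal weights keep the score scale-free; the
weights are exposed for sensitivity analyses. Ties break toward higher
Cmax and then lexicographic voxel index, making the selection independent
of storage order. The best 20 curves are averaged, smoothed with a
3-point moving average (edge-padded), clipped at zero, and truncated —
set to zero — after the first local minimum following the global peak. A
curve that decays monotonically to the end is kept whole. If fewer than
20 candidates exist the selection degrades to all available with a
warning. A gamma-variate fit would be an alternative truncation rule but
is deliberately not the default: fits on ~60-point curves are unstable and
the local-minimum rule is parameter-free.

## Deconvolution

The convolution matrix is lower-triangular Toeplitz,
`A[i,j] = dt·AIF[i−j]`. Truncated ("standard") SVD zeroes singular values
below `0.2·σ_max` — the classical sSVD threshold — before pseudo-inverting;
block-circulant (delay-insensitive) and Tikhonov variants are out of
scope. CBF is read out as the maximum of `A⁺·C_t` rather than its value
at t = 0, tolerating modest bolus delay. Negative map values are clipped
to zero. CBV is the trapezoidal integral ratio of tissue to AIF.

Raw sSVD at this threshold systematically *under*estimates flow for
sharp-cornered residues (16–19% at MTT 4 s, dt 1–1.5 s on this phantom) —
the familiar price of discarding high-order singular modes. The bias is
nearly uniform across tissue types, so the white-matter calibration
removes almost all of it: calibrated regional CBF errors on the noise-free
phantom are ≤ 4%, CBV ≤ 1%. This is also why all group statistics are run
on ratios, never raw values.

Raising the threshold strictly smooths the deconvolved residue only in the
noise-dominated regime (it removes the modes that amplify noise); on
noise-free curves truncation *adds* ringing relative to the smooth truth.
The oscillation-monotonicity test is accordingly run on a noisy curve.

## Masking

Parenchyma segmentation replaces a full EM tissue classifier with a
two-stage intensity rule on the empirical-CDF (rank) scale: Otsu's
criterion applied to ranks splits background from head, a 3-class Otsu on
the head ranks drops the darkest (CSF-like) class, and the largest
connected component is kept. Working on ranks makes the mask invariant
under any strictly monotone intensity rescaling — the property a
quantile-based rule is chosen for — and is robust to heavily tied
intensity classes, where interpolated quantile thresholds can land inside
a class and split it. The cost is that the rule is designed for volumes
with well-separated intensity classes (which the phantom has); it is not a
substitute for model-based segmentation of real T1 images, whose inputs
are expected to arrive as explicit masks.

The vessel mask thresholds the Cmax map at 3.0 × the median over
parenchymal voxels (strictly greater; the median is the empirical
distribution of the parenchyma-masked histogram, computed per subject,
with the factor configurable). The analysis inclusion mask is
parenchyma AND NOT vessel; an empty inclusion mask is fatal for VOI
statistics and is flagged as such.

## Calibration and VOI extraction

Maps are rescaled so the white-matter VOI mean (WM label ∩ inclusion mask)
equals 22 ml/100 g/min and 2.7 ml/100 g exactly; scale factors are
recorded and double calibration is a state error. rCBF/rCBV divide each
VOI mean by the white-matter reference mean computed on the identical
inclusion-masked basis, so the ratios are independent of calibration
altogether. Left/right comes solely from the label codes — no
radiological/neurological flip logic. A VOI left empty by masking is
reported as missing (with a warning), never as zero.

## Statistics

Group contrasts (patients vs controls, per structure × side × metric) use
the Mann-Whitney U test with `U = Σ [x_i > y_j] + ½[x_i = y_j]`, reported
as min(U, nm−U); side contrasts within patients use the Wilcoxon
signed-rank test with zero differences dropped and counted, W = min(W⁺,
W⁻). For total n ≤ 12 (auto mode), p-values are exact by full enumeration
— every C(n+m, n) labeling, every 2^k sign pattern — which is also valid
under ties; otherwise the tie-corrected normal approximation with
continuity correction is used, and the mode is recorded in every output
row. Tests are two-sided; an all-zero-difference Wilcoxon is reported as
undefined rather than p = 1. Summaries are median and IQR by the
linear-interpolation quantile definition. No multiplicity correction is
applied anywhere; the output carries the comparison count so users can
apply their own.

At the default cohort size (5 vs 15) the auto mode takes the asymptotic
path, whose attainable two-sided level at α = 0.05 is 0.042; the
Monte-Carlo type-I check on 500 null cohorts brackets every region's
rejection rate inside [0.02, 0.10].

## Problem sizes and numerical choices

The validation suite uses the 48×48×12×60 phantom for deterministic
recovery checks (sub-second per study) and the 28×28×7 compact phantom for
Monte-Carlo cohort studies — 500 null replicates for type-I calibration
and 200 replicates per effect level for the power curve, a few minutes
each on one CPU. `scripts/acceptance.py` reports the same quantities at
150/100 replicates, which is ample for its summary rates. SVD threshold
0.2, vessel factor 3.0, AIF n = 20 and the WM presets are all exposed in
`PipelineParams`/configuration but default to the values above. All map
outputs clip negatives at zero; all RNG streams descend from a single
seed via `numpy` SeedSequence spawning, so every artifact of a run is
reproducible byte for byte.

## Known limitations

- rCBF/rCBV here are dimensionless VOI/WM ratios; clinical reports
  sometimes print WM-calibrated absolute values under the same name. Both
  the absolute means and the ratios appear in every VOI row to keep the
  two readings separate.
- The AIF is global (volume-wise); per-slice or local AIFs, partial-volume
  correction, and delay/dispersion correction are not implemented.
- The exact-test enumeration is O(C(n+m,n)) / O(2^k) and is capped at
  total n = 12 in auto mode by design.
- Subcortical segmentation and T1↔PWI coregistration are upstream of this
  package: label maps are consumed aligned, never computed.
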