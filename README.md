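# dscq — quantitative DSC perfusion-MRI analysis with a digital phantom

`dscq` implements a complete bolus-tracking perfusion analysis of the kind
used to look for subtle regional hypoperfusion in neurological disorders
such as transient global amnesia, where nothing is visible to the naked eye
on the perfusion maps and the signal has to be pulled out by VOI-level
group statistics against matched controls.

The pipeline goes from a 4D dynamic susceptibility contrast (DSC) series to
group-level statistics:

1. **Kinetics** — invert the susceptibility signal relation
   `S(t) = S0·exp(−TE·k·C(t))` to concentration curves, and compute the
   per-voxel descriptors Cmax (peak concentration), TTP (time to peak) and
   fMTT (first-moment transit time).
2. **AIF** — select the arterial input function automatically: rank voxels
   by an equal-weight rank sum over (high Cmax, short TTP, short fMTT),
   average the best 20 curves, smooth, and truncate after the first
   post-peak local minimum to remove tracer recirculation.
3. **Deconvolution** — per voxel, solve `C_tissue = CBF·(AIF ∗ R)` by
   truncated-SVD pseudo-inversion of the lower-triangular Toeplitz
   convolution matrix (singular values below 0.2·σ_max zeroed); CBF is the
   peak of the deconvolved flow-scaled residue, CBV the tissue/AIF
   integral ratio (indicator dilution).
4. **Masking** — parenchyma from the anatomical volume (rank-based
   intensity segmentation + largest connected component); vessels as
   voxels with Cmax > 3.0 × the median parenchymal Cmax; analysis mask =
   parenchyma AND NOT vessel.
5. **Calibration & VOI** — rescale maps so normal white matter attains the
   internal-standard presets 22 ml/100 g/min and 2.7 ml/100 g; report
   per-structure, per-hemisphere means and the ratios
   rCBF = CBF̄(VOI)/CBF̄(WM), rCBV analogously.
6. **Statistics** — patient-vs-control Mann-Whitney U tests per
   structure × side × metric, within-patient left-vs-right Wilcoxon
   signed-rank tests, medians with IQR, two-sided at α = 0.05, unadjusted.
   Small samples get exact p-values by full enumeration.

Because no clinical DSC data ship with the package, everything is
validated on a **digital perfusion phantom** with known ground truth: a
gamma-variate first pass plus 30% recirculation, exponential residue
functions obeying the central volume theorem `MTT = 60·CBV/CBF`, six
bilateral subcortical structures (amygdala, hippocampus, thalamus,
putamen, globus pallidus, caudate nucleus) embedded in white matter with
arterial voxels carrying the undispersed input, and matched
patient/control cohorts (default 5 patients, 3 controls each) with a
configurable regional hypoperfusion effect.

## Worked example

```python
from dscq import AcquisitionParams, default_truth_table, generate_study
from dscq.pipeline import quantify_study

study = generate_study(AcquisitionParams(), default_truth_table(),
                       noise_sigma=0.0, seed=1)
result = quantify_study(study)
for m in result.measurements:
    if m.structure == "hippocampus":
        print(f"{m.structure:12s} {m.side:5s} n={m.n_voxels:3d} "
              f"CBF={m.cbf_mean:5.1f}  CBV={m.cbv_mean:4.2f}  "
              f"rCBF={m.rcbf:4.2f}  rCBV={m.rcbv:4.2f}")
```

prints

```
hippocampus  right n= 90 CBF= 53.0  CBV=4.21  rCBF=2.41  rCBV=1.56
hippocampus  left  n= 90 CBF= 53.0  CBV=4.21  rCBF=2.41  rCBV=1.56
```

i.e. on the noise-free phantom the calibrated hippocampal CBF of
53.0 ml/100 g/min sits within 4% of the ground truth (55), CBV within 1%
of 4.2 ml/100 g, and the ratios to the white-matter reference
(22 / 2.7) follow directly.

The same thing from the shell:

```sh
dscq simulate --out cohort/ --seed 1      # 20 synthetic subjects
dscq quantify cohort/patient_00           # maps, masks, AIF, VOI CSV
dscq compare cohort/                      # group + side statistics report
dscq run-all --out results/ --seed 1      # all of the above in memory
```

`dscq compare` writes `group_comparison.csv` and a markdown report of
medians (IQR) and p-values per structure and side, right before left.

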