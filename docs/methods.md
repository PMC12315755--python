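# Methods

`tlfmri` implements a sensory thalamic localizer (TL) analysis for fMRI:
it identifies the auditory (medial geniculate, MGN) and visual (lateral
geniculate, LGN) thalamic relay nuclei of individual participants from a
short clustered-sparse task, and validates the resulting functional ROIs
(fROIs) with resting-state functional connectivity (RSFC). A synthetic
phantom generator provides data with the statistical structure each stage
assumes, so the whole pipeline is testable without scanner data.

## Task design and schedule

A task run is one 12 s fixation trial followed by sixteen 12 s stimulus
trials, 8 auditory and 8 visual, in seeded pseudorandom order. Each trial
is: silent gap, 9 s of stimulation, a second equal gap, then a clustered
acquisition of `n_cluster_vols` (default 3) BOLD volumes. The gap is
calibrated as

    gap = (trial_dur − stim_dur − n_cluster · TR) / 2,

which gives 225 ms per side at TR = 0.85 s (the `nyspi` site preset,
cluster 2.55 s) and 300 ms at TR = 0.80 s (`sbu`, cluster 2.40 s).
Auditory stimulation is modeled at the schedule level as nine 900 ms music
segments each followed by 100 ms silence (9 s total), drawn without
replacement within a trial; waveform handling is limited to normalizing
segments to a common mean absolute amplitude.

The "pseudorandom" order is constrained to at most 3 consecutive
same-type trials (configurable); this is our concretization of an
otherwise underdetermined requirement. The fixation trial is followed by
an acquisition cluster like every other trial, with zero task-regressor
values. The schedule accounts for 17 × 12 s = 204 s of trial time per
run; any scanner lead-in/padding is left to configuration and not encoded
as fact.

## Task GLM

Per run, a 19-column design: intercept, unconvolved auditory and visual
indicators (sparse sampling precludes an HRF model; the indicator is 1 on
all volumes of the cluster following a trial), 6 motion parameters and
their squares, WM and CSF compartment signals, and indicators for the 2nd
and 3rd volume of each cluster that absorb T1-relaxation (non-steady-
state) offsets. Nuisance columns are mean-centred per run (so the
intercept carries baseline — a choice, not given by the source design);
columns that are constant after centring are dropped with a warning.
Ordinary least squares is solved per voxel on smoothed data (4 mm FWHM
Gaussian, σ = FWHM/(2√(2 ln 2)), volume-wise only); runs are fit
independently and the Auditory − Visual contrast is the voxelwise mean of
per-run (β_aud − β_vis). Because the multi-run model is block-diagonal,
this equals a joint fit exactly (verified in tests). Note the first
cluster volume has no indicator, so its T1 offset is absorbed by the
intercept; the contrast is invariant to the offsets.

## Cortical reference clusters

Per hemisphere, the auditory search mask is the BA 41/42 union dilated
once (visual: BA 17/18); the contrast inside the mask is rank-thresholded
to its top (auditory) or bottom (visual) 10% — exactly ⌈0.10·N⌉ voxels,
boundary ties included, which is deterministic under ties unlike
interpolated percentiles. Components smaller than 10 voxels (26-connected)
are discarded and the surviving component containing the greatest
|contrast| peak is kept; peak ties fall to the larger component, then the
lexicographically smallest peak index. Reference series: spatial mean per
hemisphere on smoothed data, then the unweighted mean of the two
hemispheres. Task runs are concatenated in time before series extraction
so each participant has a single AC and VC reference series.

## Thalamic search regions (TSRs)

Segmentation seed labels for MGN are dilated 3 voxels (LGN: 1 voxel;
segmentation LGN priors run larger), then voxels of surrounding
structures are removed: cortical GM, parahippocampal WM and hippocampus
as-is; mediodorsal nucleus, insular WM, choroid plexus, pulvinar, putamen
and pallidum dilated once. The posterior-most two slices *of the TSR
itself* (the two smallest y indices present in the mask) are removed — a
per-mask reading; a global-image reading would usually delete nothing.
Finally MGN-TSR voxels strictly superior to the inferior-most bilateral
pulvinar slice are removed (the boundary slice is retained). All masks
are clipped to the brain. Dilation neighborhoods are 26-connected
package-wide and configurable (6/18/26).

## Coactivation fROI extraction

Within each TSR, each voxel's smoothed task series is partially
correlated with the AC and the VC reference, controlling: WM, CSF, global
gray matter (GM union eroded by one voxel, unsmoothed data), local WM
(WM between 1 and 5 dilations of the TSR, unsmoothed; empty shells fall
back to global WM with a warning), and the cluster-volume-2/3 indicators.
The smoothed/unsmoothed split mirrors the GLM stage: voxel and reference
series come from smoothed data, compartment nuisance from unsmoothed.

Each map is thresholded to its top ⌈f·N⌉ voxels with f = k / (mean TSR
size across hemispheres), k = 32 for MGN and 20 for LGN. These numerators
are deliberately arbitrary tuning constants that produce reasonably sized
fROIs; they are configuration, not science. Voxels surviving in both the
AC and VC map of a TSR are removed from both (modality specificity), and
the largest remaining 26-connected cluster of the modality-appropriate
map is the fROI. Advisory QC flags replace the original manual review:
LGN inferior or medial to MGN (centroid comparison), and |ln(size_L /
size_R)| > ln 3 per nucleus; callers decide about exclusion.

## Resting-state censoring

Volume censoring combines, by union: (1) LPF-FD — each motion parameter
zero-phase low-pass filtered (Butterworth order 2, 0.2 Hz default),
rotations converted to arc length at 50 mm, FD the sum of absolute
backward differences, censored above Φ_F = 0.07587 mm; (2) GEV-DV — DV is
the RMS over brain voxels of the backward difference of low-pass-filtered
voxel series, a generalized extreme value distribution is fit per run and
the threshold set at location + d_G·scale with d_G = 3.105 (fit failure
falls back to median + d_G·IQR with a warning); (3) eye closures longer
than 3 s, plus volumes between two such closures less than 30 s apart
(short blinks never trigger the between rule). After the union, kept
segments shorter than 8 s are discarded (exactly 8 s is kept), runs
retaining under 90 s are invalid, and participants need ≥ 2 valid runs
and ≥ 300 s total. The exact motion low-pass cutoff and the GEV threshold
functional form are defined here explicitly (0.2 Hz; location +
d_G·scale) and are configurable, since the thresholds' upstream
optimization procedure is out of scope.

## Resting-state post-processing and connectivity

Runs are mode-1000 normalized (mode = most frequent nearest-integer
in-brain intensity, smallest wins ties), linearly detrended and centred,
then band-pass filtered 0.009–0.08 Hz (zero-phase Butterworth, order 2)
with censored samples linearly interpolated before filtering and
re-censored after; ⌈22 s / TR⌉ volumes are trimmed from each end (26 at
TR 0.85, 28 at TR 0.80). ROI series are spatial means of unsmoothed
post-processed data. Connectivity per pair (e.g. MGN–AC) is the mean of
the four hemispheric partial correlations (L–L, L–R, R–L, R–R) per run,
averaged over valid runs as raw r (no Fisher transform — a documented
choice, switchable). The nuisance set is: band-passed motion parameters,
their squares, their backward derivatives, the squares of the
derivatives, and the WM and CSF signals with their backward derivatives
(first element of a derivative is 0). Primary AC/VC ROIs for validation
are anatomy-derived: transverse temporal dilated once (AC); pericalcarine
dilated once, restricted to GM, dilated twice more (VC). Selectivity is
tested with one-tailed one-sample t-tests on the four within-participant
differences, Benjamini–Hochberg corrected; ROI-set benchmarking uses
two-tailed paired differences against alternative ROI sets. Seed maps,
and the Dice–Sørensen overlap between fROIs and anatomical ROIs, are
provided as utilities.

## The phantom

The phantom emulates what the analysis assumes, on a 40×48×36 grid of
2 mm voxels:

* **Anatomy.** Ellipsoidal brain; per hemisphere a 20-voxel truth MGN and
  30-voxel truth LGN with the LGN superior and lateral to the MGN (so
  clean geometry carries no QC flag); pulvinar superior/posterior to the
  geniculi; mediodorsal nucleus, putamen, pallidum, insular WM, choroid
  plexus, hippocampus and parahippocampal WM placed adjacent to the
  thalamic neighborhood so the exclusion algebra has work to do; cortical
  parcels (BA 41/42, BA 17/18, transverse temporal, pericalcarine, a
  frontal GM slab), white matter, and CSF. Seed labels are the truth
  nuclei displaced by a 1-voxel jitter emulating segmentation-prior
  error. The LGN jitter always includes a posterior unit component
  (random lateral component): with only a 1-voxel LGN dilation, an
  anterior or purely lateral jitter would let the posterior two-slice
  trim cut truth voxels out of the search region, which no dilation
  choice of the method could recover; the MGN's 3-voxel dilation leaves
  its jitter direction unrestricted. Truth voxels are never labeled WM
  (the WM nuisance signal must stay signal-free).
* **Task runs.** Only the acquisition-cluster volumes exist. Voxel value
  = baseline·(1 + a·c(t) + t1_offset(position)) + drift + ε with
  baseline 1000 (so mode-1000 normalization is a near-identity
  perturbation), a = 2% for structures matching the trial condition
  (truth MGN + auditory cortex labels on auditory clusters; truth LGN +
  visual labels on visual), per-cluster-position offsets (0.05, 0.02, 0)
  of baseline, a low-amplitude shared sinusoidal drift, and white noise
  (SD 5, i.e. 0.5% of baseline — an optimistic but plausible sensory
  effect-to-noise ratio; no effect sizes are reported for geniculate
  task responses, so the amplitude is an exposed placeholder). No
  hemodynamic convolution, matching the unconvolved design.
* **Rest runs.** 458 s at the site TR. Band-limited (0.009–0.08 Hz,
  same Butterworth as the analysis, avoiding filter-attenuation
  confounds) unit-variance latent sources: one shared by the auditory
  cortex labels, one by the visual labels, truth MGN = r·s_AC +
  √(1−r²)·u (default r = 0.4), truth LGN likewise with s_VC, zero latent
  coupling for the cross pairs, an independent source per remaining
  anatomical structure, and WM/CSF/global confound sources mixed into
  all tissue. The unlabeled "brain" filler deliberately has no latent of
  its own: a shared filler source would manufacture connectivity between
  any two ROIs that include filler voxels. White noise on top.
* **Motion and eyes.** Smooth low-pass drift (0.01 mm) plus Poisson
  single-volume displacement spikes of 1 mm, sized so LPF-FD crosses
  Φ_F only in spike neighborhoods; eye-closure events whose duration
  mixture (1–2.5 s and 3.5–8 s) straddles the 3 s rule.

Everything is reproducible bit-for-bit from (config, seed).

### What the phantom does not emulate

No spatial autocorrelation of noise, no hemodynamics, no spin-history or
distortion artifacts, no BOLD consequences of the synthetic motion (the
motion tables are side information only), no surface geometry, and
schematic anatomy. Passing recovery tests therefore shows the pipeline's
mask algebra, estimators and decision rules are implemented correctly and
are self-consistent under the model's own assumptions — not that the
method succeeds on real scanner data.

## Numerical choices

Rank thresholds keep ⌈fraction·N⌉ voxels with boundary ties included
(supersets never drop targets); cluster ties resolve by peak value then
lexicographic peak index; erosion uses the 6-connected cross, dilation
the 26-connected cube, both configurable; compartment erosion stops
before any step that would leave < 2 voxels; FD and DV use backward
differences with first element 0; "superior to" and "longer than" rules
are strict inequalities, the 8 s segment rule keeps exactly 8 s;
correlations are clipped to [−1, 1]; degenerate voxels (zero residual
variance) are excluded from coactivation maps with a warning rather than
failing the participant.

## Verification problem sizes

The recovery suites run 20 phantom participants per condition: the fROI
suite at the full default configuration (4 task runs), and the RSFC suite
with 2 rest runs per participant per coupling level r ∈ {0, 0.2, 0.4,
0.6}, using the implanted truth nuclei as ROIs so that connectivity
estimation is assessed separately from fROI extraction error (which the
fROI suite covers). With 2 runs the 20-participant standard error of a
null pair is ≈ 0.05, well inside the ±0.1 recovery band.

## Known limitations

The GEV-DV threshold on clean synthetic data censors a few percent of
volumes (the DV distribution of white noise is not GEV; the fitted tail
is short) — harmless for estimation but a reminder that d_G was tuned on
real data elsewhere. Multi-site harmonization, permutation inference,
and group voxelwise statistics are out of scope; the connectivity table
carries a site column as the adapter point for external harmonization.
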