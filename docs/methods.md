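# Methods

## Signal model

One cardiac-gated phase-contrast scan yields, per ROI, a velocity waveform
v(t) sampled at N uniform bins over one cardiac cycle (N = 25 or 35 in the
emulated acquisitions), caudal-positive, in cm/s. The decoder models the
scanner's velocity encoding as an affine intensity map

    v = (I − I₀) / s,

with mid-scale zero I₀ = 2048 and scale s = 204.7 intensity units per cm/s,
so that ±VENC (10 cm/s) spans a 12-bit range. I₀ and s are explicit fields
of `PhaseImageSeries`; real acquisitions with different mappings only need
different values. Decoded magnitudes beyond VENC are logged as possible
aliasing but passed through unclipped; the synthetic encoder instead
*refuses* to encode them, because phase wrapping is deliberately out of
scope. ROI membership is pixel-center-strictly-inside-circle with pixel
centers at integer (row, col), 0-based; the ROI reduction is the signed
arithmetic mean over member pixels (signed, not magnitude, averaging — the
cord's rostral excursion must come out negative).

## Synchronization

The anchor is the CSF trigger point: the bin maximizing the circular
forward difference v((t+1) mod N) − v(t) of the **ventral subarachnoid**
waveform — the steepest caudal acceleration. Ties resolve to the smallest
index; a constant waveform has no trigger and yields a degenerate-waveform
warning with index 0.

Order of operations: resample to 50 bins first (periodic linear
interpolation, input sample j at cycle fraction j/N, bin N wrapping to bin
0), then detect the trigger on the resampled ventral waveform, then apply
one common ring shift to all six waveforms so the trigger lands at bin 25.
Detecting after interpolation keeps all sessions on one grid before any
alignment decision; the latency-invariance tests show the result is robust
to the alternative order to within one raw bin. Synchronization is
idempotent and preserves each waveform's value multiset exactly during the
shift.

Resampling to 50 bins cannot be inverted for 35-bin sources; peak values
read off the synchronized grid are attenuated by interpolation by up to
~2% of the peak for the narrow caudal lobe. This is inherent to analysing
on a common grid (the emulated study did the same) and is visible in the
parameter-recovery checks as a small negative bias, well inside 3 standard
errors at n = 200/group.

## Synthetic cohort generator

The generator emulates the statistical structure of the three-group study,
not the MR physics. Defaults are the study conditions:

- **Group sizes** 21 control / 17 preop / 18 postop; patient subject ids are
  shared between preop and postop so paired tests can match scans, and one
  patient carries only a postoperative session.
- **Raw grids**: each session draws N ∈ {25, 35}.
- **Waveform shape**: two raised-cosine lobes with disjoint supports on the
  unit cycle — a sharp caudal lobe (center 0.575, width 0.25) followed by a
  broader rostral return lobe (center 0.83, width 0.26, ending at 0.96 so
  the cycle starts and ends at rest). Each lobe is normalized to unit
  sampled maximum before scaling, so the sampled waveform attains its drawn
  peak amplitudes exactly for any N ≥ 8 — which is what makes zero-noise
  recovery tests exact. The cord uses the mirrored ordering
  (rostral-then-caudal): in patients the cord moves rostrally while CSF and
  tonsils move caudally.
- **Amplitudes**: per-session, per-ROI peak caudal velocities are drawn from
  a moment-matched lognormal at the configured (mean, SD) — peak speeds are
  strictly one-signed, and the lognormal reproduces the requested first two
  moments exactly where a truncated normal would bias the mean (the postop
  tonsil entry, 0.32 ± 0.39 cm/s, would lose ~21% of its mass at zero).
  The cord's rostral peak has its own per-group table (near zero in
  controls, a clear negative excursion in patients). Rostral lobes of the
  other five ROIs are not published quantities; they default to −0.35 × the
  session's caudal peak, a visually plausible return-flow fraction, and are
  labelled non-measured parameters.
- **Latency**: per-session ECG-to-CSF latency ~ truncated normal(0, σ_L)
  with σ_L = 0.08 of a cycle by default, truncated at ±0.20 so the trigger
  stays unambiguous. It is applied as an integer circular roll of the raw
  grid, round(L·N) bins, all six waveforms together; the realized fraction
  round(L·N)/N is recorded as ground truth. Quantizing to whole raw bins
  keeps zero-noise latency-invariance exact on coincident grids.
- **Noise**: i.i.d. Gaussian per bin, default σ = 0.025 cm/s. Rationale:
  per-pixel phase-contrast velocity noise is roughly VENC/SNR ≈ 0.2–0.3
  cm/s at typical SNR, and averaging over the ~75 pixels of a radius-5 ROI
  scales it to the few-hundredths level.

What the generator does **not** emulate: phase wrapping, eddy-current and
Maxwell-term offsets, ROI placement variability, intra-session heart-rate
drift, spatial velocity gradients within an ROI (the image encoder paints
each ROI uniformly), and any biomechanical coupling between ROIs beyond the
shared latency. Passing tests therefore validate the *pipeline arithmetic*
— synchronization, extraction, statistics — under the study's statistical
structure, not the physiology of real scans.

Measurement floors worth knowing: a peak extracted as a max/min over 50
noisy bins is biased away from zero by roughly the noise SD when the true
amplitude is comparable to the noise. The control cord rostral peak
(−0.0087 cm/s configured) sits below that floor at the default noise, so
its recovered group mean reflects the noise floor (~−0.05 cm/s), not the
configured value; the caudal peaks, all ≥ 0.3 cm/s, recover within 3 SE.

## Statistics

- Per-bin group mean with pointwise 95% band: mean ± t(0.975, n−1)·SD/√n,
  n = sessions in the group (band requires n ≥ 2).
- Control vs preop: two-sided pooled-variance Student t (a Welch option
  exists but is not the default, matching the reported method).
- Preop vs postop: two-sided paired t on subject-matched scans; subjects
  lacking a counterpart scan are excluded from pairing.
- Tonsil vs dorsal-SA vs ventral-SA peak caudal velocity (within a group):
  one-way fixed-effects ANOVA plus Tukey HSD (studentized range). The three
  samples come from the same subjects but are treated as independent
  groups, replicating the reported method; a repeated-measures design is a
  documented non-default alternative, not implemented.
- All tests two-sided, alpha = 0.05, no multiple-testing correction across
  table rows (none was applied in the emulated analysis).
- Degenerate inputs are detected by exact value equality (`ptp == 0`), not
  by a variance threshold — the sample SD of identical floats can round to
  ~1e-17 and would otherwise feed a catastrophic cancellation into the t
  statistic. Identical samples give t = 0, p = 1; zero spread with unequal
  means gives p = 0 with a degenerate flag.
- scipy provides the test implementations (`ttest_ind`, `ttest_rel`,
  `f_oneway`, `tukey_hsd`); the test suite checks them against closed-form
  textbook computations to 6 significant digits and checks F = t² for two
  groups.

The summary table reports one row per ROI — with the cord contributing a
rostral-peak and a caudal-peak row — as mean (SD), with control-vs-preop
and preop-vs-postop p-values. The control "syrinx" row is the cord ROI at
the C3/C5 level (the label is configuration, the level is not resolved
here).

## Numerical and design choices

- Midpoint of the 50-bin cycle = index 25 (0-based); `ring_shift` takes any
  integer shift mod 50.
- Dataset JSON is serialized with sorted keys and repr-roundtrip floats, so
  identical datasets are byte-identical; the pipeline's report bundle is
  byte-identical across runs at a fixed seed and config (per-stage timings
  are logged, not embedded in the bundle).
- The deposited-file adapter normalizes ROI/group label aliases and checks
  the sign convention by the dominance of caudal flow in the ventral
  subarachnoid waveform (median over sessions of |min| − max must not be
  positive); if the file is stored caudal-negative it is flipped and the
  flip recorded in provenance. The adapter is exercised against synthetic
  stand-ins only; the real deposit is an external download.
- Problem sizes in the checks: latency-invariance over 40–60 sessions,
  conservation oracles over 1,000 random waveforms, type-I calibration over
  1,000 null cohorts of 20+20 sessions, amplitude recovery at 200
  sessions/group, and the headline analysis at the study's own 21/17/18.

## Known limitations

- Trigger detection has one-bin jitter under measurement noise when the
  caudal upstroke spans several bins; group means at steep-slope bins
  inherit a corresponding small bias (the band-calibration test is placed
  at a rest-phase bin for exactly this reason).
- The ANOVA ignores the within-subject correlation of the three ROI
  samples, by design (method replication).
- No phase unwrapping, no in-plane velocity components, no automatic ROI
  placement.
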