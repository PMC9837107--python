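# Methods

This note records the models, parameter choices and limitations behind
`musedecode`, at the level of detail a user needs to judge what the
package's results do and do not show.

## Synthetic study design

The generator emulates a joint EEG–fMRI music-listening session entirely
from a seed, so every downstream stage can be tested without any
recordings.

**Stimuli.** 36 monophonic piano-like pieces of 40 s at 1000 Hz, four for
each of the 9 valence/arousal classes (low/neutral/high × low/neutral/high;
the affect labels are metadata only — no affective modulation of the signal
is simulated, since the decoder does not use the affect dimension). Each
piece draws a tempo uniformly from 60–180 bpm; notes sit on a metronome
train at that tempo, optionally jittered (default jitter in the pipeline
configuration: 5 % of a beat; the bare generator defaults to an exact
metronome so that onset arithmetic is testable). A note is a sinusoid at a
fundamental drawn from an 8-step log-spaced scale between 2 and 10 Hz under
a 0.4 s exponential-decay envelope. The low fundamentals are deliberate:
after the decoder's 10× downsampling and the identification band-pass
(0.035–4.75 Hz), a stimulus with piano-register fundamentals would retain
only its envelope, whereas this design keeps part of the note content
itself inside the analysed band. The realised mean tempo of the onset train
is stored per piece and used by the tempo-confound analysis.

**Schedule.** 3 runs × 12 trials. Per run: 5 music-only, 5 music-with-
reporting and 2 reporting-only trials in seeded pseudo-random order (the
counts are this package's choice; they give 30 music trials, each of the 36
pieces used at most once, and a ~10 min run). Each trial is preceded by a
uniform 1–3 s fixation and followed by a 0.5 s break; 10 s of rest close
each run so the haemodynamic response of the last trial is observed.
Piece-to-trial assignment is without replacement by default (a `replace`
switch exists because nothing forces uniqueness in general).

**EEG forward simulation.** The four "music-responsive" source locations
(the planted truth) carry `coupling_gain ×` the amplitude envelope of the
concurrently playing piece — low-passed at 8 Hz and lagged 100 ms, the
established envelope-tracking regime of auditory EEG — plus unit-variance
1/f noise; during reporting-only trials and rests they carry noise only.
Twenty further background sources at random grid points add spatially
structured 1/f noise. Sensor data are leadfield projections of all sources
plus white sensor noise. Because the analytic leadfield has a physical gain
scale (~1e-5 potential units per unit dipole moment), `sensor_noise_sd` is
defined **relative to the RMS of the source-driven sensor data**; the
default 0.5 means sensor noise at half the brain-signal RMS. The defaults
(`coupling_gain 5`, `source_noise_sd 1`, `sensor_noise_sd 0.5`, 20
background sources) constitute the strong-coupling / low-noise regime the
end-to-end tests exercise. One 100 ms subtlety: with 2–10 Hz fundamentals
the rectified-and-low-passed envelope itself oscillates at ~4–8 Hz, so the
lag makes the drive nearly *anti*-correlated with the instantaneous
envelope; only a decoder with temporal context (the biLSTM is bidirectional)
can exploit it, which is intended.

**BOLD simulation.** TR 2 s. Voxels inside 15 mm of a planted cluster
centre follow the music boxcar convolved with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s, undershoot ratio 1/6 — the standard canonical
parameters), scaled by `amplitude`, on top of white noise. The voxel lattice uses
the leadfield spacing so that fMRI-selected voxels coincide with EEG source
grid points.

What the generator does **not** emulate: realistic piano timbre, affect-
dependent neural modulation, MR gradient or ballistocardiogram artifacts,
physiological (ocular/muscular) artifacts, non-stationary coupling, and
inter-subject variability. Passing tests therefore show that the pipeline
recovers what it assumes — envelope-coupled sources at fMRI-identified
locations — not that it would decode real recordings at any particular
accuracy.

## Head model

A concentric three-shell sphere replaces subject-specific FEM modelling:
the decoding algorithms only consume a gain matrix, and an imported
leadfield (HDF5 container: `/gain`, `/grid`, spacing, conductivities,
reference) can stand in for any better model. Defaults: radii 80/85/92 mm
(standard adult fits), conductivities 0.33/0.01/0.43 S/m. The five-tissue
published values collapse onto three shells by folding white matter and CSF
into the brain compartment — the analytic solution supports arbitrary shell
counts, but three is the conventional EEG sphere. The potential is a
Legendre series with per-order transfer coefficients obtained from the
interface continuity conditions; 100 terms are kept (the series decays as
`(b/R)^n`; with sources at most 0.87 of the scalp radius, truncation error
is < 1e-8 relative — the tests verify 0.1 % agreement with the closed-form
homogeneous-sphere potential). Dipoles at the exact sphere centre have no
defined tangential field and are dropped from the grid with a notice.
Gains are stored average-referenced (every column sums to zero), and the
source grid is a 15 mm cubic lattice strictly inside the brain shell,
mirroring the 1.5 cm voxel grid of the fMRI side.

## fMRI GLM and dipole selection

Ordinary least squares per voxel with regressors: music boxcar ∗ HRF,
no-music boxcar ∗ HRF, per-run intercept and linear drift. Boxcars are
built on a 0.1 s grid before convolution and sampled at volume times. |T|
is capped at 1e6 for numerically perfect fits; two-sided p-values come from
the Student-t distribution with the residual degrees of freedom.
Family-wise control is Bonferroni by default (a stand-in with the same
contract as random-field FWE, which is out of scope), switchable to
uncorrected thresholds. The greedy selection follows the printed recurrence
exactly: pop the largest-T candidate (ties broken by lowest linear voxel
index, making the output reproducible), accept iff its minimum distance to
the selected set is strictly greater than m = 30 mm, stop at n_l = 4 or
when candidates are exhausted (short sets are logged, not raised). An
exhausted or empty candidate set yields a short or empty `DipoleSet` with a
warning because downstream stages can still run with fewer dipoles.

## SOBI

Classical second-order blind identification: centre, whiten via the
eigendecomposition of the zero-lag covariance (rank-deficient data reduce
the dimension with a warning), then jointly diagonalize the symmetrised
covariances at lags 1..100 samples with Jacobi rotations (closed-form
Givens angle per pair, convergence when the largest rotation angle of a
sweep is below 1e-8, at most 200 sweeps). SOBI is occasionally glossed as
maximising independence of "second order derivatives"; this package takes
the standard reading — second-order *statistics*, i.e. lagged covariances. Components are ordered by variance and
sign-fixed (largest mixing coefficient positive) so the decomposition is a
pure function of the data. Artifact rejection is an explicit index list or
simple heuristics (kurtosis > 10, 50 Hz line-power ratio), never
interactive; the pipeline default rejects nothing, so M = 31 components
feed the 124-row feature matrix.

## eLORETA and features

Free-orientation eLORETA: 3×3 depth-weight blocks iterated to a fixed
point, regularised by `alpha ×` the trace-normalised channel gram times the
average-reference centering matrix H. Defaults: alpha 0.05, tolerance 1e-6,
100 iterations; non-convergence returns the operator with a flag and a
warning rather than failing. The kernel annihilates common-mode channel
offsets (reference invariance) and, at small alpha, attains eLORETA's
zero-localization-error property — verified over every grid truth in the
tests.

Each independent component's back-projection is rank-1, so its source
estimate at a dipole along a fixed orientation is a scalar multiple of the
component time course; features are built that way. The three moment
orientations are reduced to one time course by projecting onto the
**principal orientation of the full reconstructed data**, computed once per
dipole and shared by all components. Sharing the orientation keeps the
construction linear — the per-component blocks sum exactly to the source
estimate of the cleaned data — whereas re-estimating an orientation per
component would break that identity. Features are computed at the full
1000 Hz rate and downsampled afterwards, so the anti-alias filtering acts
on the finished source estimates.

## Decoder

A stacked bidirectional LSTM implemented directly on NumPy arrays with
explicit backpropagation through time, full seeding, and single-thread
bit-reproducibility (the implementation is gradient-checked against central
finite differences to ~1e-7 relative). Gate order (input, forget, cell,
output); forget-gate bias initialised to 1; weights uniform ±1/√H. The
reference architecture is 4 layers × 250 hidden units per direction with a
linear head; the desk preset used throughout the tests is 1 layer × 32
units. Training hyperparameters are this package's choices: Adam at 1e-3, global-norm gradient clipping at 1.0,
sequences chunked into 10 s windows, minibatches of 8 chunks reshuffled
each epoch, 25 epochs (≈ 500 Adam steps per fold at the default study
scale — calibrated on an identifiable linear-readout toy problem).

Features are z-scored per row and targets z-scored with whole-training-fold
statistics. An earlier design normalised targets per run, but per-run
affine maps make the supervision inconsistent across runs of one fold and
measurably destroy held-out generalisation; fold-global statistics avoid
that while still using no test-run information. Cross-validation is
leave-one-run-out over the 3 runs; each trial is reconstructed by the model
that never saw its run. A non-finite training loss aborts the fold with a
diagnostic exception — the analogue of excluding a participant whose data
break training — rather than silently continuing.

Downsampling (both for features and targets) is a zero-phase 8th-order
Butterworth low-pass at 0.4× the target rate followed by decimation;
output length is ⌈N/factor⌉.

## Evaluation

Per-trial measures: Pearson r between the 100 Hz time series; Pearson r
between Welch power spectra (power rather than amplitude spectra;
nperseg = min(256, N)); SSIM between log-power
spectrograms (STFT, 1 s Hann, 50 % overlap, 0–50 Hz, log10 with a 1e-10
floor; each image pair jointly min–max normalised so the dynamic range is
1; K1 = 0.01, K2 = 0.03, 11-bin Gaussian window σ = 1.5, delegated to
scikit-image). Constant series make r undefined; such trials are recorded
as missing and excluded from means with a notice.

Significance of each mean similarity uses a 4000-resample bootstrap that
re-pairs reconstructions with originals by random permutation;
`p = (1 + #{null ≥ observed}) / (n_boot + 1)`, which is never exactly zero.

Identification: both series are z-scored and band-pass filtered
0.035–4.75 Hz with a 4th-order zero-phase Butterworth applied to the
**continuous concatenated** series — a 0.035 Hz high-pass cannot act within
a single 40 s segment — then re-segmented, spectrogrammed, and compared:
`C[k,i] = ssim(R_k, M_i)`. The comparison set for trial k excludes trials
of the same piece (the stricter of the two readings of the trial-exclusion
rule; a `self_only` option implements the other). Rank accuracy gives ties
half credit, which keeps the chance level at exactly 0.5 — the null
calibration test averages 10 000 signal-free similarity matrices and lands
within ±0.005 of 0.5. Significance of the mean rank accuracy is a
permutation test (10 000 re-pairings of the same C matrix), chosen because
it is exact under exchangeability and needs no distributional assumption.

Tempo: onsets are detected as peaks of the rectified envelope derivative
above 25 % of its maximum with a 0.18 s refractory interval; tempo is
60 / median inter-onset interval, the range from the 10–90 % IOI quantiles.
Fewer than three onsets leave the tempo undefined (NaN with a warning).
Typicality is the Gaussian density of a trial's tempo under the
distribution of all trial tempos. Both are correlated with per-trial rank
accuracy (Pearson, two-sided p).

## Study-scale choices

The default study (36 trials × 40 s, 3 runs, 31 channels at 1000 Hz, 15 mm
grids, desk decoder) runs end-to-end in roughly ten minutes on one CPU
core; the unit-test fixtures use coarser 30 mm grids and seconds-long
signals. The reference 4×250 decoder preset is provided (`reference_spec`,
`--spec reference`) but is not exercised by the default test run.

## Known limitations

- The raw-spectrogram SSIM similarity is an insensitive measure under this
  generator: the envelope-coupling model makes reconstructions band-limited
  below ~8 Hz, so most of the 0–50 Hz spectrogram image compares
  pairing-invariant noise floors, and the bootstrap on the SSIM mean
  typically does not reach significance even when time-domain and
  frequency-domain correlations and rank-accuracy identification are
  decisively significant. Identification (which band-passes before
  comparing) is the measure this study design can support.
- The spherical head model ignores head-shape and tissue anisotropy; the
  HDF5 import path exists precisely so a better leadfield can be swapped in.
- Bonferroni is conservative relative to random-field FWE; selection
  thresholds are configurable per analysis.
- The greedy selection operates on voxel p-values, not cluster extent;
  cluster-level inference is out of scope.
- Seeded bit-reproducibility is guaranteed on a single CPU thread;
  multi-threaded BLAS reductions may differ in the last bits.
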