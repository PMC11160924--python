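# Methods

This note documents the models and procedures implemented in `stimmap`, the
design choices made where the design was genuinely open, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Signal model of a stimulation-evoked session

A session is continuous multichannel voltage at 1000 Hz with a train of
~42 biphasic pulses per stimulated bipolar pair at 2 s intervals. The
synthetic generator (`stimmap.synthdata`) builds each subject as:

* **Background** — independent 1/f Gaussian noise per contact (spectral
  shaping of white noise; default SD 5 µV). Real sEEG additionally has
  shared physiological rhythms, inter-channel correlation and
  non-stationarity; none of these are emulated, so passing tests show that
  the pipeline's operations are correct, not that its thresholds are
  clinically tuned.
* **Stimulation artifact** — a deterministic damped 300 Hz transient
  strictly confined to [0, 8) ms after every pulse, added to all contacts
  scaled by 1/(1 + distance-to-stimulation-midpoint in mm). Being identical
  across trials it survives averaging, which is what the artifact-only
  exclusion rule and the non-activated template subtraction must handle.
* **F1 — fast phase-locked response** (default 20 µV × gain U(0.8, 1.2),
  onset U(15, 45) ms): a gamma Gabor atom (carrier U(55, 75) Hz, envelope
  SD 8 ms) riding on an N1-like slow deflection (alpha function, τ = 15 ms,
  same amplitude), with fixed per-trial phase. Evoked potentials are
  multi-component waveforms; an isolated narrowband atom is not a realistic
  fast response and, with only ~10 informative cells out of 720 on the
  down-sampled feature grid, it is also nearly invisible to manifold
  learning after rank-based quantile transformation.
* **F2 — non-phase-locked theta–alpha burst** (default 15 µV, carrier
  U(7, 10) Hz, envelope SD 30 ms, onset U(90, 150) ms, per-trial onset
  jitter N(0, 40 ms) with the carrier phase tied to the jittered onset).
  With 40 ms jitter the phase SD at 8 Hz is ≈ 2 rad, so the raw ITPC of an
  F2 burst is indistinguishable from the n-trial chance level
  √π/(2√n) ≈ 0.14 at n = 40 while trial-averaged *power* survives the
  smearing — the property that separates F2 from F1/F3 throughout.
* **F3 — delayed phase-locked oscillation** (default 15 µV, frequency
  U(4.5, 5.5) Hz, ≥ 2 cycles, onset U(240, 285) ms drawn once per
  stimulated pair and planted identically on all of that pair's targets,
  including contralateral ones): a damped oscillation (20 ms raised-cosine
  attack, 120 ms exponential ring-down). Evoked rhythms decay; the decay is
  also what gives the oscillation an identifiable onset — a symmetric or
  rectangular burst puts its power-envelope peak at the burst midpoint
  (≥ 400 ms after onset), outside every admissible decoding window.
* **Montage** — four 8-contact shafts at 4 mm pitch: hippocampal-L (two
  mid-shaft contacts flagged white matter), MTG-R, LFC-R, and a thalamic-L
  shaft split antTH(3)/midTH(2)/pstTH(3). Four pairs are stimulated (two
  cortical, two thalamic). One contact carries ×6 amplitude inflation (the
  "pathological channel" surrogate), one carries 200 planted >80 µV jumps,
  and three (channel, trial) combinations carry a 200 µV box transient.
* **Connectivity** — each ordered (stimulating pair, plantable recording
  pair) is a connection with probability 0.2. Feature composition:
  P(F1) = 0.9; P(F2) = 0.7; P(F3) = 0.8 for thalamic stimulation and 0.05
  otherwise (delayed oscillations are a thalamic-outflow signature; slow
  power responses follow the same paths as fast ones). A connection with no
  feature is forced to F2.

Bipolar leakage is physical, not simulated noise: a waveform planted on
contact *a* appears sign-flipped in the neighbouring derivation sharing
*a*. Ground-truth scoring therefore excludes contact-sharing neighbours of
planted pairs from both the sensitivity and the false-positive sets.

## Preprocessing

Zero-phase IIR notches (Q = 30) at 60/120/180 Hz. Channel QC flags
amplitude SD > 5 SD of the cross-channel distribution or consecutive-sample
jumps > 80 µV with a count above max(3 × median, 5); the statistics ignore
±20 ms around each pulse so the artifact itself does not register, and the
floor handles the realistic case of a zero median count. Note that with n
channels a single outlier can reach at most (n−1)/√n cross-channel SDs, so
the amplitude rule needs montages of roughly 30+ channels to fire at the
5 SD cutoff. Trial QC removes trials whose mean |v| exceeds 4 SD or whose
variance exceeds 3.5 SD of the across-trial distributions, computed on the
full −500…1000 ms epoch. Exclusion rules run per stimulating pair over all
adjacent-contact bipolar derivations: both-contacts-white-matter,
cross-region, midpoint ≤ 5 mm, artifact-only responders (|z| ≥ 7 inside
0–10 ms and never in 10–800 ms), and pairs containing a rejected channel;
every pair lands exactly once in the retained set or the exclusion log.
The baseline window is −300…−50 ms (clear of filter edges and the pulse
lead-in); evoked potentials are z-scored against that window's mean/SD of
the trial-averaged trace.

## Spectral features

The Morlet bank (59 log-spaced frequencies 1–256 Hz, 5 cycles, L2-normalised
zero-mean atoms) is applied by shared-FFT linear convolution on epochs
padded by ±1 s; the bank is verified cell-for-cell against MNE-Python's
implementation wherever MNE's wavelet fits the signal. Frequencies whose
5-cycle atom outlasts the epoch (< ~3.3 Hz) are flagged edge-dominated.
Power at 1000 Hz is decimated to 200 samples/s by averaging non-overlapping
5-sample blocks; phase is taken at block centres (block-averaging phasors
would mix phase and amplitude). The batched pipeline path runs the bank in
single precision (~1e-6 relative error); tests of numerical identity use
double.

Feature vectors average spectrogram cells over 60 time kernels
(5/25/20/10 points over [−30, 10], [11, 117], [118, 283], [284, 800] ms) ×
6 bands (δ [0.5, 5], θ [5, 8], α [8, 15], β [15, 30], γ [30, 70], high
> 70 Hz), power and ITPC halves concatenated (720 features). On the 200 Hz
grid a few of the 25 kernels spanning [11, 117] ms contain no sample; those
entries are NaN by construction and are mean-imputed (or dropped when empty
everywhere) during training preparation — this is the pipeline's natural
source of missing data.

## Activation detection

The three preliminary criteria and the plausibility gate are implemented as
stated in the pipeline summary (README). Choices that were open:

* the phase-locking connectivity index is the maximum over 10–600 ms of the
  frequency-averaged raw ITPC (simplest per-pair scalar; exposed as a
  plug-in);
* peak detection uses local extrema of both signs with minimum prominence
  0.5 z;
* the plausibility gate takes a monotone ≥ 10 ms climb into a local peak at
  10–60 ms (early clause) OR a post-250 ms peak with |z| > 5 (late clause),
  AND mean |z| < 2 after 800 ms.

The semi-supervised UMAP uses the stated parameters (2-D, neighbourhood 5,
min-dist 0.01, fixed recorded seed) with the preliminary labels as targets
(−1 = unlabeled). Density clusters come from HDBSCAN on the embedding.
Cluster labelling is by *enrichment*: a cluster is the activation cluster
when its labeled members contain a higher fraction of 1s than the
subject-wide labeled-1 rate. A plain majority vote fails structurally here:
the phase-locking criterion admits only the top 5% of pairs, so label-1
instances are rare and even a perfectly formed activation cluster contains
more labeled 0s than 1s. Instances labeled by the consensus keep their
labels; only −1 instances inherit their cluster's label, and unclustered
−1 points are outliers. Subjects whose clusters cannot be told apart are
flagged failed and excluded — the deterministic replacement for the manual
cluster verification a human rater would do.

## Group-level encoding and decoding

Non-activated templates (cell-wise means over a stimulation channel's
non-activated pairs; ≥ 10 required) are subtracted from all of that
channel's spectrograms before group analysis. The cluster-based permutation
test uses within-subject one-sample t-maps, 4-connected suprathreshold
clusters of mass = Σt, and a sign-flip null of the maximum cluster mass
(exhaustive enumeration when 2^n ≤ the permutation budget, so small-n
p-values are exact); a paired test is the same machinery on within-subject
difference maps. With fewer than 10 maps the test still runs but is flagged
contact-level. Thresholds follow the stated defaults (|t| > 6 two-sided or
t > 6 one-sided, 5000 permutations, P_cluster < 0.01).

Templates are cut at fixed windows ([10, 50] COR-ipsi, [70, 160] COR-contr,
[165, 280] ms THAL-contr) from the denoised category means and jointly
z-transformed. Sliding correlation computes Pearson r between the
vectorised template (power + ITPC) and the instance patch at every 5 ms
placement; r(t) is indexed at the **window centre** — with start indexing an
instance identical to the template peaks at the window's left edge
(165 ms for F3), below the stated F3 admissible range (200, 400) ms, i.e.
the stated constants are only mutually consistent under centre indexing.
Placements over constant patches give r = 0; windows reaching past the
epoch end are not computed. r\* is the highest local peak in the admissible
range (earliest wins on ties); without a local peak in range the feature is
absent and the range maximum is recorded.

## Statistics

Model comparisons fit null and alternative mixed models by ML (REML
likelihoods are not comparable across fixed-effect structures) with a
subject random intercept and variance components for the nested levels;
the LRT degrees of freedom equal the added fixed-effect columns. AIC/BIC
are computed from the log-likelihood with all estimated parameters counted.
Estimation failures trigger a deterministic downgrade ladder
(site → region → subject → OLS), flagged in the result. FDR correction is
Benjamini–Hochberg. Cohort summaries use sample SDs and round half away
from zero to printed precision.

## Problem sizes used by the test suite

Parameter recovery runs one 12-subject cohort at the defaults above
(~970 instances); determinism compares two full 2-subject runs byte for
byte; mixed-model calibration uses 15 subjects × 20 sites for effect
recovery and 200 replicates of 10 × 10 for the null rejection rate; the
permutation error-control simulation uses 500 null datasets of 12 subjects
on 20 × 30 grids with 1000 permutations each.

## Known limitations

* **Per-instance F3 latency is weakly identified.** The decoder is
  self-referential (the template is the cohort mean), so the expected
  decoded latency is pinned to the template window's position, with spread
  equal to each instance's onset minus the cohort mean onset — inside the
  (200, 400) ms admissible range that leaves only ~±22 ms of usable onset
  variation. Meanwhile a 5-cycle Morlet at 5 Hz has σ_t ≈ 160 ms, so
  windowed correlation cannot localise a theta-band event to better than a
  few tens of ms per instance at realistic SNR. Group-level latency
  contrasts average this noise away; instance-level rank correlation with
  planted onsets saturates around 0.4–0.6, and the corresponding recovery
  test documents (and currently fails) the stricter bound it states. F1
  latencies, by contrast, track planted onsets to ~3 ms median error —
  gamma wavelets are short and the F1 window matches its blob size.
* The hold-out generalisation check needs ≥ 20 activated instances per
  anatomical category; small cohorts skip it (reported in the summary).
* The amplitude bad-channel rule cannot fire on very small montages (see
  Preprocessing); the generator's pathological-channel surrogate is
  therefore also spiky so the QC path stays exercised.
* Quantile transformation is rank-based and discards magnitude separation;
  with sparse single-feature responses this measurably weakens the
  embedding (the motivation for the multi-component F1 waveform above).
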