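# Methods

`paramwm` re-implements, end to end, a working-memory decoding analysis for
*parametric* memoranda: the numerosity of a tactile pulse train held in mind
across a 12 s delay. The pipeline comprises (1) the stimulus/protocol
generator, (2) a synthetic 4D BOLD simulator with planted ground truth,
(3) time-resolved FIR first-level models with aCompCor nuisance regression,
(4) whole-brain searchlight support-vector-regression (SVR) decoding,
(5) a rank-distance label-permutation control, and (6) permutation-based
group cluster inference, plus a univariate parametric control model. All
stages run on simulated data, so every claim the test suite makes is
checked against known ground truth.

## Stimuli and task

A stimulus is a train of 7, 9, 11 or 13 electric pulses distributed over a
60 ms onset grid spanning 960, 1020, 1080 or 1140 ms — 17, 18, 19 or 20
onset slots (fencepost count: onsets at 0, 60, …, duration). The first and
last slot always carry a pulse; the remaining pulses are placed uniformly
at random without replacement over the interior slots. Varying duration and
randomizing pulse placement decouples numerosity from stimulus length and
mean pulse rate; `spectral_profile` reports the amplitude spectra used to
check that numerosity groups share similar frequency content (a report,
not a gate — no quantitative criterion is defined for "similar").

A delayed match-to-numerosity trial presents two samples with different
numerosities, a retro-cue with a simultaneous 20-pulse mask, a retention
period, then two test stimuli for a two-alternative forced choice. The
match shares the cued numerosity but never the cued sample's duration; the
foil numerosity is the target ±3 pulses, with 7−3 mapped to 5 to stay above
the tactile subitizing range. A run holds every ordered (cued, uncued) pair
of the four numerosities exactly four times: 48 trials.

Timing is TR-locked (TR = 2 s): samples at 0 and 2 s, cue+mask at 4 s,
tests at 16 and 18 s, response window from 20 s; the cue-to-test retention
interval is exactly 12 s and covers time bins 3–8 of the 10-bin (20 s)
trial model. The nominal trial length is 21 s with inter-trial intervals of
1.5 or 3.5 s (half each); the next trial onset is snapped down to the TR
grid (effective onset-to-onset spacing 22 or 24 s), because the stated ITIs
and TR-locking cannot both hold exactly — we keep the TR-locking invariant
and record the nominal ITI in the events table.

Trial sequencing uses blocks of four trials whose (cued, uncued) pairs form
a fixed-point-free pairing of the numerosity set; the three such
double-transpositions partition all 12 ordered pairs and are each used in
four blocks. Consequently *any* prefix of whole blocks is balanced over
both cued and uncued conditions — this is what allows scaled-down
simulations to truncate a run without losing a condition in either the
main or the nonmemorized-label model. Duration assignment rotates each
numerosity through short (960/1020 ms) and long (1080/1140 ms) grids
across runs (Latin-square style), alternating short/long over a
numerosity's presentations within a run.

The number-naming battery generates numerosities 1–15, five
duration/placement combinations each (75 stimuli); numerosities 1–2 relax
the two-endpoint rule where it cannot apply.

## BOLD simulation and ground truth

Defaults (the "study conditions" of all tests): 24 × 24 × 15 voxel grid at
3 mm, TR 2 s, 120 volumes/run, 4 runs, 8 subjects. The full-scale
acquisition (64 × 64 × 37, 565 volumes) is reachable through `SimConfig`.
With 120 volumes, the 48-trial schedule truncates to the ~10 leading trials
whose 20 s model span fits the run (2–3 trials per condition per run).

The planted code: a ball-shaped ROI (radius 3 voxels) at the grid center
carries per-voxel weights drawn i.i.d. normal, mean-centered over the ROI
and scaled to unit RMS. During each trial's retention period (a 12 s boxcar
convolved with the canonical double-gamma HRF — peak 6 s, undershoot 16 s,
ratio 1/6, samples normalized to unit sum so a sustained boxcar plateaus at
~1), every ROI voxel adds `weight × amplitude(numerosity)`, with
`amplitude(n) = snr · noise_sd · (n − 10)/6` — affine in numerosity, so the
extreme memoranda differ by `snr` noise-standard-deviations per voxel.
Because the weights sum to zero, the ROI-mean signal is identically zero:
the code is multivariate by construction and invisible to a mean-activation
analysis. Default `snr = 2`; the pipeline's ROI-recovery behavior is
reliable for `snr ≳ 1` under the default geometry and degrades gracefully
below (the SNR-monotonicity test covers {0, 0.5, 2}).

Noise model: baseline 100, one slow cosine drift per voxel (random phase,
period 1–2 run lengths), stationary AR(1) noise (ρ = 0.3, SD 1), three
smooth latent nuisance time courses loading on CSF and white-matter blocks
(and leaking weakly, 0.05, into the brain), and six-parameter random-walk
motion coupled into the data at amplitude 0.2. The simulator does not model
field distortions, spin-history effects, multiband artifacts or
physiological cycles; passing tests therefore demonstrate correctness of
the analysis machinery under a plausible noise model, not robustness to
every artifact of real acquisitions.

Between-subject pattern consistency defaults to 0: each subject draws
independent ROI weights (shared geometry). Fine-scale multivariate codes
are subject-idiosyncratic — that is the standard argument for aggregating
searchlight *accuracy maps* across subjects rather than averaging patterns.
Decoding accuracy is computed within subject, so group-level sensitivity
does not require between-subject pattern alignment; `consistency` is a knob
for users who want aligned patterns. An optional transient
encoding-phase response exists (off by default) for probing
perception-versus-memory dissociations; no fidelity claim attaches to it.

## First-level models

The FIR model assigns one regressor per condition and 2 s time bin, bin 1
aligned to trial onset, 10 bins spanning the 20 s modeled trial (40 task
columns/run). Overlapping trials superpose. Nuisance columns per run: the
top five principal components of the demeaned CSF and white-matter voxel
time courses (aCompCor; computed per run on unfiltered signals), six
motion parameters, and the SPM-convention discrete-cosine high-pass basis
(K = ⌊2·N·TR/cutoff⌋ cosines, cutoff 128 s) — implemented as design
columns, which is equivalent to pre-filtering for OLS and easier to test.
Estimation is voxelwise OLS (no prewhitening); the AR(1) content of the
simulations lets the acceptance suite confirm empirically that inference
stays calibrated under the autocorrelation actually present. Rank
deficiency is rejected with the offending columns named. The
`label_source` switch relabels trials by the nonmemorized sample's
numerosity to build the perceptual-residue control model.

The univariate control replaces the FIR set with 10 HRF-convolved
regressors: a delay-period boxcar, the same boxcar parametrically modulated
by the memorized numerosity (mean-centered per run; the effect of
interest), and boxcar + modulator pairs for each sample and test stimulus.
If all trials share one numerosity the modulator is identically zero; the
model flags this and drops the column rather than fitting a singular
design.

## Searchlight SVR decoding

For each center voxel, all in-mask voxels within a Euclidean radius of 4
voxels (257 offsets on the full lattice; truncated at mask borders, centers
with fewer than 10 sphere voxels skipped) contribute pattern vectors: 16
per time bin (4 conditions × 4 runs). Leave-one-run-out cross-validation:
per fold, patterns are z-scaled per voxel using training-fold statistics
only (a `pooled_scaling` switch reproduces pooled scaling; train-only is
the default to exclude even nominal leakage), a linear epsilon-SVR
(C = 1, ε = 0.1 — ε is unstated upstream and 0.1 is the solver-family
default; both exposed in `DecoderConfig`) is fit on the 12 training
vectors, and the fold score is the Fisher z (atanh) of the Pearson
correlation between the predicted and true numerosities of the 4 held-out
vectors, capped at atanh(1 − 1e−15). Zero-variance predictions score the
fold 0, so degenerate searchlights cannot produce extreme accuracies. The
mean over the four folds is assigned to the center; each time bin is
decoded independently, and the delay summary is the voxelwise mean over
bins 3–8.

The hot path calls scikit-learn's low-level libsvm binding directly (same
solver as `sklearn.svm.SVR`, verified identical in tests, ~16× less call
overhead); the `SVR` estimator remains as fallback. An independent
brute-force QP solver for the epsilon-SVR dual (SLSQP plus an active-set
KKT polish) lives in the test suite and pins the production path to 1e-6.

Correlation-based accuracy is invariant to the bias term and to the sign
convention pairing (an ordering and its reversal yield identical
accuracy) — the reason the permutation control needs only 12 of the 24
label orderings.

## Label-permutation control

Numerosities map to ranks 1–4 by ascending value; an ordering's distance
from the correct linear order is the sum of absolute adjacent-rank
differences, ranging 3 (correct/reversed) to 7. Reversal pairs share a
distance (and, by the correlation symmetry above, an accuracy), leaving 12
representatives in five classes of sizes {1, 2, 6, 2, 1} at distances
{3, 4, 5, 6, 7}. Each representative relabels the conditions' regression
targets and the full LORO SVR is re-run at designated peak-voxel
searchlights, averaging over delay bins. On planted-linear data the
per-class mean accuracy decreases with distance; the suite tests this with
a one-sided Spearman trend over seeds, an addition of this package (the
original analysis presents the profile descriptively).

## Group inference

Subject delay-mean maps are smoothed at 8 mm FWHM (Gaussian,
σ = FWHM/(2√(2 ln 2)) per axis, mask-aware renormalization so borders do
not dim) and tested voxelwise against 0 — the chance level of Fisher-z
accuracy — with a one-sample t. This collapses the original two-factor
(subject × time bin) ANOVA to its reported contrast: the t-test on the
delay-bin mean. Cluster-level FWE control replaces parametric random-field
theory with sign-flip permutation: threshold at the one-sided t-quantile of
the cluster-defining p (0.001), form 26-connected clusters, and refer each
observed cluster's extent to the permutation distribution of the maximum
cluster size under random sign-flips of the subject maps (valid because
chance-level accuracy maps are sign-symmetric; cluster mass is a one-line
variant). Corrected p uses the add-one rank estimator. An
uncorrected-reporting mode keeps all supra-threshold clusters for
exploratory use.

## Validation design and problem sizes

All validation runs use scaled-down geometries chosen so the full suite
runs on a single CPU in minutes: parameter recovery uses 20 single-subject
replicates of the default 24 × 24 × 15 / 120-volume configuration
(peak-in-ROI assessed on the 8 mm-smoothed subject delay map — smoothing
precedes inference in the pipeline, and the unsmoothed argmax is degenerate
because every center within one searchlight radius of the ROI sees most ROI
voxels); chance calibration uses 20 replicates at snr = 0 (whole-map mean
within 2 SE of 0 — note the spatially shared component of accuracy noise
makes single-map means swing ±0.1, so the replicate count matters);
permutation monotonicity pools 20 seeds at 16 × 16 × 15; the group-level
dissociation and nonmemorized-label controls share one 6-subject cohort at
16 × 16 × 15 with 500 sign-flips; FWE calibration runs 100 null cohorts of
8 smoothed-noise maps each at 12 × 12 × 10 with 500 sign-flips.

## Known limitations and open choices

- OLS without prewhitening slightly misweights autocorrelated noise; the
  calibration tests show the downstream inference tolerates the simulated
  AR(1) level, which is not a guarantee for arbitrary real noise spectra.
- The simulator's nuisance/motion model is generic; aCompCor recovers the
  planted latents well here precisely because the compartment masks are
  exact, which flatters nuisance regression relative to real tissue masks.
- Whether the original univariate-null finding depends on between-subject
  pattern alignment cannot be probed from published values; the default
  consistency = 0 setting encodes the standard assumption and the knob
  allows the alternative.
- Sphere-truncation at mask borders keeps centers with ≥ 10 voxels; the
  threshold is exposed and maps report skipped centers as NaN.
- The 24-pairing sentence in the stimulus description (4 numerosities × 2
  durations × 3 uncued) does not factor into the 48-trial run composition;
  the 12-ordered-pairs × 4 reading is enforced, the other is not.
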