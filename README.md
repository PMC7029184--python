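# paramwm

Searchlight SVR decoding of parametric working-memory content, with a
fully synthetic, ground-truth-bearing test bed.

## The problem

How does the brain hold an *analog* quantity — here, the approximate
numerosity of a tactile pulse train (7, 9, 11 or 13 pulses) — in working
memory across a delay? A delayed match-to-numerosity task presents two
pulse-train samples, retro-cues one of them, imposes a 12 s retention
period, and asks which of two test trains matches the memorized
numerosity. Stimulus durations and pulse placements are randomized so that
neither stimulus length nor mean pulse rate predicts the answer; the foil
differs by ±3 pulses (7−3 is mapped to 5 to stay above the subitizing
range).

The analysis question is whether the delay-period BOLD pattern encodes the
memorized numerosity *as a linear continuum*. The pipeline answers it
with:

- **FIR first-level models** — one regressor per memorized numerosity and
  2 s time bin (4 × 10 per run), with aCompCor (5 CSF + 5 white-matter
  PCs), 6 motion parameters and a 128 s DCT high-pass as nuisance;
- **searchlight SVR decoding** — for every voxel, the 16 pattern vectors
  (4 numerosities × 4 runs) within a 4-voxel-radius sphere enter a linear
  epsilon-SVR (C = 1) under leave-one-run-out cross-validation; accuracy
  is the Fisher z of the correlation between predicted and true
  numerosities, per time bin, averaged over delay bins 3–8;
- **controls** — decoding the *nonmemorized* stimulus (should fail), a
  univariate parametric-modulation GLM (blind to a zero-sum multivariate
  code), and the rank-distance label-permutation profile: relabelings
  farther from the true order (distance = Σ|adjacent rank differences|,
  classes {3,4,5,6,7} with sizes {1,2,6,2,1} over 12 reversal-reduced
  orderings) should decode progressively worse;
- **group inference** — 8 mm-smoothed subject delay-accuracy maps tested
  against chance with sign-flip max-statistic cluster-extent FWE
  correction (cluster-defining p < 0.001, FWE p < 0.05).

No empirical dataset ships with this package. A simulator generates 4D
BOLD runs with the numerosity code *planted* in a known region as zero-sum
voxel weights scaled affinely by the memorized numerosity, plus realistic
nuisance (AR(1) noise, drift, CSF/WM components, motion). Every pipeline
stage is validated against this ground truth. See `docs/methods.md` for
the full model description.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (each takes seconds to ~2 minutes):

```bash
python analysis/01_simulate_protocol.py   # events + pulse protocol
python analysis/02_simulate_bold.py       # 4D BOLD with planted code
python analysis/03_fit_firstlevel.py      # FIR betas (cued + uncued labels)
python analysis/04_searchlight_decode.py  # whole-brain accuracy maps
python analysis/05_label_permutations.py  # rank-distance profile
python analysis/06_group_inference.py     # cluster FWE + controls
```

With the default seed, `04_searchlight_decode.py` prints

```
mean delay accuracy (Fisher z): ROI 1.207 vs whole brain 0.127
smoothed delay-map peak (12, 14, 7), inside planted ROI: True
```

— the decoder recovers the planted region (chance level is 0), and
`05_label_permutations.py` shows accuracy falling off with rank distance
from the correct numerosity order:

```
distance 3: +1.379
distance 4: +0.780
distance 5: +0.282
distance 6: +0.423
distance 7: +0.155
```

`06_group_inference.py` completes the dissociation on a 6-subject cohort:
exactly one FWE-significant cluster overlapping the planted region for
cued-label decoding, and none for either the nonmemorized-label decoding
or the univariate parametric contrast —

```
cluster_id  size_vox  peak_ijk    peak_t    p_fwe
         1       140 (5, 5, 6) 21.753682 0.025948
nonmemorized-label significant clusters: 0
univariate significant clusters: 0
```

## Layout

```
src/paramwm/
  stimgen.py         pulse trains, trials, balanced runs, events tables
  synthetic_bold.py  simulator + ground truth (SimConfig is the one config)
  firstlevel.py      FIR/parametric designs, aCompCor, DCT high-pass, OLS
  searchlight.py     sphere geometry, z-scaling, SVR, LORO accuracy maps
  permutation.py     rank distances, class enumeration, permuted decoding
  group.py           smoothing, delay t-maps, sign-flip cluster FWE
  pipeline.py        subject/cohort glue used by scripts and tests
analysis/            numbered drivers reproducing the study flow
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      models, parameters, defaults, limitations
```
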