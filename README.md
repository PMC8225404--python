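# naturalreach

Behavioral segmentation, event-related spectral power, and event-by-event
regression for naturalistic arm-movement electrophysiology — with a
synthetic-study generator so the whole pipeline is testable without any
data downloads.

The pipeline mirrors a naturalistic ECoG/video analysis workflow:

1. **Segment** wrist keypoint trajectories into move/rest states with a
   two-state autoregressive hidden semi-Markov model (AR(1) on per-frame
   displacements, negative-binomial dwells, duration-explicit Viterbi).
2. **Detect** movement-initiation events (0.5 s rest → 0.5 s move) and prune
   them: duration in [0.5, 4] s, tracking confidence > 0.4, quadratic radial
   fit R² > 0.6, and at most the 200 fastest onsets per day.
3. **Preprocess** multichannel neural recordings: median DC removal,
   high-amplitude artifact zeroing (±2 s), 1–200 Hz band-pass + 60/120/180 Hz
   notches, resampling to 500 Hz, common-median rereferencing per electrode
   group, and IQR-based bad-channel flagging (SD > 5·IQR, kurtosis > 10·IQR).
4. **Spectral**: 10 s event-centred segments, bad-segment rejection
   (<0 dB mean PSD or 115–125 Hz power > 3 SD), Morlet log power
   (4–124 Hz), baseline subtraction (−1.5…−1 s), and LFB (8–32 Hz) / HFB
   (76–100 Hz) averages over the first 0.5 s.
5. **Project** electrode power onto atlas regions with a 3D Gaussian
   (2 cm FWHM), density-based region retention (>3), normalized weights.
6. **Group stats**: median-over-events, mean-over-subjects aggregation; a
   2000-draw bootstrap baseline null with Benjamini–Hochberg FDR masking;
   Kruskal–Wallis comparisons across subjects/days.
7. **Features**: 10 per-event behavioral/environmental features (timing,
   reach kinematics, 370–900 Hz speech-band audio ratio, bimanual metrics).
8. **Regress**: per-electrode, per-band Huber regression (IRLS) of band
   power on the features, with forward selection on OLS adjusted R²,
   day-balanced 90/10 train/test splits, withheld-data R², and permutation
   ΔR² feature importance, averaged over repeated splits.

The `synthetic` module generates multi-subject studies (trajectories,
neural recordings with injected band-power effects that follow a known
linear model, audio, electrode layouts, atlas point clouds) with full
ground truth, closing the loop for parameter-recovery tests.

## CLI

Everything is exposed through one entry point:

```bash
# full synthetic pipeline, all stages, one master seed
naturalreach run --seed 1 --out-dir out/

# individual stages on files
naturalreach simulate --seed 2 --subjects 2 --days 3 --out-dir study/
naturalreach segment --traj study/simulate/sub00_day01_contra.csv --out states.csv
naturalreach detect-events --states states.csv --traj .../sub00_day01_contra.csv --out events.csv
naturalreach preprocess --rec .../sub00_day01_raw --out clean
naturalreach spectral --rec clean --events events.csv --out powers.csv
naturalreach project --rec clean --atlas study/simulate/atlas.csv --out weights.csv
naturalreach features --traj ... --ipsi-traj ... --states ... --ipsi-states ... \
    --events events.csv --audio .../sub00_day01.wav --out features.csv
naturalreach regress --powers powers.csv --features features.csv --splits 200 --out reg
```

Tables are plain CSV (with small JSON sidecars for rates/labels); neural
recordings are a `.npy` voltage array plus a `.json` metadata sidecar;
audio is WAV. `naturalreach run` derives every stage seed from the master
seed and writes a `provenance.json` (config hash + seed) per stage;
rerunning the same config is byte-identical.

## Acceptance

`tests/test_acceptance.py` holds the acceptance suite (Viterbi vs
exhaustive-enumeration oracle, exact event rules, preprocessing contracts,
spectral calibration, projection correctness, masking null calibration and
power, end-to-end regression recovery of planted coefficients, pipeline
determinism). The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a pipeline smoke and writes the (empty) numeric-target report — this
build's acceptance is property-based rather than value-based.
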