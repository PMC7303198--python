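# Methods

`mmnkit` implements the analysis chain of a multi-feature passive auditory
oddball study of the mismatch negativity (MMN) to spoken pseudowords, plus
a synthetic-EEG generator that emulates the study so every stage can be
validated without access to human recordings.

## The paradigm being modeled

Four bisyllabic pseudowords form a 2×2 crossing of **phonotactic
probability** (PhonProb: a high-probability -ts- cluster, HPP, vs a
low-probability -tk- cluster, LPP) and **syllable stress** (SylStr: first
vs second syllable stressed): `NOTsal`, `NOTkal`, `notSAL`, `notKAL`
(capitals mark stress). Each stimulus serves as the frequent **standard**
(SD) of its own condition block; within a block, a **formal deviant** (FD,
cluster exchanged, i.e. PhonProb flips) and a **temporal deviant** (TD,
stress flips) occur rarely. A condition comprises 1,620 trials — 1,332
standards and 144 of each deviant type (8.9% per type) — presented at a
1,200 ms stimulus-onset asynchrony with deviants separated by 1–8
standards. Because every deviant is the standard of another condition,
difference waves can contrast *identical* stimuli (deviant − standard),
isolating expectation effects from acoustics.

### Separation allocation (`design`)

How the original randomization distributed separations over 1–8 is not
recoverable; the generator's default `balanced=True` allocates each
deviant type's 144 separations equally (18 per separation, shuffled; for
counts not divisible by 8 the remainder goes to the smallest separations
to stay inside the standard budget). This choice makes the downstream
selection arithmetic exact: deviants preceded by a single standard are
excluded, so 144 − 18 = 126 deviants per type survive, with 252
immediately-preceding standards per condition. Both deviant types are
interleaved in one block and the separation constraint is enforced between
successive deviants of any type. `balanced=False` draws separations
uniformly (with re-draws until the standard budget fits). Trial-level
token variants (3 utterances per pseudoword) are assigned uniformly at
random; block/run structure (blocks of 270 trials) is carried as metadata
only, since analysis pools across blocks.

## Synthetic EEG (`simulate`)

The generator renders continuous data (µV) for a 57 scalp + 2 mastoid +
4 EOG montage at 1,000 Hz (10% system names; Fpz/AFz serve as reference/
ground and are not data channels). Channels carry schematic grid
coordinates used only for topography. Per trial the neural source is a sum
of Gaussian-envelope pulses:

- obligatory N1 (−1.0 µV, 100 ms post syllable onset, FWHM 80 ms) and P2
  (+0.8 µV, 200 ms, FWHM 120 ms) for each syllable; syllable 2 onset is
  fixed at 300 ms (half the 600 ms stimulus — the actual syllable timing
  is not modeled);
- on deviant trials, an MMN: a negative Gaussian pulse centered at
  *deviation onset + true latency*, default FWHM 60 ms. Deviation onset is
  stimulus onset for temporal deviants and the /t/-onset (250 ms) for
  formal deviants.

The source projects through a radial Gaussian topography peaked at FCz
(weight 1 at FCz, σ = 3 grid units; mastoids 0 by default so the mastoid
reference is neutral; EOG 0). Defaults for the ground truth emulate the
study's qualitative findings: MMN amplitude −2.5 µV in every cell; formal
latency 160 ms (HPP) vs 200 ms (LPP) — a 40 ms "HPP earlier" effect;
temporal latency 250 ms in all cells (no latency effect). Amplitudes in
the low-µV range and a frontocentral maximum are the textbook MMN regime.

Nuisance terms: per-channel 1/f ("pink") noise (default SD 8 µV, a
realistic post-cleanup single-trial level), 50 Hz line noise (1 µV,
random phase per channel), and Poisson blinks (4/min, 150 µV) that appear
on the EOG channels (inverted below the eye) and propagate to scalp with
an exponential front-to-back decay. Because identical stimuli produce
identical obligatory responses, these components cancel exactly in
identical-stimulus difference waves; they are nuisance structure only.

Ground-truth pulses are hard-zeroed beyond 6σ so that direct template
evaluation and placement in continuous data agree exactly; this is what
makes the noiseless end-to-end check exact to ~1e-13 µV. Stochastic
simulations are rendered in single precision (noise dwarfs float32
rounding by ~7 orders of magnitude); noiseless simulations stay in double
precision.

What the generator does **not** model: real head geometry or volume
conduction (the topography is schematic), acoustic stimulus content,
between-subject amplitude/latency variability (inter-subject variability
arises only through noise), muscle/electrode artifacts beyond blinks, and
drifts. Passing tests therefore demonstrate correctness of the analysis
chain under the stated signal model, not robustness to everything real
recordings contain.

## Preprocessing (`preprocess`)

Stage order is fixed: band-pass 0.5–70 Hz + notch 48–52 Hz → downsample
to 250 Hz → ocular artifact removal → epoch −100..1000 ms → DC/baseline
correction → 75 µV amplitude rejection → average-mastoid re-reference.

- **Filter realization.** The Butterworth cascades (4th-order band-pass,
  2nd-order band-stop) are applied as their squared-magnitude response in
  the frequency domain. This is numerically equivalent to forward-backward
  (filtfilt) IIR filtering except within a settling time of the record
  edges — negligible for minutes-long recordings — and is exactly
  zero-phase, which matters because MMN peak latency is an outcome
  measure. It is also several times faster, which keeps the full-pipeline
  recovery experiments cheap. A test asserts agreement with
  `scipy.signal.sosfiltfilt` on interior samples.
- **Downsampling** is plain sample picking (the 70 Hz low-pass directly
  above is the anti-alias filter); event indices are rescaled to the
  nearest sample. 1,000 → 250 Hz is the supported integer path.
- **Ocular removal.** The original manual ICA component selection is
  replaced by an automated surrogate: FastICA (seeded) over the scalp +
  mastoid channels with as many components as channels; components whose
  time course correlates with any EOG channel at |r| ≥ 0.7 (configurable)
  are zeroed. A cheaper least-squares EOG regression and a pass-through
  `none` are available; the scaled-down profiles use regression.
- **Epochs** are half-open `[−100, 1000)` ms on the sample grid → 275
  samples at 250 Hz. Events whose window does not fit are flagged
  (`reason="edge"`), never silently dropped.
- **DC/baseline/rejection.** Per trial and channel the epoch mean is
  subtracted, then the −100..0 ms baseline mean (net effect: baseline mean
  exactly zero). Trials exceeding ±75 µV after correction on any *scalp*
  electrode (mastoids and EOG excluded) are flagged `amplitude`. The
  criterion is applied before mastoid re-referencing, following the stage
  order above.

## Trial selection and equalization (`select`)

Deviants preceded by fewer than 2 standards since the previous deviant are
excluded; the standard immediately preceding each kept deviant is its
comparison trial (if that standard was artifact-rejected, the deviant is
kept and no replacement standard is sought — the pool simply shrinks).
Counts are then equalized to N = the minimum kept-deviant count over all
8 deviant cells of the participant (one global minimum, giving the strict
cross-condition balance the amplitude ANOVA assumes); every deviant cell
and every condition's standard pool is subsampled to N without
replacement, seeded. A single standard subset per condition is shared
between the FD and TD comparisons, so both deviant types are compared
against the same standard trials.

## ERP measures (`erp`)

Averages are time-locked to deviation onset (offset 0 for TD, 250 ms for
FD), the standard always locked to the same moment as its deviant. The MMN
peak is found on the FCz difference wave: among interior local minima in
the primary window (FD: 100–300 ms, TD: 200–350 ms after deviation onset),
candidates must pass a topography check — the frontocentral ROI mean
within ±24 ms more negative than the centroparietal one — and the most
negative passing candidate wins (ties to the earlier latency). If none
passes, the fallback window (FD: 80–300 ms, TD: 120–370 ms) is searched;
failing that, the fallback window's global minimum is returned with a QC
flag. This deterministic rule replaces the human visual inspection step;
the QC flag marks the cases an analyst would have inspected.

Mean amplitudes are computed per electrode for standard and deviant waves
separately over ±24 ms (13 samples at 250 Hz, endpoints inclusive) around
the FCz-derived latency. ROI means average 10 electrodes each
(frontocentral: Fz, F1–F4, FCz, FC1–FC4; centroparietal: Cz, C1–C4, CPz,
CP1–CP4); FCz's own amplitude is included in the frontocentral mean (the
printed ROI membership), and reduced 6-electrode ROIs accompany the
16-channel scaled montage. Note that the 250 ms formal lock offset is not
a multiple of the 4 ms sample period, so formal-deviant latencies are
reported on a grid offset by 2 ms; a true latency midway between two
samples resolves to the earlier one.

## Statistics (`stats`)

All factors are two-level and fully within-subject, so every effect of the
2×2×2×2 amplitude ANOVA (PhonProb × SylStr × Cond × ROI) and the 2×2
latency ANOVA (PhonProb × SylStr; Cond and ROI are meaningless for a
single-electrode difference-wave measure) has df = (1, n−1) and reduces to
a one-sample t test on per-subject contrast scores (±1 coding over cells,
averaged): F = n·mean(score)²/var(score). Sphericity corrections are moot
at df = 1 and omitted. Zero-variance contrasts are reported with a
`degenerate` flag (F = ∞, p = 0 if the mean score is nonzero; F = 0
otherwise) rather than raising. Partial eta-squared is reported as
F/(F + n − 1).

Holm's step-down correction is applied within an a priori hypothesis
family per deviant type (m = 5 by default, printed alongside every
adjusted p): amplitude Cond main effect; the feature×Cond interaction
(PhonProb×Cond for FD, SylStr×Cond for TD); the three-way
PhonProb×SylStr×Cond; the latency main effect of the deviant's feature;
and the latency PhonProb×SylStr interaction. The exact family composition
of the original analysis is not recoverable from the published text, so
the family is configurable. Post-hoc two-sided paired t tests carry a
Bonferroni multiplier over the ROI family.

The published F values on human data are not reproduction targets (the
recordings are not deposited); the machinery is validated by (a) exact
agreement with an independent cell-means sums-of-squares oracle and with
pingouin, (b) equivalence of main effects with squared collapsed paired
t tests, (c) null calibration — on Gaussian null cell means with n = 24,
per-effect rejection at α = 0.05 sits in [0.03, 0.07] over 1,000
replicates — and (d) parameter recovery on the synthetic pipeline.

## Orchestration and problem sizes (`pipeline`)

`run_study` drives the chain per participant; all randomness derives from
one master seed via `numpy.random.SeedSequence` spawning (per-participant,
then per-stage), so reruns are byte-identical. Artifacts (TSV/JSON) embed
the config hash and package version.

Three built-in profiles:

- `paper_profile()` — full design: 1,620 trials × 4 conditions, 63-channel
  montage, 24 participants, ICA cleanup. This is the faithful
  configuration; a single participant's raw data is ~0.5 GB in memory.
- `test_profile()` — the scaled-down study used throughout the test
  suite: 400 trials per condition (328/36/36, preserving the 8.9–9%
  deviant rate), 16 scalp channels with midline-ROI coverage, 8
  participants, EOG-regression cleanup. Chosen so a full simulated study
  runs in well under a minute.
- `recovery_profile()` — `test_profile` with pink noise at 1 µV: in the
  per-subject average over ~31 equalized trials this yields ~10:1 peak
  SNR, the high-SNR regime in which the recovery experiment measures the
  correctness of the chain (bias of the recovered 40 ms latency effect
  ≤ one 250 Hz sample; detection of the PhonProb latency effect with the
  HPP-earlier direction in ≥ 80% of seeded runs) rather than noise
  robustness. At the realistic 8 µV default, an 8-subject scaled study
  does not reliably detect the effect — expected, since the original
  design used 24 participants and ~126 trials per cell.

`recovery_experiment` repeats such studies over a grid of ground-truth
overrides and reports detection rate, bias and RMSE of the recovered
latency difference. `type1_calibration` simulates null cell-mean tables
directly (no EEG), vectorized over replicates.

## Numerical conventions and degenerate inputs

- Epoch window half-open; baseline interval `[−100, 0)` ms.
- Peak ties break toward earlier latency; peak windows are inclusive.
- Amplitude criterion is a strict `>` comparison.
- BrainVision export: little-endian int16, multiplexed, 0.1 µV/bit
  (values clip at ±3,276.8 µV); marker descriptions encode
  role:stimulus:condition:token so event tables round-trip exactly. A
  lossless float32 + JSON-header fallback is provided. Parse errors report
  file and line number.
- Infeasible designs (separation budget exceeding the standard count),
  incomplete stimulus crossings, empty analysis cells, missing ROI
  electrodes or mastoids, and out-of-window search ranges raise typed
  errors naming the offending element; report-only validation never
  raises.

## Known limitations

- The simulator's subject-level ground truth is fixed (no random effects);
  between-subject variance in recovered measures is noise-driven.
- ICA unmixing on mostly-Gaussian synthetic noise may not converge within
  the iteration cap; the EOG-correlation flagging still operates, and the
  blink test asserts the outcome (frontal-EOG correlation drops below
  0.2), not convergence.
- The BrainVision reader supports the subset of the format the writer
  emits (INT_16, multiplexed); it is not a general-purpose reader.
- The latency grid is 4 ms; all latency claims are made at that
  resolution.
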