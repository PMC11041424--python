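# Methods

## Problem and model

`typefatigue` detects *mental fatigue* from the timing of natural typing.
The premise is physiological: fatigue (e.g. sleep inertia after a nighttime
awakening) slows and destabilises fine motor output, and keystroke
press/release timings — collectable passively on commodity keyboards —
carry that signature.

The pipeline has four stages.

1. **Timing features.** Each keystroke contributes four features, in
   seconds: hold time (release − press of one key), flight time
   (press → press), inter-key latency (release → press of the next key;
   negative when keys overlap, "rollover"), and inter-release latency
   (release → release). The first key of a sequence has no predecessor, so
   its last three features are zero. A model input is a fixed 150×4 matrix:
   shorter sequences are zero-padded (with the valid length tracked),
   longer ones head-truncated. Working in seconds keeps typical values in
   the 0.05–1 range, which avoids saturating the recurrent units; no
   further scaling is applied.

2. **Typing embedding v(x).** A two-layer LSTM (128 units per layer,
   recurrent dropout 0.2, dropout 0.5 between layers, masking of padded
   rows) maps the 150×4 input to a 128-d embedding — the hidden state of
   the last layer at the final valid timestep. The network is pretrained
   for *identity* with a triplet hinge loss (anchor/positive = two
   sequences from one typist, negative = another typist), so the embedding
   space organises typing style. No deep-learning framework is used: the
   LSTM forward/backward passes, dense layers, losses and Adam are
   implemented in NumPy (`typefatigue/_nn.py`) and verified against finite
   differences in the test suite. Initialisation is Glorot (input weights)
   / orthogonal (recurrent weights) with forget bias 1; a global
   gradient-norm clip of 5 stabilises full-sequence backpropagation.

   Two choices specific to *desk-scale* pretraining (tens of typists
   rather than the corpus scale the architecture was designed for) matter
   and were arrived at by measurement. First, the pretraining loss acts on
   *batch-standardised* embeddings (batch-centred, divided by the batch
   RMS radius) with margin 0.2: the raw-scale hinge has two degenerate
   descent directions — global shrinkage and common-mode drift — and with
   bounded recurrent outputs it collapses the embedding cloud instead of
   organising it. Standardising inside the loss removes both, so the loss
   can only improve by rearranging identities; `transform` still returns
   the raw final hidden state. Second, dropout is disabled during
   desk-scale pretraining (the estimator exposes the architecture's 0.2 /
   0.5 rates, sized to regularise corpus-scale training): at a few dozen
   typists the 0.5 inter-layer dropout injects more gradient noise than
   the identity signal carries, and the held-out triplet loss *rises*
   under it; with dropout off it falls and held-out triplet accuracy
   improves. Default optimiser for pretraining is Adam at 3e-4.

3. **Fatigue adaptation g(v(x)).** The backbone is frozen (its parameter
   checksum is asserted unchanged) and a single dense 128-unit relu layer
   is trained on top, with the triplet hinge loss
   `max(0, d(g_A, g_P) − d(g_A, g_N) + α)` on plain Euclidean distances.
   Anchor and positive share a state (rest or fatigue), the negative is the
   other state, and *all three come from the same participant*, cancelling
   identity variation. Defaults follow the upstream training recipe:
   α = 1.5, Adam (lr 0.005, β₁ = 0.9, β₂ = 0.999, ε = 1e−8), 30 epochs ×
   100 batches × 64 triplets. Triplet sampling is uniform (no hard-negative
   mining): uniform eligible participant, uniform eligible anchor class,
   distinct uniform anchor/positive, uniform negative. A participant is
   eligible when one class has ≥ 2 windows and the other ≥ 1. The
   "different sequences from the same class" are the nonoverlapping 150-key
   windows cut from each long session. A softmax variant (relu layer +
   2-way softmax, cross-entropy) is provided purely as a comparison arm.

4. **Detection.**
   * *Onetime:* the change score for a pair of same-participant windows is
     the Euclidean distance of their g-embeddings; distance > threshold ⇒
     state change. Evaluation is leave-one-participant-out: every score is
     produced by a head that never saw that participant. ROC/AUC are
     reported pooled (all cross-validated pairs as one set) and
     per-participant averaged (vertical TPR mean on a common FPR grid);
     the operating point is the closest-to-(0,1) ROC corner, ties broken
     toward higher sensitivity.
   * *Active (quick change detection):* g-embeddings are projected to a
     scalar score; the log-likelihood ratio
     `L_j = ln f_F(score_j) − ln f_R(score_j)` under Gaussian KDEs
     (Silverman bandwidth, evaluations floored at 1e−12) of fatigue/rest
     scores feeds a clamped Page CUSUM `S_j = max(0, S_{j−1} + L_j)`;
     `S_j ≥ τ` raises a detection. Sweeping τ (200-point grid over the
     observed S range) yields PFD (alarm before the true change), PND (no
     alarm after it) and ADD (delay in sessions, first post-change session
     = 1); EER is the linearly interpolated PFD = PND crossing.

## Design choices where the design was open

* **Scalar projection.** The default is a deterministic *centroid axis*:
  the signed projection onto the unit vector from the rest centroid to the
  fatigue centroid of the training folds, origin at the rest centroid. A
  1-D t-SNE projection is also provided; it is transductive and
  seed-sensitive, which makes it unsuitable as a default for an inductive
  detector, so it is kept as an option.
* **Density fitting for the CUSUM.** Two modes exist. The 15+15 sequence
  evaluation (`simulate_afd_sequences`) defaults to fitting f_R/f_F on the
  participant's *remaining* held-out scores (those not drawn into the
  sequence), mirroring an evaluation on precomputed cross-validated
  scores; `training_folds` mode fits them on the training participants'
  scores and is the fully subject-independent variant a deployment would
  use (it is measurably harder: on the strong-effect cohort EER rises from
  ≈0.01 to ≈0.17).
* **ADD and monotonicity.** ADD is reported with nondetections censored at
  the post-change horizon (counted as the full horizon delay). Under the
  detected-only mean, ADD is not monotone in τ (the detected set shrinks);
  under censoring, per-sequence delay is nondecreasing in τ, so the curve
  is a well-behaved trade-off. The median delay among detected sequences
  at the EER threshold is reported separately.
* **CUSUM form.** The clamp at zero follows the requirement that the
  statistic hovers near zero under rest; an unclamped sum would drift to
  −∞ and delay detection indefinitely.
* **Pairs.** Pairs are unordered and intra-participant only; under the
  balanced policy each participant contributes at most a fixed number of
  change and no-change pairs (default 50, tests/acceptance use 100),
  subsampled without replacement.
* **Daily trend score.** For a stream session, the scalar score is the
  centroid-axis projection of its g-embedding; the pair score of two
  consecutive sessions (< 2 h apart, same day) is the later session's
  score minus the participant's running mean score (their "running
  reference"), so each person acts as their own control. Scores are binned
  by the later session's hour of day; bins get the pooled mean and a
  bootstrap 95% CI; empty bins are absent, not zero.

## The synthetic typist simulator

No public corpus ships with the package; the simulator generates the three
study conditions the pipeline expects:

* **Pretraining corpus** (default 200 typists × 15 sessions × ~70 keys):
  identity signal from between-typist differences in timing parameters.
* **Supervised cohort** (default 14 participants × 2 rest + 2 fatigue
  sessions × 15 min): labelled states for adaptation.
* **Daily stream** (default hourly ~3-min sessions over a week): latent
  fatigue follows a circadian cosine (acrophase 23:00, amplitude 0.8)
  plus a post-lunch dip bump at 14:00 and Gaussian noise, recorded as
  ground truth.

Hold and inter-key times are i.i.d. log-normal per typist (hold ≈ 0.11 s,
inter-key ≈ 0.22 s medians; ≈ 3 keys/s), right-skewed and positive as real
latencies are. Rollover occurs with per-typist probability ≈ 0.1 and
produces negative inter-key latencies bounded so press times stay ordered.
Fatigue at latent level z ∈ [0,1] shifts log-means by `z·log(mean_scale)`
and inflates log-sds by `1 + z·(sd_scale − 1)`; the canonical strong-effect
condition is mean_scale = 1.3, sd_scale = 1.5, and per-typist effects are
drawn with a ±60% spread on the excess over 1 so cohorts mix strong and
weak responders (the user-dependent separability real cohorts show).
Setting the between-typist spread to zero, or the effect scales to 1,
yields the negative controls (identity pretraining must fail; detection
AUC must sit at chance).

What the simulator does *not* emulate: linguistic content and key
identity (keycodes are discarded by design), within-session learning or
drift, device/keyboard differences, non-stationary schedules, and any
physiological model of sleep inertia beyond multiplicative slowing.
Passing recovery tests therefore shows the *pipeline* recovers planted
timing effects of plausible magnitude under realistic sampling noise — not
that real fatigue produces effects of that size.

## Numerical choices and degenerate inputs

* Density floor 1e−12 before taking logs (no infinite LLRs outside KDE
  support); KDE requires ≥ 5 scores per class and non-constant samples.
* Triplet gradients guard zero distances with a 1e−12 floor on the unit
  vectors; the hinge's subgradient at 0 is taken as 0.
* EER uses linear interpolation between the adjacent grid thresholds where
  PFD − PND changes sign; if the curves never cross on the grid the
  closest point is used.
* Sessions must be non-empty with non-decreasing press times and
  release ≥ press per key; violations raise typed errors naming the first
  offending row. Malformed (unparseable) rows are dropped and counted.
* LOO folds sort samples by participant id before training, so fold
  contents are invariant to input ordering.

## Problem sizes used by tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at
desk scale, chosen so the statistical properties under test are
well-resolved: a 20-typist × 8-session pretraining corpus (4 epochs × 12
batches × 48 triplets), the default 14-participant supervised cohort
(~1000 windows of 150 keys), a reduced adaptation schedule of 15 epochs ×
50 batches × 64 triplets (the printed 30 × 100 schedule changes pooled AUC
by ~1 point on these data), 8 simulated 15+15 sequences per participant,
and a 4-typist × 7-day hourly stream for the circadian recovery.

## Known limitations

* The backbone is pretrained at desk scale; it provides a genuine
  identity-organised embedding but not the representation quality of a
  corpus with 10⁵ typists. External checkpoints matching the architecture
  can be loaded via `TypingEmbedder.load` / `load_weights`.
* 1-D t-SNE projection cannot embed new sessions without refitting; the
  centroid-axis default exists precisely to make the active detector
  inductive.
* KDE-based LLRs are unreliable in the far tails of the score
  distributions (the floor caps them); the CUSUM is robust to this in
  practice because extreme scores saturate rather than explode.
* The circadian trend is a population aggregate; per-person schedules and
  habits are not modelled.
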