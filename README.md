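# typefatigue

Detection of mental fatigue from keystroke dynamics — the timing of key
press/release events during natural typing. Fatigue (sleep inertia,
sustained cognitive load) slows and destabilises fine motor output; this
package quantifies that signature passively, from data any mechanical
keyboard produces, without questionnaires or dedicated tasks. It is aimed
at researchers in digital biomarkers and psychomotor health monitoring.

## What it computes

A keystroke session is reduced to a 150×4 matrix **x** of per-key timing
features (hold, flight, inter-key and inter-release latencies, seconds). A
two-layer masked LSTM — pretrained on typist *identity* with a triplet
loss — maps it to a 128-d embedding **v(x)**. A fatigue detection layer
(dense, 128 relu units) is then trained on top of the *frozen* backbone by
distance metric learning with the triplet hinge

    L = max(0, d(g(v(x_A)), g(v(x_P))) − d(g(v(x_A)), g(v(x_N))) + α),

where anchor/positive share a state (rest or fatigue), the negative is the
other state, all three from the same participant, and *d* is the Euclidean
distance. Detection operates in two regimes, always evaluated
leave-one-participant-out:

* **Onetime** — the distance between two same-participant samples in the
  fatigue space g(v(x)) scores *change* vs *no change*; ROC/AUC, and
  sensitivity/specificity/precision/F1 at the closest-to-(0,1) corner.
  Random-forest / RBF-SVM / k-NN classifiers on summary timing statistics
  serve as baselines, and a softmax head as the deep baseline.
* **Active (quick change detection)** — each session's fatigue-space
  embedding is projected to a scalar score; the CUSUM statistic
  S_j = max(0, S_{j−1} + L_j) with L_j = ln f_F(score_j) − ln f_R(score_j)
  accumulates evidence and raises a detection at a threshold τ. Sweeping τ
  gives PFD / PND / ADD trade-off curves and the EER.

Because the original keystroke corpora are proprietary, the package ships
a synthetic typist simulator (log-normal timing, multiplicative fatigue
effects, circadian latent fatigue with ground truth) that emulates the
three acquisition protocols — identity pretraining corpora, labelled
rest/fatigue cohorts, and timestamped real-world streams. All neural
components are pure NumPy (no deep-learning framework required).

## Worked example

```python
import numpy as np, typefatigue as tf

# synthetic study: identity corpus, then a labelled 14-participant cohort
pre = tf.simulate_pretraining_corpus(n_users=20, sessions_per_user=8,
                                     keys_per_session=60, seed=1)
backbone = tf.pretrain_backbone(pre, seed=1, recurrent_dropout=0.0,
                                inter_layer_dropout=0.0)

cohort = tf.simulate_supervised_cohort(n_participants=14, seed=2)
windows = tf.featurize_sessions(cohort.sessions)          # 150-key windows
cfg = tf.AdaptationConfig(epochs=15, batches_per_epoch=50, seed=1)
folds = tf.loo_protocol(windows, backbone, cfg)           # 14 held-out folds
pairs = tf.build_pairs(folds, max_pairs_per_class=100, rng=1)
rep = tf.roc_analysis(pairs)
print(f"pooled AUC {rep.auc_percent:.1f}%  "
      f"sens {rep.sensitivity:.0f}%  spec {rep.specificity:.0f}%")

seqs = tf.simulate_afd_sequences(folds, n_sequences_per_participant=8, rng=1)
m = tf.evaluate_afd(seqs)
print(f"AFD EER {m.eer:.3f}  median detection delay {m.median_add_at_eer:.0f} sessions")
```

Output:

    pooled AUC 99.7%  sens 99%  spec 99%
    AFD EER 0.000  median detection delay 1 sessions

Read: on a cohort with a strong planted fatigue effect (30% mean slowing,
50% dispersion inflation), distances in the learned fatigue space separate
state-change pairs from same-state pairs almost perfectly, and once a
simulated session stream switches from rest to fatigue the cumulative
detector fires after about one session at the equal-error threshold. A
zero-effect cohort run the same way yields AUC ≈ 50% (chance), which is
the package's calibration check.

The same stages are scriptable from a shell via the `typefatigue` CLI
(`simulate`, `pretrain`, `adapt`, `detect`, `afd`, `trend`).

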