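# Methods

## Model

A user is a chronological sequence of posts `x_1 … x_T`, each a token
sequence padded/truncated to `post_len`. The pipeline:

**Emotion network (TextCNN).** Convolutional filters of heights
`filter_heights` (default 3, 4, 5; `n_filters` each) slide over the
embedded post; ReLU and max-over-time pooling feed a fully connected layer
whose activation is the post's emotion vector `e_t` (dimension
`hidden_dim`). A per-class sigmoid head (positive / negative / neutral)
trains the network on the emotion corpus with early stopping on a dev
split; afterwards the parameters are frozen (the trainer asserts the
parameter hash is unchanged). The user-level emotion expectation is the
arithmetic mean `v_emo = (1/T) Σ_t e_t`.

**Post encoder (BiLSTM).** A bidirectional LSTM over the embedded tokens;
the post vector is `p_t = [h_fwd_last ; h_bwd_first]`, dimension
`2·bilstm_hidden`. PAD positions carry the hidden state through unchanged,
so appending PAD tokens leaves `p_t` bitwise identical (tested). An
all-PAD post encodes to the zero vector.

**Selection policy (REINFORCE).** State
`s_t = [p_t ; avg(selected so far) ; e_t]` (zero average while nothing is
selected; the `no_emotion_in_state` ablation drops `e_t`). A one-hidden-
layer MLP with sigmoid head gives `P(select | s_t)`. Per update, `N =
n_episodes` episodes are sampled in parallel per user; the terminal reward
is the frozen-classifier probability of the gold label given the selected
subset. The surrogate loss is

    loss_1 = -(1/N) Σ_n (R_n − b_n) Σ_t log p_θ(a_t | s_t).

An episode that selects nothing is scored on the zero pooled vector and
penalized with reward offset −0.5 (`EMPTY_SELECTION_PENALTY`), so the
all-skip policy is never a fixed point. Inference is greedy:
select iff `P(select | s_t) > greedy_threshold` (default 0.5), yielding
the subset split `H^dep` (selected) / `H^non` (rest).

**Attention and fusion.** `u_t = tanh(W_s p_t + b_s)`, scores
`u_t · u_s` against a learned context vector, masked softmax over the real
(non-PAD, selected) posts gives `alpha_t`; the pooled vector
`Σ_t alpha_t p_t` is concatenated with `v_emo` and classified by a
two-class softmax with cross-entropy loss (mean over the batch). The
`no_attention` ablation replaces `alpha` with uniform weights, which is
exactly plain averaging (tested to machine precision).

**Schedule.** Warm-up trains encoder + attention + classifier on all
posts for `warmup_epochs`; then each of `epochs` alternating epochs runs a
policy pass with the classifier frozen followed by a classifier pass on
the current greedy selections with the policy frozen. Dropout 0.5 is
applied to post vectors during training; the optimizer is Adam
(`learning_rate`, default 1e-3). The best dev-F1 state is checkpointed and
restored.

## Parameter reference (TrainConfig)

| field | default | meaning |
|---|---|---|
| `embedding_dim` | 300 | token embedding width |
| `bilstm_hidden` | 200 | LSTM units per direction (post dim is 2×) |
| `dropout` | 0.5 | dropout on post vectors during training |
| `batch_size` | 128 | users per classifier batch |
| `learning_rate` | 1e-3 | Adam step size |
| `post_len` | 32 | tokens per post (pad/truncate) |
| `policy_hidden` | 128 | policy MLP hidden width |
| `n_episodes` | 8 | sampled episodes per user per policy update |
| `entropy_weight` | 0.0 | optional policy entropy bonus (off by default) |
| `warmup_epochs` / `epochs` | 2 / 6 | schedule lengths |
| `greedy_threshold` | 0.5 | inference selection threshold |
| `no_rl`, `no_emotion`, `no_attention`, `no_emotion_in_state` | False | ablations |

The defaults are the reference configuration. The package's own
benchmarks (`trainer_eval.benchmark_config()`, used by the tests, the CLI
default, and `scripts/acceptance.py`) scale the widths down — embedding
32, BiLSTM 24, batch 16, post_len 12, policy hidden 64, warm-up 10 +
18 alternating epochs; emotion net with filter heights (2, 3), 16 filters,
16-d emotion vectors — so that full training runs complete in seconds to
minutes on one CPU in pure numpy. The 18 alternating epochs were set from
training logs (the mean episode reward was still climbing at epoch 10 on
100-user runs); these sizes are the package's benchmark sizing, not a
claim about the reference configuration.

## Numerical design choices

- **Leave-one-out baseline.** The REINFORCE baseline for episode `n` is
  the mean of the *other* `N−1` rewards, not the plain within-batch mean.
  The plain mean leaks each episode's own reward into its baseline, an
  `O(1/N)` bias that is measurable at `N = 8–10`; leave-one-out keeps the
  estimator exactly unbiased while preserving the property that equal
  rewards give zero advantage (no update).
- **Zero-initialized policy head.** The policy's output weights start at
  zero, so the untrained policy is exactly uniform (`P(select) = 0.5` for
  every state). A randomly initialized head is a random hyperplane through
  post-vector space whose greedy thresholding correlates with content,
  making an "untrained" selector look informative; the zero head removes
  that artifact and gives maximum-entropy exploration. For the same
  reason, the null-control subsets are *sampled* from the uniform policy
  rather than greedily thresholded.
- **Latest-best checkpointing.** The best-dev-F1 checkpoint keeps the
  *latest* state among ties. Dev F1 saturates within a few epochs on
  separable data, and a strict improvement rule would freeze an
  early-epoch policy while the mean episode reward is still rising;
  keeping the latest tied state retains that refinement (indicator recall
  rose from ~0.77 to ~0.92–1.0 on the recovery benchmark).
- **Masked softmax** subtracts the per-row max over unmasked entries,
  assigns exactly 0 to masked slots, and raises on fully masked rows
  rather than returning NaNs.
- **Gradients.** All backward passes go through `erandet.nn`, a
  reverse-mode autodiff engine over float64; every component's gradient is
  verified against central finite differences (relative tolerance 1e-4) in
  the test suite, and the REINFORCE estimator is verified against finite
  differences of the *exact* expected reward computed by enumerating all
  `2^T` episodes of a toy problem.

## Synthetic benchmarks: scope and limitations

The generator builds five disjoint ~40-word lexicons (depression,
positive, negative, neutral, filler). Emotion posts draw ~70% of their
tokens from their own class; indicator posts mix depression and negative
words; depressed users receive `ceil(indicator_fraction · T)` planted
indicator posts at random positions, and `noise_rate` of all tokens are
resampled uniformly. An optional `distractor_rate` replaces a share of
the background posts of *both* classes with strongly emotional but
diagnosis-neutral posts. Labels are balanced and everything is
deterministic per seed.

Two benchmark constructions are used. The **recovery benchmark** uses the
default lexicons, so indicator posts carry an exclusive depression
vocabulary and the planted posts are unambiguous — the right setting for
asking whether the selector finds them (indicator recall). The **ablation
benchmark** instead draws indicator posts from the negative-emotion
lexicon, so the class signal is concentrated negativity rather than a
giveaway token. With the exclusive lexicon every variant that sees all
posts classifies perfectly (a ceiling effect that makes module
comparisons meaningless); with emotion-carried signal each module has
measurable work to do — the emotion net supplies the discriminative
feature, selection prunes ambiguous content — and removing any of them
costs median F1.

This is a lexical benchmark by construction. Passing it shows that the
pipeline can discover and exploit a sparse subset of diagnostic posts
end-to-end — the policy recovers the planted indicators, the
selected-subset probe beats the full-history probe, and each module's
removal does not help. It does **not** show clinical validity, robustness
to real social-media language (sarcasm, topic drift, code-switching), or
fairness across demographic groups; the vocabulary is tiny and the signal
is far cleaner than in real data. The indicator-recall metric is only
meaningful on generated data where ground truth exists. A structural
limit of the reward design is worth noting: the terminal reward
`p(gold | selected)` saturates once a *sufficient* subset is selected, so
redundant indicators carry little marginal reward and recall of every
planted post varies across training seeds even when test F1 is at
ceiling.

Model outputs are screening signals over text, not diagnoses.
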