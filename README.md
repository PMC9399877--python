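# erandet

Depression detection from social-media post histories with an
emotion-based reinforcement attention network.

## The problem

Given a user's chronological posts, classify the user as depressed or
non-depressed. Most of a typical history is irrelevant chatter; the
diagnostic signal lives in a small number of indicator posts. `erandet`
therefore combines three ideas:

1. **Emotion extraction.** A TextCNN, pretrained on a
   positive/negative/neutral emotion corpus and then frozen, maps each post
   to an emotion vector `e_t`. The arithmetic mean over the history gives a
   user-level emotion expectation `v_emo`.
2. **Reinforcement-learning post selection.** A policy network walks the
   posts in order. Its state at step `t` is `[p_t ; avg(selected) ; e_t]`,
   where `p_t` is the post's BiLSTM encoding and `avg(selected)` summarizes
   the posts picked so far. It selects or skips each post; the terminal
   reward is the classifier's probability of the gold label given only the
   selected posts, and the policy is trained with REINFORCE (N sampled
   episodes per user, mean-reward baseline). At inference the selection is
   greedy, splitting each history into a selected subset `H^dep` and its
   complement `H^non`.
3. **Sentence-level attention and fusion.** Attention weights
   `alpha_t = softmax_t(u_t . u_s)` with `u_t = tanh(W_s p_t + b_s)` pool
   the selected posts into a single vector, which is concatenated with
   `v_emo` and fed to a two-class softmax classifier.

Training warms up the classifier on all posts, then alternates per epoch
between a policy pass (classifier frozen) and a classifier pass on the
greedy selections (policy frozen), checkpointing the best dev-F1 state.

All neural components run on a small hand-written reverse-mode autodiff
engine over numpy float64 (`erandet.nn`) — there is no deep-learning
framework dependency, and every gradient is finite-difference checked in
the test suite.

## Worked example

The package ships a synthetic-data generator with known ground truth:
depressed users receive a small fraction of planted indicator posts and
everything else is neutral filler, so indicator-post recovery can be
measured exactly.

```bash
erandet synth --n-users 200 --posts-min 20 --posts-max 20 --seed 13 --out-dir data/
erandet train --histories data/user_histories.jsonl \
              --emotion-corpus data/emotion_corpus.tsv \
              --seed 1 --dump-selection --out-dir runs/full
```

The same experiment through the Python API:

```python
from erandet.experiments import selection_recovery

res = selection_recovery(seed=1)
print(res["test_f1"], res["indicator_recall"])
# 1.0  0.983   — test F1 of the trained model, and the fraction of
#                planted indicator posts its greedy selection recovers
```

Other subcommands: `erandet ablate` (full model vs. no-selection,
no-emotion and no-attention variants), `erandet subset-exp` (an
independent BiLSTM probe trained on the selected posts, the unselected
remainder, and the original histories), and `erandet viz` (per-user
attention-weight dump as TSV, optionally an HTML heat map). Pass
`--config config.yaml` to override any `TrainConfig` field; without it the
compact benchmark configuration is used.

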