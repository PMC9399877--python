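"""Synthetic corpora for exercising the full depression-detection pipeline.

Two generators are provided:

* a 3-class (positive / negative / neutral) emotion corpus whose classes are
  separable through small built-in lexicons, used to pretrain the emotion
  TextCNN;
* labelled user histories in which each depressed user carries a small
  fraction of planted "depression indicator" posts (depression-lexicon words
  mixed with negative-emotion words) among ordinary filler posts, while
  non-depressed users carry none.

The planted indicator indices are returned as ground truth so the
reinforcement-learning selector can be scored directly with
:func:`indicator_recall` — something no real weakly-labelled dataset allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import EmotionCorpus, Post, UserHistory

# ~40 words per class; classes pairwise disjoint, and the depression lexicon
# is kept disjoint from the negative lexicon so "no depression words for
# non-depressed users" is guaranteed by construction.
POSITIVE_WORDS = [
    "nice", "happy", "great", "love", "awesome", "fun", "proud", "excited",
    "amazing", "wonderful", "beautiful", "glad", "smile", "laugh", "enjoy",
    "best", "cool", "sweet", "lovely", "grateful", "blessed", "win", "yay",
    "fantastic", "cheerful", "delight", "sunshine", "bright", "hope", "joy",
    "celebrate", "friendly", "kind", "warm", "pleasant", "thrilled", "super",
    "brilliant", "perfect", "cute",
]
NEGATIVE_WORDS = [
    "sad", "suck", "die", "hate", "awful", "terrible", "cry", "angry",
    "horrible", "pain", "hurt", "alone", "tired", "sick", "bad", "worst",
    "annoyed", "upset", "fear", "scared", "ugly", "failure", "broken",
    "stress", "dark", "gloomy", "miserable", "bitter", "regret", "sorrow",
    "tears", "lost", "cold", "grim", "dread", "ashamed", "guilty", "numb",
    "drained", "wreck",
]
NEUTRAL_WORDS = [
    "today", "weather", "coffee", "train", "office", "meeting", "lunch",
    "phone", "news", "game", "movie", "book", "road", "city", "shop",
    "music", "video", "photo", "street", "morning", "evening", "week",
    "month", "schedule", "ticket", "airport", "kitchen", "table", "window",
    "garden", "market", "report", "email", "class", "homework", "bus",
    "station", "river", "bridge", "keyboard",
]
DEPRESSION_WORDS = [
    "depressed", "depression", "suicidal", "suicide", "worthless",
    "hopeless", "insomnia", "meds", "therapy", "antidepressant", "selfharm",
    "empty", "despair", "diagnosed", "disorder", "anxiety", "panic",
    "breakdown", "overdose", "psychiatrist", "counseling", "relapse",
    "isolation", "exhausted", "unloved", "helpless", "paralyzed",
    "sleepless", "darkness", "void", "burden", "crying", "selfhate",
    "medication", "hospitalized", "trauma", "grief", "withdrawn", "fatigue",
    "apathy",
]
FILLER_WORDS = [
    "the", "a", "and", "to", "of", "in", "on", "at", "it", "is", "was",
    "with", "for", "this", "that", "my", "so", "just", "now", "then",
    "here", "there", "some", "really", "about", "like", "going", "got",
    "make", "new", "one", "two", "day", "time", "thing", "stuff", "people",
    "went", "saw", "bit",
]

DEFAULT_LEXICONS: dict[str, list[str]] = {
    "positive": POSITIVE_WORDS,
    "negative": NEGATIVE_WORDS,
    "neutral": NEUTRAL_WORDS,
    "depression_indicator": DEPRESSION_WORDS,
    "filler": FILLER_WORDS,
}


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpora.

    ``indicator_fraction`` is kept small by default: most posts of a
    depressed user are ordinary, and only a minority signal depression.
    """

    n_users: int = 200
    posts_per_user: tuple[int, int] = (15, 25)
    indicator_fraction: float = 0.15
    noise_rate: float = 0.05
    distractor_rate: float = 0.0
    post_len_range: tuple[int, int] = (5, 10)
    n_emotion_posts: int = 300
    lexicons: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_LEXICONS)
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("positive", "negative", "neutral", "depression_indicator", "filler"):
            if not self.lexicons.get(name):
                raise GeneratorConfigError(f"lexicon {name!r} is empty or missing")
        if self.posts_per_user[0] < 1:
            raise GeneratorConfigError("posts_per_user minimum must be >= 1")
        if not 0.0 < self.indicator_fraction < 1.0:
            raise GeneratorConfigError("indicator_fraction must be in (0, 1)")
        if not 0.0 <= self.noise_rate < 1.0:
            raise GeneratorConfigError("noise_rate must be in [0, 1)")
        if not 0.0 <= self.distractor_rate < 1.0:
            raise GeneratorConfigError("distractor_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted indicator post indices per user (empty for non-depressed)."""

    indicator_indices: dict[str, set[int]]

    def for_user(self, user_id: str) -> set[int]:
        return self.indicator_indices.get(user_id, set())


def _emotion_post(rng: np.random.Generator, cfg: GeneratorConfig, label: str) -> str:
    """One post of class `label`: own-class words and filler, with cross-class
    noise words at rate noise_rate."""
    own = cfg.lexicons[label]
    others = [w for c in ("positive", "negative", "neutral") if c != label
              for w in cfg.lexicons[c]]
    filler = cfg.lexicons["filler"]
    length = int(rng.integers(cfg.post_len_range[0], cfg.post_len_range[1] + 1))
    words = []
    for _ in range(length):
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            words.append(others[rng.integers(len(others))])
        elif rng.random() < 0.7:
            # own-class share chosen so a bag-of-words linear classifier
            # separates the classes (>=95% held out) at noise <= 0.1
            words.append(own[rng.integers(len(own))])
        else:
            words.append(filler[rng.integers(len(filler))])
    if not any(w in own for w in words):
        words[int(rng.integers(length))] = own[rng.integers(len(own))]
    return " ".join(words)


def generate_emotion_corpus(cfg: GeneratorConfig) -> EmotionCorpus:
    """Balanced 3-class emotion corpus, deterministic given cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_emotion_posts
    per_class = n // 3
    counts = {"positive": per_class, "negative": per_class, "neutral": per_class}
    # distribute any remainder deterministically
    for i in range(n - 3 * per_class):
        counts[("positive", "negative", "neutral")[i]] += 1
    records = []
    for label in ("positive", "negative", "neutral"):
        for _ in range(counts[label]):
            records.append((_emotion_post(rng, cfg, label), label))
    return EmotionCorpus(records)


def _indicator_post(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """Depression-indicator post: depression-lexicon words mixed with
    negative-emotion words, so both the content and the emotion channels
    carry signal."""
    dep = cfg.lexicons["depression_indicator"]
    neg = cfg.lexicons["negative"]
    filler = cfg.lexicons["filler"]
    length = int(rng.integers(cfg.post_len_range[0], cfg.post_len_range[1] + 1))
    words = []
    for _ in range(length):
        u = rng.random()
        if u < 0.35:
            words.append(dep[rng.integers(len(dep))])
        elif u < 0.7:
            words.append(neg[rng.integers(len(neg))])
        else:
            words.append(filler[rng.integers(len(filler))])
    if not any(w in dep for w in words):
        words[int(rng.integers(length))] = dep[rng.integers(len(dep))]
    return " ".join(words)


def _ordinary_post(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """Everyday post drawn from filler / neutral / positive vocabulary; with
    probability noise_rate a word is a stray negative-emotion word (moody but
    not depression-related)."""
    pool = (list(cfg.lexicons["filler"]) + list(cfg.lexicons["neutral"])
            + list(cfg.lexicons["positive"]))
    neg = cfg.lexicons["negative"]
    length = int(rng.integers(cfg.post_len_range[0], cfg.post_len_range[1] + 1))
    words = []
    for _ in range(length):
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            words.append(neg[rng.integers(len(neg))])
        else:
            words.append(pool[rng.integers(len(pool))])
    return " ".join(words)


def _distractor_post(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """Strongly emotional but diagnosis-neutral post: a plain positive or
    negative emotion post (both classes of user produce both kinds).

    With distractor_rate > 0 these replace a share of the ordinary posts, so
    the emotion channel alone no longer separates the user classes and a
    model pooling over the *whole* history must cope with misleading
    emotional content — the regime in which pruning posts matters."""
    label = "positive" if rng.random() < 0.5 else "negative"
    return _emotion_post(rng, cfg, label)


def generate_user_histories(cfg: GeneratorConfig) -> tuple[list[UserHistory], GroundTruth]:
    """Balanced user histories with planted indicator posts.

    The first half of users is depressed (label 1) with
    ``ceil(indicator_fraction * T)`` indicator posts at random positions;
    the second half is non-depressed with no depression-lexicon words at all.
    With ``distractor_rate`` > 0, that share of each user's non-indicator
    posts is replaced by emotional distractor posts (positive or negative),
    for depressed and non-depressed users alike.
    """
    cfg.validate()
    if cfg.n_users % 2 != 0:
        raise GeneratorConfigError("n_users must be even (balanced classes)")
    rng = np.random.default_rng(cfg.seed)
    histories: list[UserHistory] = []
    truth: dict[str, set[int]] = {}
    lo, hi = cfg.posts_per_user
    for i in range(cfg.n_users):
        depressed = i < cfg.n_users // 2
        user_id = f"u{i:04d}"
        T = int(rng.integers(lo, hi + 1))
        def background_post() -> Post:
            if cfg.distractor_rate > 0 and rng.random() < cfg.distractor_rate:
                return Post(text=_distractor_post(rng, cfg))
            return Post(text=_ordinary_post(rng, cfg))

        if depressed:
            k = math.ceil(cfg.indicator_fraction * T)
            positions = set(rng.choice(T, size=k, replace=False).tolist())
            posts = [
                Post(text=_indicator_post(rng, cfg)) if t in positions
                else background_post()
                for t in range(T)
            ]
            truth[user_id] = positions
        else:
            posts = [background_post() for _ in range(T)]
            truth[user_id] = set()
        histories.append(UserHistory(user_id=user_id, label=int(depressed), posts=posts))
    return histories, GroundTruth(truth)


def indicator_recall(selected: Mapping[str, set[int]], truth: GroundTruth) -> float:
    """Micro-averaged recall of planted indicator posts.

    ``selected`` maps user_id -> set of selected post indices, and only the
    users appearing in it are scored (so a selector can be evaluated on a
    test split against the full ground truth). Users with no planted posts
    contribute nothing; raises if no scored user has planted posts.
    """
    hit = 0
    total = 0
    for user_id, chosen in selected.items():
        planted = truth.for_user(user_id)
        if not planted:
            continue
        total += len(planted)
        hit += len(planted & set(chosen))
    if total == 0:
        raise ValueError("no planted indicator posts in ground truth")
    return hit / total
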