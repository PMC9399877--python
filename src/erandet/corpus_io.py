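"""Reading and writing user histories, emotion corpora and word embeddings.

File formats
------------
* user histories: JSON lines, one user per line with fields ``user_id``
  (string), ``label`` (0 = not depressed, 1 = depressed) and ``posts``
  (array of strings, chronological order).
* emotion corpus: two-column TSV ``text<TAB>label`` with labels in
  {positive, negative, neutral}, no header.
* embeddings: word2vec text format — a ``"count dim"`` header followed by
  ``token v1 ... vd`` lines.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

EMOTION_LABELS = ("positive", "negative", "neutral")
PAD_ID = 0
UNK_ID = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_MENTION_RE = re.compile(r"@\w+")
_SPLIT_RE = re.compile(r"[^a-z0-9<>]+")


class CorpusFormatError(ValueError):
    """Raised for malformed input files (names the offending line)."""


@dataclass
class Post:
    """One social-media post: raw text plus its padded token-id encoding."""

    text: str
    tokens: list[str] = field(default_factory=list)
    token_ids: np.ndarray | None = None


@dataclass
class UserHistory:
    """Ordered post history of one user with a binary depression label."""

    user_id: str
    label: int
    posts: list[Post]

    @property
    def T(self) -> int:
        return len(self.posts)


@dataclass
class EmotionCorpus:
    """Posts labelled positive / negative / neutral for emotion pretraining."""

    records: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in EMOTION_LABELS}
        for _, label in self.records:
            counts[label] += 1
        return counts


class Vocabulary:
    """Token <-> id maps plus the embedding matrix.

    Id 0 is PAD (zero embedding), id 1 is UNK; masking a padded batch is
    therefore just ``ids != 0``.
    """

    def __init__(self, tokens: Sequence[str], embeddings: np.ndarray):
        if embeddings.shape[0] != len(tokens) + 2:
            raise ValueError("embedding matrix must have len(tokens)+2 rows (PAD, UNK)")
        self.token_to_id: dict[str, int] = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
        for tok in tokens:
            if tok in self.token_to_id:
                raise ValueError(f"duplicate token {tok!r}")
            self.token_to_id[tok] = len(self.token_to_id)
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        self.embeddings = np.asarray(embeddings, dtype=np.float64)
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain non-finite entries")

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def lookup(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)


def tokenize(text: str) -> list[str]:
    """Lowercase, map URLs/@-mentions to placeholders, split on
    non-alphanumerics."""
    text = text.lower()
    text = _URL_RE.sub(" <url> ", text)
    text = _MENTION_RE.sub(" <user> ", text)
    return [t for t in _SPLIT_RE.split(text) if t]


def tokenize_and_pad(text: str, vocab: Vocabulary, n: int) -> np.ndarray:
    """Encode `text` as exactly `n` token ids (truncate / right-pad with PAD)."""
    if n < 1:
        raise ValueError("padded length n must be >= 1")
    ids = [vocab.lookup(t) for t in tokenize(text)][:n]
    ids.extend([PAD_ID] * (n - len(ids)))
    return np.asarray(ids, dtype=np.int64)


def read_user_histories(path: str | Path) -> list[UserHistory]:
    """Read one UserHistory per JSONL line; preserves post order."""
    histories: list[UserHistory] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                user_id = str(obj["user_id"])
                label = int(obj["label"])
                posts = list(obj["posts"])
            except (KeyError, TypeError, ValueError) as exc:
                raise CorpusFormatError(f"{path}: bad record on line {lineno}: {exc}") from exc
            if label not in (0, 1):
                raise CorpusFormatError(
                    f"{path}: label {label!r} outside {{0,1}} on line {lineno}"
                )
            if not posts:
                raise CorpusFormatError(f"{path}: user with no posts on line {lineno}")
            histories.append(
                UserHistory(user_id=user_id, label=label, posts=[Post(text=str(p)) for p in posts])
            )
    return histories


def write_user_histories(histories: Sequence[UserHistory], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in histories:
            fh.write(
                json.dumps(
                    {"user_id": h.user_id, "label": h.label, "posts": [p.text for p in h.posts]},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_emotion_corpus(path: str | Path) -> EmotionCorpus:
    records: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(f"{path}: expected text<TAB>label on line {lineno}")
            text, label = parts
            if label not in EMOTION_LABELS:
                raise CorpusFormatError(
                    f"{path}: unknown emotion label {label!r} on line {lineno}"
                )
            records.append((text, label))
    if not records:
        raise CorpusFormatError(f"{path}: empty emotion corpus")
    return EmotionCorpus(records)


def write_emotion_corpus(corpus: EmotionCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for text, label in corpus.records:
            fh.write(f"{text}\t{label}\n")


def load_embeddings(path: str | Path, d: int) -> Vocabulary:
    """Load a word2vec text-format embedding file into a Vocabulary.

    The PAD row is all-zeros and the UNK row is the mean of the loaded
    vectors, so out-of-vocabulary tokens fall back to an "average word".
    """
    tokens: list[str] = []
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}: expected 'count dim' header")
        count, dim = int(header[0]), int(header[1])
        if dim != d:
            raise CorpusFormatError(f"{path}: header dimension {dim} != requested {d}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip().split(" ")
            if len(parts) != dim + 1:
                raise CorpusFormatError(
                    f"{path}: row on line {lineno} has {len(parts) - 1} values, expected {dim}"
                )
            tokens.append(parts[0])
            rows.append(np.asarray(parts[1:], dtype=np.float64))
    if len(tokens) != count:
        raise CorpusFormatError(f"{path}: header promised {count} rows, found {len(tokens)}")
    loaded = np.stack(rows)
    emb = np.zeros((len(tokens) + 2, d))
    emb[UNK_ID] = loaded.mean(axis=0)
    emb[2:] = loaded
    return Vocabulary(tokens, emb)


def write_embeddings(vocab: Vocabulary, path: str | Path) -> None:
    """Write the non-special rows of a Vocabulary in word2vec text format."""
    tokens = [vocab.id_to_token[i] for i in range(2, len(vocab))]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {vocab.dim}\n")
        for i, tok in enumerate(tokens, start=2):
            vec = " ".join(repr(float(v)) for v in vocab.embeddings[i])
            fh.write(f"{tok} {vec}\n")


def build_vocabulary(texts: Sequence[str], d: int, seed: int = 0,
                     min_count: int = 1) -> Vocabulary:
    """Build a Vocabulary from raw texts with uniform[-0.25, 0.25] embeddings.

    Used when no pretrained embedding file is supplied; token order is the
    deterministic (count desc, token asc) order so the same texts always give
    the same vocabulary.
    """
    counts: dict[str, int] = {}
    for text in texts:
        for tok in tokenize(text):
            counts[tok] = counts.get(tok, 0) + 1
    tokens = sorted((t for t, c in counts.items() if c >= min_count),
                    key=lambda t: (-counts[t], t))
    rng = np.random.default_rng(seed)
    emb = rng.uniform(-0.25, 0.25, size=(len(tokens) + 2, d))
    emb[PAD_ID] = 0.0
    return Vocabulary(tokens, emb)


def encode_histories(histories: Sequence[UserHistory], vocab: Vocabulary, n: int) -> None:
    """Fill tokens/token_ids for every post, in place."""
    for h in histories:
        for p in h.posts:
            p.tokens = tokenize(p.text)
            p.token_ids = tokenize_and_pad(p.text, vocab, n)
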