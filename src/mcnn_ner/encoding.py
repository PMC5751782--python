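"""Vocabularies, embedding initialization and window-instance encoding.

The tagger is a word-level classifier: for every token a fixed-size odd
window of neighbors (default 13) is encoded as a triple of id sequences
(word ids over lowercased number-normalized surfaces, character ids over the
original cased text, dictionary-match label ids).  The training target is
the center token's B/I/O label; the auxiliary target is the ordered pair of
the previous and next tokens' labels, encoded jointly as one of 9 classes.
Positions outside the sentence are padded and count as label O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import LabeledSentence

__all__ = [
    "PAD",
    "UNK",
    "LABEL_TO_ID",
    "ID_TO_LABEL",
    "Vocab",
    "EmbeddingSpec",
    "TrainingInstance",
    "aux_encode",
    "aux_decode",
    "build_vocabs",
    "load_word_vectors",
    "random_embedding",
    "encode_windows",
]

PAD = "<pad>"
UNK = "<unk>"

LABEL_TO_ID = {"B": 0, "I": 1, "O": 2}
ID_TO_LABEL = {v: k for k, v in LABEL_TO_ID.items()}
N_LABELS = 3
N_AUX = 9


def aux_encode(prev_label: str, next_label: str) -> int:
    """Bijection {B,I,O}^2 -> 0..8 for the joint auxiliary class."""
    return LABEL_TO_ID[prev_label] * N_LABELS + LABEL_TO_ID[next_label]


def aux_decode(aux_id: int) -> tuple[str, str]:
    return ID_TO_LABEL[aux_id // N_LABELS], ID_TO_LABEL[aux_id % N_LABELS]


@dataclass
class EmbeddingSpec:
    """Embedding dimensionalities (defaults are the published settings)."""

    word_dim: int = 200
    char_dim: int = 20
    lex_dim: int = 5

    def __post_init__(self) -> None:
        if min(self.word_dim, self.char_dim, self.lex_dim) <= 0:
            raise ValueError("embedding dims must be positive")


class Vocab:
    """Word, character and lexicon-label id maps with reserved PAD/UNK ids."""

    def __init__(self) -> None:
        self.word_to_id: dict[str, int] = {PAD: 0, UNK: 1}
        self.char_to_id: dict[str, int] = {PAD: 0, UNK: 1}
        self.lex_to_id: dict[str, int] = {"O": 0, "B": 1, "I": 2}

    @property
    def n_words(self) -> int:
        return len(self.word_to_id)

    @property
    def n_chars(self) -> int:
        return len(self.char_to_id)

    @property
    def n_lex(self) -> int:
        return len(self.lex_to_id)

    def add_word(self, word: str) -> int:
        return self.word_to_id.setdefault(word, len(self.word_to_id))

    def add_char(self, ch: str) -> int:
        return self.char_to_id.setdefault(ch, len(self.char_to_id))

    def word_id(self, word: str) -> int:
        return self.word_to_id.get(word, self.word_to_id[UNK])

    def char_ids(self, text: str) -> list[int]:
        unk = self.char_to_id[UNK]
        return [self.char_to_id.get(c, unk) for c in text]

    def to_dict(self) -> dict:
        return {"word": self.word_to_id, "char": self.char_to_id, "lex": self.lex_to_id}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocab":
        v = cls()
        v.word_to_id = dict(d["word"])
        v.char_to_id = dict(d["char"])
        v.lex_to_id = dict(d["lex"])
        return v


@dataclass
class TrainingInstance:
    """One window instance: center-token features plus main and aux targets.

    ``word_ids``/``lex_ids`` have window length; ``char_ids`` holds one id
    sequence per window position (PAD positions get a PAD-char sequence).
    ``y`` is the center label id; ``y_aux`` the joint (prev, next) class;
    ``y_prev``/``y_next`` the separate 3-way targets for the two-head mode.
    """

    word_ids: np.ndarray
    char_ids: list[list[int]]
    lex_ids: np.ndarray
    y: int
    y_aux: int
    y_prev: int
    y_next: int
    sent_index: int = 0
    token_index: int = 0


def build_vocabs(corpus: list[LabeledSentence]) -> Vocab:
    """Map every training word norm (lowercased) and every character.

    Deterministic given corpus order.  Word-level lookup uses the
    number-normalized lowercased surface; the character map is built from
    the original cased text so the char-CNN sees capitalization.
    """
    if not corpus:
        raise ValueError("empty corpus")
    vocab = Vocab()
    for ls in corpus:
        for tok in ls.sentence.tokens:
            vocab.add_word(tok.norm.lower())
            for ch in tok.text:
                vocab.add_char(ch)
    return vocab


def random_embedding(n_rows: int, dim: int, rng: np.random.Generator, scale: float = 0.05):
    """Uniform(-scale, scale) table; row 0 (PAD) zeroed."""
    table = rng.uniform(-scale, scale, size=(n_rows, dim))
    table[0] = 0.0
    return table


def load_word_vectors(path, vocab: Vocab, dim: int = 200, seed: int = 0) -> np.ndarray:
    """Build the |V| x dim word table from a whitespace-delimited vector file.

    Rows for in-vocabulary words are copied; words missing from the file are
    initialized uniformly in +-0.05 (seeded).  An optional ``count dim``
    header line is accepted.  A dimension mismatch is an error.
    """
    rng = np.random.default_rng(seed)
    table = random_embedding(vocab.n_words, dim, rng)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().split()
        lines = []
        if len(first) == 2 and all(p.isdigit() for p in first):
            if int(first[1]) != dim:
                raise ValueError(f"vector dim {first[1]} != configured {dim}")
        elif first:
            lines.append(first)
        for line in fh:
            parts = line.split()
            if parts:
                lines.append(parts)
    for parts in lines:
        word, values = parts[0], parts[1:]
        if len(values) != dim:
            raise ValueError(f"vector dim {len(values)} != configured {dim} for {word!r}")
        idx = vocab.word_to_id.get(word)
        if idx is not None:
            table[idx] = np.asarray(values, dtype=float)
    return table


def encode_windows(
    sent: LabeledSentence,
    vocab: Vocab,
    window: int = 13,
    lex_labels: list[str] | None = None,
    sent_index: int = 0,
) -> list[TrainingInstance]:
    """Encode one instance per token with the given context window.

    ``lex_labels`` are the dictionary-match labels from
    :func:`mcnn_ner.lexicon.dict_tag`; ``None`` means all O (lexicon feature
    disabled).  Neighbors beyond the sentence edge are PAD positions and
    their labels count as O for the auxiliary target.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    tokens = sent.sentence.tokens
    labels = sent.labels
    n = len(tokens)
    if lex_labels is None:
        lex_labels = ["O"] * n
    if len(lex_labels) != n:
        raise ValueError("lex_labels/tokens length mismatch")
    half = window // 2
    pad_word = 0
    pad_chars = [0]
    word_row = [vocab.word_id(t.norm.lower()) for t in tokens]
    char_row = [vocab.char_ids(t.text) for t in tokens]
    lex_row = [vocab.lex_to_id[lab] for lab in lex_labels]
    instances = []
    for i in range(n):
        w_ids = np.empty(window, dtype=np.int64)
        l_ids = np.empty(window, dtype=np.int64)
        c_ids: list[list[int]] = []
        for k, j in enumerate(range(i - half, i + half + 1)):
            if 0 <= j < n:
                w_ids[k] = word_row[j]
                l_ids[k] = lex_row[j]
                c_ids.append(char_row[j])
            else:
                w_ids[k] = pad_word
                l_ids[k] = vocab.lex_to_id["O"]
                c_ids.append(pad_chars)
        prev_lab = labels[i - 1] if i > 0 else "O"
        next_lab = labels[i + 1] if i + 1 < n else "O"
        instances.append(
            TrainingInstance(
                word_ids=w_ids,
                char_ids=c_ids,
                lex_ids=l_ids,
                y=LABEL_TO_ID[labels[i]],
                y_aux=aux_encode(prev_lab, next_lab),
                y_prev=LABEL_TO_ID[prev_lab],
                y_next=LABEL_TO_ID[next_lab],
                sent_index=sent_index,
                token_index=i,
            )
        )
    return instances
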