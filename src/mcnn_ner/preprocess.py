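"""Offset-preserving preprocessing: sentence splitting, tokenization, number normalization.

Raw abstract text is turned into :class:`Sentence` objects whose tokens carry
document-absolute character offsets, so that BIO label sequences can be mapped
back to exact character spans at any later stage.  Two normalizations are
applied before any vocabulary lookup:

* tokens are split on whitespace and on a configurable set of punctuation
  delimiters, which are *retained* as single-character tokens (hyphens and
  brackets occur inside disease names and must survive for exact-span
  reconstruction);
* integer and decimal tokens are rewritten to the uniform surface ``"num"``
  in their ``norm`` field, leaving ``text`` and offsets untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Token",
    "Sentence",
    "Document",
    "DEFAULT_DELIMITERS",
    "split_sentences",
    "tokenize",
    "normalize_numbers",
    "preprocess_text",
]

# Punctuation treated as token boundaries and kept as one-character tokens.
# Includes both ASCII hyphen-minus and U+2212 minus.
DEFAULT_DELIMITERS = set("/−-><;:?[]{}()!@#$%^&*+,.")

# Abbreviations after which a period does not end a sentence.
DEFAULT_SENTENCE_ABBREVS = frozenset(
    {"e.g", "i.e", "etc", "vs", "cf", "fig", "figs", "dr", "al", "ref", "no", "approx"}
)

_NUMBER_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")


@dataclass(frozen=True)
class Token:
    """A tokenized text unit with document-absolute character offsets."""

    text: str
    start: int
    end: int
    norm: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token span [{self.start}, {self.end})")
        if not self.norm:
            raise ValueError("token norm must be non-empty")


@dataclass
class Sentence:
    """An ordered run of tokens belonging to one document."""

    tokens: list[Token]
    doc_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def start(self) -> int:
        return self.tokens[0].start if self.tokens else 0

    @property
    def end(self) -> int:
        return self.tokens[-1].end if self.tokens else 0


@dataclass
class Document:
    """A title+abstract unit with sentences and gold mention annotations."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    gold_mentions: list = field(default_factory=list)

    @property
    def text(self) -> str:
        """Concatenated document text over which all offsets are interpreted."""
        if self.title and self.abstract:
            return self.title + " " + self.abstract
        return self.title or self.abstract


def split_sentences(
    text: str,
    abbreviations: frozenset[str] | set[str] = DEFAULT_SENTENCE_ABBREVS,
) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans, returned as (start, end) offsets.

    Rule-based: a sentence ends at ``.``, ``!`` or ``?`` followed by
    whitespace and an upper-case letter or digit, unless the word before the
    period is a known abbreviation or a single capital letter (initials).
    Spans are trimmed of surrounding whitespace; the terminal punctuation
    stays inside its sentence.
    """
    spans: list[tuple[int, int]] = []
    if not text:
        return spans
    n = len(text)
    start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch in ".!?":
            j = i + 1
            while j < n and text[j] in ".!?\")]'":
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            boundary = k > j and k < n and (text[k].isupper() or text[k].isdigit())
            if boundary and ch == ".":
                m = re.search(r"(\w[\w.]*)$", text[:i])
                prev = m.group(1).lower().rstrip(".") if m else ""
                if prev in abbreviations or (len(prev) == 1 and prev.isalpha()):
                    boundary = False
            if boundary:
                spans.append((start, j))
                start = k
                i = k
                continue
            i = j
        else:
            i += 1
    if start < n:
        spans.append((start, n))
    out = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            out.append((s, e))
    return out


def _is_delimiter(text: str, i: int, delimiters: set[str]) -> bool:
    ch = text[i]
    if ch not in delimiters:
        return False
    # Keep decimals intact: a period flanked by digits is part of a number.
    if ch == "." and 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
        return False
    return True


def tokenize(
    sentence_text: str,
    offset: int = 0,
    delimiters: set[str] = DEFAULT_DELIMITERS,
) -> list[Token]:
    """Tokenize on whitespace and punctuation delimiters, keeping delimiters.

    ``offset`` is the sentence start within the document; emitted token
    offsets are document-absolute.  Each delimiter character becomes its own
    single-character token; runs of other non-space characters become word
    tokens.  ``norm`` is initialized to ``text`` (see :func:`normalize_numbers`).
    """
    tokens: list[Token] = []
    n = len(sentence_text)
    i = 0
    while i < n:
        ch = sentence_text[i]
        if ch.isspace():
            i += 1
            continue
        if _is_delimiter(sentence_text, i, delimiters):
            tokens.append(Token(ch, offset + i, offset + i + 1, ch))
            i += 1
            continue
        j = i
        while (
            j < n
            and not sentence_text[j].isspace()
            and not _is_delimiter(sentence_text, j, delimiters)
        ):
            j += 1
        word = sentence_text[i:j]
        tokens.append(Token(word, offset + i, offset + j, word))
        i = j
    return tokens


def normalize_numbers(tokens: list[Token]) -> list[Token]:
    """Rewrite the ``norm`` of integer/decimal tokens to ``"num"``.

    The match is against the whole token only (optional sign, digits, at most
    one internal decimal point); mixed alphanumerics like ``p53`` are left
    alone.  ``text`` and offsets are never altered, so spans still resolve.
    Idempotent.
    """
    out = []
    for t in tokens:
        if _NUMBER_RE.match(t.text):
            out.append(Token(t.text, t.start, t.end, "num"))
        else:
            out.append(Token(t.text, t.start, t.end, t.text))
    return out


def preprocess_text(
    text: str,
    doc_id: str = "",
    delimiters: set[str] = DEFAULT_DELIMITERS,
) -> list[Sentence]:
    """Full pipeline: sentence split, tokenize, number-normalize."""
    sentences = []
    for s, e in split_sentences(text):
        toks = normalize_numbers(tokenize(text[s:e], offset=s, delimiters=delimiters))
        if toks:
            sentences.append(Sentence(toks, doc_id=doc_id))
    return sentences
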