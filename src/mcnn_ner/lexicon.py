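"""Disease-vocabulary loading and dictionary BIO tagging (the lexicon feature).

A vocabulary (MEDIC-style TSV with synonyms, or a plain one-term-per-line
list) is normalized with the same tokenizer and number transform as the
corpus, then token sequences are tagged greedily leftmost-longest: each
matched term span becomes ``B I ... I``, everything else ``O``.  The
resulting per-token label is later embedded as a learned 5-dimensional
vector and concatenated to the word representation.
"""

from __future__ import annotations

import logging

from .preprocess import DEFAULT_DELIMITERS, Sentence, normalize_numbers, tokenize

logger = logging.getLogger(__name__)

__all__ = ["Lexicon", "load_lexicon", "dict_tag", "normalize_term"]


def normalize_term(term: str, delimiters: set[str] = DEFAULT_DELIMITERS) -> tuple[str, ...]:
    """Normalize a vocabulary term to a lowercased token-norm sequence."""
    toks = normalize_numbers(tokenize(term, delimiters=delimiters))
    return tuple(t.norm.lower() for t in toks)


class Lexicon:
    """A set of normalized term token-sequences for dictionary matching."""

    def __init__(self, terms=(), name: str = "lexicon"):
        self.terms: set[tuple[str, ...]] = {t for t in terms if t}
        self.name = name
        # max term length bounds the longest-match search
        self._max_len = max((len(t) for t in self.terms), default=0)

    @property
    def size(self) -> int:
        return len(self.terms)

    def add(self, term: str) -> None:
        norm = normalize_term(term)
        if norm:
            self.terms.add(norm)
            self._max_len = max(self._max_len, len(norm))

    def __contains__(self, seq) -> bool:
        return tuple(seq) in self.terms

    def __len__(self) -> int:
        return self.size


def load_lexicon(
    path,
    format: str = "plain",
    name_col: int = 0,
    synonyms_col: int = 7,
) -> Lexicon:
    """Load a vocabulary file into a :class:`Lexicon`.

    ``format="plain"``: one term per line.  ``format="medic"``: TSV with a
    primary-name column and a pipe-separated synonyms column (defaults match
    the MEDIC distribution: DiseaseName first, Synonyms eighth); ``#``
    comment lines are skipped.  Duplicate terms collapse.
    """
    lex = Lexicon(name=str(path))
    if format not in ("plain", "medic"):
        raise ValueError(f"unknown lexicon format: {format!r}")
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if format == "plain":
                lex.add(line.strip())
            else:
                cols = line.split("\t")
                if name_col < len(cols) and cols[name_col].strip():
                    lex.add(cols[name_col].strip())
                if synonyms_col < len(cols):
                    for syn in cols[synonyms_col].split("|"):
                        if syn.strip():
                            lex.add(syn.strip())
    if lex.size == 0:
        logger.warning("empty lexicon loaded from %s", path)
    return lex


def dict_tag(sentence: Sentence, lex: Lexicon) -> list[str]:
    """Tag tokens with dictionary-match B/I/O labels.

    Greedy left-to-right longest match over lowercased normalized tokens;
    matches never overlap.  Applied identically at train and predict time.
    """
    norms = [t.norm.lower() for t in sentence.tokens]
    n = len(norms)
    labels = ["O"] * n
    i = 0
    while i < n:
        best = 0
        for length in range(min(lex._max_len, n - i), 0, -1):
            if tuple(norms[i : i + length]) in lex.terms:
                best = length
                break
        if best:
            labels[i] = "B"
            for j in range(i + 1, i + best):
                labels[j] = "I"
            i += best
        else:
            i += 1
    return labels
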