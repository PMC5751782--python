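"""PubTator-style corpus reading/writing and BIO label projection.

The PubTator dialect stores one document per block::

    PMID|t|Title text
    PMID|a|Abstract text
    PMID<TAB>start<TAB>end<TAB>mention text<TAB>type[<TAB>concept id]

with a blank line between documents.  Character offsets are 0-based,
half-open, over ``title + " " + abstract``.  Concept identifiers are ignored
here; only annotations of the configured type(s) are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .preprocess import (
    DEFAULT_DELIMITERS,
    Document,
    Sentence,
    normalize_numbers,
    split_sentences,
    tokenize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Mention",
    "LabeledSentence",
    "PubTatorFormatError",
    "read_pubtator",
    "write_pubtator",
    "tokenize_document",
    "project_mentions_to_bio",
    "write_conll",
    "read_conll",
    "corpus_stats",
]

LABELS = ("B", "I", "O")


@dataclass(frozen=True)
class Mention:
    """An annotated entity span; the unit of exact-match evaluation."""

    doc_id: str
    start: int
    end: int
    text: str
    type: str = "Disease"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty mention span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.doc_id, self.start, self.end)


@dataclass
class LabeledSentence:
    """A sentence paired with one B/I/O label per token."""

    sentence: Sentence
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sentence.tokens):
            raise ValueError("labels/tokens length mismatch")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"labels outside {{B,I,O}}: {bad}")


class PubTatorFormatError(ValueError):
    pass


def read_pubtator(path, mention_types: set[str] | None = frozenset({"Disease"})) -> list[Document]:
    """Read a PubTator-style file into :class:`Document` objects.

    Annotations whose type is not in ``mention_types`` are dropped
    (``None`` keeps everything).  A mention whose text does not match the
    document text at its offsets triggers a warning but is kept.  Malformed
    lines raise :class:`PubTatorFormatError` with the line number.
    """
    docs: dict[str, Document] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if "|t|" in line or "|a|" in line:
                pmid, kind, text = line.split("|", 2)
                if pmid not in docs:
                    docs[pmid] = Document(doc_id=pmid)
                    order.append(pmid)
                if kind == "t":
                    docs[pmid].title = text
                else:
                    docs[pmid].abstract = text
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise PubTatorFormatError(
                    f"{path}:{lineno}: expected >=5 tab-separated fields, got {len(parts)}"
                )
            pmid, start_s, end_s, text, mtype = parts[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PubTatorFormatError(f"{path}:{lineno}: non-integer offsets") from exc
            if pmid not in docs:
                raise PubTatorFormatError(f"{path}:{lineno}: annotation before title for {pmid}")
            if mention_types is not None and mtype not in mention_types:
                continue
            mention = Mention(pmid, start, end, text, mtype)
            doc_text = docs[pmid].text
            if doc_text[start:end] != text:
                logger.warning(
                    "%s:%d: mention text %r != document span %r",
                    path,
                    lineno,
                    text,
                    doc_text[start:end],
                )
            docs[pmid].gold_mentions.append(mention)
    return [docs[pmid] for pmid in order]


def write_pubtator(docs: list[Document], mentions_by_doc: dict[str, list[Mention]], path) -> None:
    """Write documents plus per-document mention annotations in PubTator format."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in sorted(mentions_by_doc.get(doc.doc_id, []), key=lambda m: (m.start, m.end)):
                fh.write(f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.type}\n")
            fh.write("\n")


def tokenize_document(doc: Document, delimiters: set[str] = DEFAULT_DELIMITERS) -> Document:
    """Populate ``doc.sentences`` with preprocessed tokens.

    Sentences are merged when a gold mention crosses a sentence-splitter
    boundary, so that every gold mention stays within one sentence and
    exact-span evaluation remains possible.
    """
    text = doc.text
    spans = split_sentences(text)
    if doc.gold_mentions:
        spans = _merge_spans_for_mentions(spans, doc.gold_mentions)
    doc.sentences = []
    for s, e in spans:
        toks = normalize_numbers(tokenize(text[s:e], offset=s, delimiters=delimiters))
        if toks:
            doc.sentences.append(Sentence(toks, doc_id=doc.doc_id))
    return doc


def _merge_spans_for_mentions(spans, mentions) -> list[tuple[int, int]]:
    spans = list(spans)
    changed = True
    while changed:
        changed = False
        for m in mentions:
            for i in range(len(spans) - 1):
                s1, e1 = spans[i]
                s2, e2 = spans[i + 1]
                if m.start < e1 and m.end > s2:
                    spans[i : i + 2] = [(s1, e2)]
                    changed = True
                    break
            if changed:
                break
    return spans


def _resolve_overlaps(mentions: list[Mention]) -> list[Mention]:
    """Leftmost-longest-first resolution; overlap losers dropped with a warning."""
    ordered = sorted(mentions, key=lambda m: (m.start, -(m.end - m.start)))
    kept: list[Mention] = []
    for m in ordered:
        if any(m.start < k.end and m.end > k.start for k in kept):
            logger.warning("dropping overlapping gold mention %r in %s", m.text, m.doc_id)
            continue
        kept.append(m)
    return kept


def project_mentions_to_bio(doc: Document) -> list[LabeledSentence]:
    """Project character-offset gold mentions onto tokens as B/I/O labels.

    A token overlapping a mention is inside it; the first overlapping token
    gets B, the rest I.  A mention boundary strictly inside a token is
    clipped to the token with a warning.  Overlapping gold mentions are
    resolved leftmost-longest-first before projection.
    """
    mentions = _resolve_overlaps(doc.gold_mentions)
    labelled = []
    for sent in doc.sentences:
        labels = ["O"] * len(sent.tokens)
        for m in mentions:
            first = True
            for i, t in enumerate(sent.tokens):
                if t.start < m.end and t.end > m.start:
                    if t.start < m.start < t.end or t.start < m.end < t.end:
                        logger.warning(
                            "mention %r boundary inside token %r (%s); clipped",
                            m.text,
                            t.text,
                            doc.doc_id,
                        )
                    labels[i] = "B" if first else "I"
                    first = False
        labelled.append(LabeledSentence(sent, labels))
    return labelled


def write_conll(sentences: list[LabeledSentence], path) -> None:
    """Write token<TAB>label lines, blank line between sentences."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, ls in enumerate(sentences):
            if i:
                fh.write("\n")
            for tok, lab in zip(ls.sentence.tokens, ls.labels):
                fh.write(f"{tok.text}\t{lab}\n")


def read_conll(path) -> list[tuple[list[str], list[str]]]:
    """Read (tokens, labels) pairs back from CoNLL-style TSV (lossless in labels)."""
    out: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    labs: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if toks:
                    out.append((toks, labs))
                    toks, labs = [], []
                continue
            tok, lab = line.split("\t")
            toks.append(tok)
            labs.append(lab)
    if toks:
        out.append((toks, labs))
    return out


def corpus_stats(docs: list[Document]) -> dict[str, int]:
    """Abstract and mention counts, for sanity-checking a loaded release."""
    return {
        "abstracts": len(docs),
        "mentions": sum(len(d.gold_mentions) for d in docs),
    }
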