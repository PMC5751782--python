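"""Post-processing: BIO sequence repair, abbreviation propagation, span decoding.

A window classifier predicts each token's label independently, so raw
output can contain structurally illegal sequences — above all an ``I`` not
preceded by ``B`` or ``I``.  :func:`repair_illegal` zeroes such orphans to
``O`` (and, in strict mode, also the second ``B`` of a ``B B`` bigram).
After repair, maximal ``B I*`` runs decode into character-span mentions.

Abbreviation propagation recovers short forms the tagger misses: when the
long form of a parenthesized abbreviation definition is recognized as a
disease mention, every later occurrence of the short form in the document
is labeled as a disease too.  Definitions are found with the standard
parenthesis long-form/short-form alignment heuristic (Schwartz–Hearst).
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import Mention
from .preprocess import Document, Sentence

__all__ = [
    "AbbrevPair",
    "repair_illegal",
    "bio_to_mentions",
    "extract_abbreviations",
    "propagate_abbreviations",
]

_VALID = {"B", "I", "O"}


@dataclass(frozen=True)
class AbbrevPair:
    """A long-form/short-form pair from a parenthesized definition."""

    doc_id: str
    long_start: int  # char span of the long form
    long_end: int
    long_text: str
    short_form: str


def repair_illegal(labels: list[str], strict_bb: bool = False) -> tuple[list[str], int]:
    """Set structurally illegal labels to O; returns (labels', n changed).

    Default mode: every ``I`` whose predecessor is neither ``B`` nor ``I``
    (including a sentence-initial ``I``) becomes ``O``, applied
    left-to-right until stable.  Strict mode additionally treats ``B B`` as
    illegal and turns the second ``B`` into ``O``.  Idempotent.
    """
    bad = set(labels) - _VALID
    if bad:
        raise ValueError(f"unknown label symbols: {bad}")
    out = list(labels)
    n_fixed = 0
    changed = True
    while changed:
        changed = False
        prev = "O"
        for i, lab in enumerate(out):
            if lab == "I" and prev not in ("B", "I"):
                out[i] = "O"
                n_fixed += 1
                changed = True
            elif strict_bb and lab == "B" and prev == "B":
                out[i] = "O"
                n_fixed += 1
                changed = True
            prev = out[i]
    return out, n_fixed


def bio_to_mentions(sentence: Sentence, labels: list[str], doc_id: str | None = None) -> list[Mention]:
    """Decode each maximal ``B I*`` run into one exact character-span mention.

    Labels must have been repaired first; an orphan ``I`` is a contract
    violation and raises.
    """
    if len(labels) != len(sentence.tokens):
        raise ValueError("labels/tokens length mismatch")
    doc_id = sentence.doc_id if doc_id is None else doc_id
    mentions: list[Mention] = []
    run_start: int | None = None
    run_end: int | None = None
    prev = "O"
    for tok, lab in zip(sentence.tokens, labels):
        if lab == "I" and prev not in ("B", "I"):
            raise ValueError("orphan I label: run repair_illegal first")
        if lab == "B":
            if run_start is not None:
                mentions.append(Mention(doc_id, run_start, run_end, text=""))
            run_start, run_end = tok.start, tok.end
        elif lab == "I":
            run_end = tok.end
        else:
            if run_start is not None:
                mentions.append(Mention(doc_id, run_start, run_end, text=""))
                run_start = None
        prev = lab
    if run_start is not None:
        mentions.append(Mention(doc_id, run_start, run_end, text=""))
    return mentions


def _fill_texts(mentions: list[Mention], doc_text: str) -> list[Mention]:
    return [
        Mention(m.doc_id, m.start, m.end, doc_text[m.start : m.end], m.type) for m in mentions
    ]


def decode_document(doc: Document, labels_per_sentence: list[list[str]]) -> list[Mention]:
    """Repair + decode all sentences of a document into text-filled mentions."""
    mentions: list[Mention] = []
    for sent, labels in zip(doc.sentences, labels_per_sentence):
        repaired, _ = repair_illegal(labels)
        mentions.extend(bio_to_mentions(sent, repaired, doc_id=doc.doc_id))
    return _fill_texts(mentions, doc.text)


def extract_abbreviations(
    doc: Document,
    min_len: int = 2,
    max_len: int = 10,
) -> list[AbbrevPair]:
    """Find parenthesized short-form definitions by character alignment.

    For each ``( SF )`` whose short form is ``min_len``–``max_len``
    characters with at least one letter, the short form's alphanumeric
    characters are aligned in order into the tokens before the parenthesis
    (rightmost match, the classic parenthesis heuristic).  A pair is emitted
    when all characters match and the long form spans at most
    ``min(|SF| + 5, 2 * |SF|)`` words.
    """
    pairs: list[AbbrevPair] = []
    text = doc.text
    for sent in doc.sentences:
        toks = sent.tokens
        for i, tok in enumerate(toks):
            if tok.text != "(" or i == 0 or i + 2 >= len(toks) + 1:
                continue
            # short form = the tokens up to the matching ")"
            j = i + 1
            depth = 1
            inner: list = []
            while j < len(toks) and depth:
                if toks[j].text == "(":
                    depth += 1
                elif toks[j].text == ")":
                    depth -= 1
                    if depth == 0:
                        break
                inner.append(toks[j])
                j += 1
            if depth != 0 or not inner:
                continue
            sf = text[inner[0].start : inner[-1].end]
            if not (min_len <= len(sf) <= max_len) or not any(c.isalpha() for c in sf):
                continue
            max_words = min(len(sf) + 5, 2 * len(sf))
            span = _align_long_form(toks[:i], sf, max_words)
            if span is not None:
                s, e = span
                pairs.append(AbbrevPair(doc.doc_id, s, e, text[s:e], sf))
    return pairs


def _align_long_form(prev_tokens, sf: str, max_words: int):
    """Rightward alignment of the short form's alphanumerics into the
    preceding tokens; returns the (start, end) char span of the long form or
    None."""
    cand = prev_tokens[-max_words:]
    if not cand:
        return None
    chars = [c.lower() for c in sf if c.isalnum()]
    if not chars:
        return None
    long_text_tokens = cand
    # scan right-to-left over the candidate characters, consuming SF chars
    flat = []
    for ti, tok in enumerate(long_text_tokens):
        for ci, ch in enumerate(tok.text):
            flat.append((ti, ci, ch.lower()))
    ci = len(chars) - 1
    fi = len(flat) - 1
    first_ti = None
    while fi >= 0 and ci >= 0:
        ti, tci, ch = flat[fi]
        if ch == chars[ci]:
            # the first SF char must start a word (anchors the long form)
            if ci == 0 and tci != 0:
                fi -= 1
                continue
            if ci == 0:
                first_ti = ti
            ci -= 1
        fi -= 1
    if ci >= 0 or first_ti is None:
        return None
    start_tok = long_text_tokens[first_ti]
    end_tok = long_text_tokens[-1]
    n_words = len(long_text_tokens) - first_ti
    if n_words > max_words:
        return None
    return start_tok.start, end_tok.end


def propagate_abbreviations(
    doc: Document,
    mentions: list[Mention],
    pairs: list[AbbrevPair],
) -> list[Mention]:
    """Label every short-form occurrence as a disease when its long form was
    recognized.

    Document-scoped: a pair fires only if some predicted mention span equals
    its long-form span exactly; then each occurrence of the short form (as a
    whole token run) becomes a mention unless the span already overlaps a
    predicted mention.  Never removes a mention.
    """
    spans = {(m.start, m.end) for m in mentions}
    out = list(mentions)
    covered = [(m.start, m.end) for m in mentions]
    text = doc.text
    for pair in pairs:
        if (pair.long_start, pair.long_end) not in spans:
            continue
        sf = pair.short_form
        for sent in doc.sentences:
            toks = sent.tokens
            for i in range(len(toks)):
                for j in range(i, len(toks)):
                    span_text = text[toks[i].start : toks[j].end]
                    if span_text == sf:
                        s, e = toks[i].start, toks[j].end
                        if not any(s < ce and e > cs for cs, ce in covered):
                            m = Mention(doc.doc_id, s, e, sf)
                            out.append(m)
                            covered.append((s, e))
                        break
                    if len(span_text) > len(sf):
                        break
    return out
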