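"""Seeded synthetic corpus generation for end-to-end testing without downloads.

The generator emits PubTator-style documents with exact character-offset
gold annotations that emulate the structural properties of disease NER
corpora: multi-token mentions (1-5 tokens, occasionally hyphenated),
parenthesized abbreviation definitions whose short forms recur later in the
document, numeric tokens, and a disease vocabulary with only partial
coverage of the gold mention types.  Disease-name tokens and distractor
(context) tokens are built from disjoint syllable inventories, so the
tagging task is learnable from word identity plus context — by design much
easier than real biomedical text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus_io import Mention, write_pubtator
from .lexicon import Lexicon, normalize_term
from .preprocess import Document

__all__ = ["SynthConfig", "gen_lexicon", "gen_corpus", "generate"]

# Disjoint syllable inventories: disease-name tokens vs context tokens.
_DISEASE_SYLLABLES = [
    "car", "cino", "myo", "neuro", "fibro", "lymph", "oma", "itis", "osis",
    "pathy", "algia", "emia", "derma", "gastro", "hepa", "nephro", "sclero",
    "dys", "trophy", "plasia", "megaly", "spasm",
]
_CONTEXT_SYLLABLES = [
    "ta", "ben", "lor", "mi", "sun", "vel", "dor", "pin", "ral", "ket",
    "fam", "wos", "zun", "hib", "nal", "tup", "ser", "gol", "vin", "rud",
]


@dataclass
class SynthConfig:
    """Generator settings; defaults give a corpus in which a default model
    is expected to reach a high mention F-score within a few epochs."""

    n_docs: int = 100
    sentences_per_doc: int = 10
    lexicon_size: int = 150
    mention_rate: float = 0.7
    mention_length_dist: tuple[float, ...] = (0.40, 0.30, 0.15, 0.10, 0.05)
    lexicon_coverage: float = 0.7
    abbrev_rate: float = 0.10
    number_rate: float = 0.15
    vocab_size: int = 300
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("mention_rate", "lexicon_coverage", "abbrev_rate", "number_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.mention_length_dist) - 1.0) > 1e-9:
            raise ValueError("mention_length_dist must sum to 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _make_word(rng: np.random.Generator, syllables: list[str]) -> str:
    n = int(rng.integers(2, 4))
    return "".join(rng.choice(syllables) for _ in range(n))


def _make_term(rng: np.random.Generator) -> str:
    """A pronounceable fake disease name of 1-5 space-separated tokens,
    occasionally with an internal hyphen to exercise the tokenizer."""
    length = int(rng.choice(5, p=(0.40, 0.30, 0.15, 0.10, 0.05))) + 1
    words = [_make_word(rng, _DISEASE_SYLLABLES) for _ in range(length)]
    if length >= 2 and rng.random() < 0.2:
        i = int(rng.integers(0, length - 1))
        words[i : i + 2] = [words[i] + "-" + words[i + 1]]
    return " ".join(words)


def gen_lexicon(cfg: SynthConfig) -> tuple[list[str], Lexicon]:
    """Generate the full disease-term list and its partial-coverage lexicon.

    The emitted lexicon contains ``round(coverage * lexicon_size)`` of the
    full terms; the remainder emulates vocabulary gaps of a real dictionary.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    terms: list[str] = []
    seen = set()
    while len(terms) < cfg.lexicon_size:
        t = _make_term(rng)
        if t not in seen:
            seen.add(t)
            terms.append(t)
    n_emit = round(cfg.lexicon_coverage * len(terms))
    emitted_idx = rng.choice(len(terms), size=n_emit, replace=False)
    lex = Lexicon((normalize_term(terms[i]) for i in sorted(emitted_idx)), name="synthetic")
    return terms, lex


def _short_form(term: str) -> str:
    return "".join(w[0].upper() for w in term.replace("-", " ").split())


@dataclass
class _SentencePlan:
    text: str = ""
    mentions: list[tuple[int, int, str]] = field(default_factory=list)  # sentence-local


def _gen_sentence(
    rng: np.random.Generator,
    cfg: SynthConfig,
    context_vocab: list[str],
    terms: list[str],
    pending_sf: list[str],
) -> _SentencePlan:
    plan = _SentencePlan()
    n_ctx = int(rng.integers(4, 9))
    words = [str(rng.choice(context_vocab)) for _ in range(n_ctx)]
    words[0] = words[0].capitalize()

    inserts: list[tuple[str, str]] = []  # (kind, payload)
    if rng.random() < cfg.mention_rate:
        length = int(rng.choice(5, p=cfg.mention_length_dist)) + 1
        candidates = [t for t in terms if len(t.split()) == length] or terms
        inserts.append(("mention", str(rng.choice(candidates))))
    if rng.random() < cfg.number_rate:
        if rng.random() < 0.5:
            inserts.append(("plain", str(int(rng.integers(1, 1000)))))
        else:
            inserts.append(("plain", f"{rng.integers(1, 100)}.{rng.integers(0, 10)}"))
    if pending_sf and rng.random() < 0.5:
        inserts.append(("sf_mention", pending_sf.pop(0)))

    pieces: list[tuple[str, str]] = [("plain", w) for w in words]
    for kind, payload in inserts:
        pos = int(rng.integers(1, len(pieces) + 1))
        pieces.insert(pos, (kind, payload))

    parts: list[str] = []
    offset = 0
    for kind, payload in pieces:
        if parts:
            offset += 1  # joining space
        if kind == "mention":
            plan.mentions.append((offset, offset + len(payload), payload))
            if rng.random() < cfg.abbrev_rate and len(payload.split()) >= 2:
                sf = _short_form(payload)
                if len(sf) >= 2:
                    defn = payload + " (" + sf + ")"
                    plan.mentions.append(
                        (offset + len(payload) + 2, offset + len(defn) - 1, sf)
                    )
                    pending_sf.append(sf)
                    payload = defn
        elif kind == "sf_mention":
            plan.mentions.append((offset, offset + len(payload), payload))
        parts.append(payload)
        offset += len(payload)
    plan.text = " ".join(parts) + "."
    return plan


def gen_corpus(cfg: SynthConfig, term_list: list[str] | None = None) -> list[Document]:
    """Generate documents with exact gold mention offsets.

    Mentions never cross sentence boundaries and never start a sentence (so
    surface capitalization never mangles a gold span).  Offsets are over
    ``title + " " + abstract``, matching the PubTator convention.
    """
    rng = np.random.default_rng(cfg.seed + 1 if term_list is not None else cfg.seed)
    if term_list is None:
        term_list, _ = gen_lexicon(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
    context_vocab = []
    seen: set[str] = set()
    while len(context_vocab) < cfg.vocab_size:
        w = _make_word(rng, _CONTEXT_SYLLABLES)
        if w not in seen:
            seen.add(w)
            context_vocab.append(w)

    docs: list[Document] = []
    for d in range(cfg.n_docs):
        doc_id = f"SYN{d:05d}"
        title_words = [str(rng.choice(context_vocab)) for _ in range(int(rng.integers(3, 6)))]
        title = (" ".join(title_words) + ".").capitalize()
        pending_sf: list[str] = []
        sentence_plans = [
            _gen_sentence(rng, cfg, context_vocab, term_list, pending_sf)
            for _ in range(cfg.sentences_per_doc)
        ]
        abstract = " ".join(p.text for p in sentence_plans)
        doc = Document(doc_id=doc_id, title=title, abstract=abstract)
        base = len(title) + 1
        offset = 0
        for p in sentence_plans:
            for s, e, text in p.mentions:
                doc.gold_mentions.append(Mention(doc_id, base + offset + s, base + offset + e, text))
            offset += len(p.text) + 1
        docs.append(doc)
    return docs


def generate(cfg: SynthConfig, out_dir=None) -> tuple[list[Document], Lexicon, list[str]]:
    """Full generation; optionally writes corpus.pubtator, lexicon.tsv and
    manifest.json (seed + config echo) to ``out_dir``."""
    terms, lex = gen_lexicon(cfg)
    docs = gen_corpus(cfg, terms)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pubtator(docs, {d.doc_id: d.gold_mentions for d in docs}, out / "corpus.pubtator")
        with open(out / "lexicon.tsv", "w", encoding="utf-8") as fh:
            for term in sorted(" ".join(t) for t in lex.terms):
                fh.write(term + "\n")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"config": asdict(cfg), "n_terms": len(terms)}, fh, indent=2)
    return docs, lex, terms
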