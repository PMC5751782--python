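"""End-to-end orchestration: preprocess -> encode -> train -> predict -> score.

Thin glue over the stage modules so the CLI, the test-suite and user
scripts share one code path.  All functions are deterministic given the
config seed.
"""

from __future__ import annotations

import logging

import numpy as np

from . import postprocess as pp
from .corpus_io import LabeledSentence, Mention, project_mentions_to_bio, tokenize_document
from .encoding import TrainingInstance, Vocab, build_vocabs, encode_windows
from .evaluation import PRF, mention_prf
from .lexicon import Lexicon, dict_tag
from .model import ModelConfig, fit, pack_batch, predict_labels
from .preprocess import Document

logger = logging.getLogger(__name__)

__all__ = [
    "prepare_documents",
    "encode_corpus",
    "train",
    "predict_document",
    "predict_raw_labels",
    "evaluate_documents",
    "ablate",
]


def prepare_documents(docs: list[Document]) -> list[Document]:
    """Tokenize + number-normalize every document in place."""
    for doc in docs:
        tokenize_document(doc)
    return docs


def _labelled(docs: list[Document]) -> list[LabeledSentence]:
    out = []
    for doc in docs:
        out.extend(project_mentions_to_bio(doc))
    return out


def encode_corpus(
    docs: list[Document],
    vocab: Vocab,
    config: ModelConfig,
    lexicon: Lexicon | None = None,
) -> list[TrainingInstance]:
    """Window instances for every token of every (gold-labelled) sentence."""
    instances: list[TrainingInstance] = []
    for si, ls in enumerate(_labelled(docs)):
        lex_labels = (
            dict_tag(ls.sentence, lexicon) if (lexicon and config.use_lexicon) else None
        )
        instances.extend(
            encode_windows(ls, vocab, window=config.window, lex_labels=lex_labels, sent_index=si)
        )
    return instances


def train(
    train_docs: list[Document],
    config: ModelConfig,
    lexicon: Lexicon | None = None,
    dev_docs: list[Document] | None = None,
    word_table: np.ndarray | None = None,
    word_vectors_path=None,
) -> tuple[dict, Vocab]:
    """Train on gold-annotated documents; returns (params, vocab).

    When ``dev_docs`` is given, mention-level F on it is logged per epoch and
    the best-epoch parameters are returned.  ``word_vectors_path`` loads
    pre-trained vectors for the training vocabulary (missing words randomly
    initialized); otherwise the word table starts random unless
    ``word_table`` is supplied directly.
    """
    prepare_documents(train_docs)
    vocab = build_vocabs(_labelled(train_docs))
    if word_vectors_path is not None:
        from .encoding import load_word_vectors

        word_table = load_word_vectors(
            word_vectors_path, vocab, dim=config.word_dim, seed=config.seed
        )
    instances = encode_corpus(train_docs, vocab, config, lexicon)
    dev_eval = None
    if dev_docs is not None:
        prepare_documents(dev_docs)
        dev_gold = [m for d in dev_docs for m in d.gold_mentions]

        def dev_eval(params):
            pred = []
            for doc in dev_docs:
                pred.extend(predict_document(doc, params, config, vocab, lexicon))
            return mention_prf(pred, dev_gold).f

    params = fit(instances, config, vocab, dev_eval=dev_eval, word_table=word_table)
    return params, vocab


def _sentence_instances(doc, vocab, config, lexicon):
    for sent in doc.sentences:
        dummy = LabeledSentence(sent, ["O"] * len(sent.tokens))
        lex_labels = dict_tag(sent, lexicon) if (lexicon and config.use_lexicon) else None
        yield sent, encode_windows(dummy, vocab, window=config.window, lex_labels=lex_labels)


def predict_raw_labels(
    doc: Document,
    params: dict,
    config: ModelConfig,
    vocab: Vocab,
    lexicon: Lexicon | None = None,
) -> list[list[str]]:
    """Per-sentence raw label sequences (no repair) for a tokenized document."""
    return [
        predict_labels(instances, params, config)
        for _, instances in _sentence_instances(doc, vocab, config, lexicon)
    ]


def predict_document(
    doc: Document,
    params: dict,
    config: ModelConfig,
    vocab: Vocab,
    lexicon: Lexicon | None = None,
    repair: bool = True,
    strict_bb: bool = False,
    abbrev: bool = False,
) -> list[Mention]:
    """Predict mention spans for one tokenized document.

    ``repair`` applies the illegal-sequence fix before decoding; without it
    (post-processing ablated) an orphan I run is decoded leniently as if it
    began with B.  ``abbrev`` additionally propagates recognized long forms
    to their short-form occurrences.
    """
    mentions: list[Mention] = []
    for sent, instances in _sentence_instances(doc, vocab, config, lexicon):
        labels = predict_labels(instances, params, config)
        if repair:
            labels, _ = pp.repair_illegal(labels, strict_bb=strict_bb)
        else:
            prev = "O"
            labels = [
                ("B" if (lab == "I" and prev not in ("B", "I")) else lab)
                for prev, lab in zip(["O"] + labels[:-1], labels)
            ]
        mentions.extend(pp.bio_to_mentions(sent, labels, doc_id=doc.doc_id))
    mentions = pp._fill_texts(mentions, doc.text)
    if abbrev:
        pairs = pp.extract_abbreviations(doc)
        mentions = pp.propagate_abbreviations(doc, mentions, pairs)
    return mentions


def evaluate_documents(
    docs: list[Document],
    params: dict,
    config: ModelConfig,
    vocab: Vocab,
    lexicon: Lexicon | None = None,
    **predict_kwargs,
) -> PRF:
    """Micro-averaged exact-span PRF of the model over tokenized documents."""
    pred: list[Mention] = []
    gold: list[Mention] = []
    for doc in docs:
        pred.extend(predict_document(doc, params, config, vocab, lexicon, **predict_kwargs))
        gold.extend(doc.gold_mentions)
    return mention_prf(pred, gold)


def ablate(
    train_docs: list[Document],
    test_docs: list[Document],
    config: ModelConfig,
    lexicon: Lexicon | None = None,
) -> list[dict]:
    """Re-train and score with each feature/strategy removed in turn.

    Rows: the full model, then one per single toggle off (character-level
    representation, lexicon feature, the auxiliary multi-label objective,
    post-processing).  Each row reports P/R/F and the F drop vs. the full
    model.
    """
    rows: list[dict] = []

    def run(name: str, cfg: ModelConfig, use_postprocess: bool = True) -> dict:
        tdocs = [_clone_doc(d) for d in train_docs]
        edocs = [_clone_doc(d) for d in test_docs]
        params, vocab = train(tdocs, cfg, lexicon if cfg.use_lexicon else None)
        prepare_documents(edocs)
        prf = evaluate_documents(
            edocs,
            params,
            cfg,
            vocab,
            lexicon if cfg.use_lexicon else None,
            repair=use_postprocess,
            abbrev=use_postprocess,
        )
        return {
            "ablation": name,
            "precision": prf.precision,
            "recall": prf.recall,
            "f": prf.f,
        }

    full = run("none", config)
    rows.append({**full, "delta_f": 0.0})
    for name, cfg, use_post in [
        ("character-level", _replace(config, use_char=False), True),
        ("lexicon", _replace(config, use_lexicon=False), True),
        ("mls", _replace(config, use_mls=False), True),
        ("post-processing", config, False),
    ]:
        row = run(name, cfg, use_post)
        rows.append({**row, "delta_f": full["f"] - row["f"]})
    return rows


def _replace(config: ModelConfig, **kw) -> ModelConfig:
    from dataclasses import replace

    return replace(config, **kw)


def _clone_doc(doc: Document) -> Document:
    return Document(
        doc_id=doc.doc_id,
        title=doc.title,
        abstract=doc.abstract,
        gold_mentions=list(doc.gold_mentions),
    )
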