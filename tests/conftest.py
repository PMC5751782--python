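import numpy as np
import pytest

from mcnn_ner.encoding import TrainingInstance, Vocab
from mcnn_ner.model import ModelConfig


@pytest.fixture
def tiny_vocab() -> Vocab:
    v = Vocab()
    for w in ["alpha", "beta", "gamma", "delta"]:
        v.add_word(w)
    for ch in "abgdxyz":
        v.add_char(ch)
    return v


@pytest.fixture
def tiny_config() -> ModelConfig:
    """A model small enough for finite-difference checks (window 5, 2 char
    filters, 3 word filters, 1 conv layer, float64, no dropout)."""
    return ModelConfig(
        window=5,
        word_dim=6,
        char_dim=4,
        char_cnn_filters=2,
        word_conv_filters=3,
        n_conv_layers=1,
        lex_dim=2,
        dropout_rate=0.0,
        dtype="float64",
        seed=0,
    )


def random_instance(rng: np.random.Generator, vocab: Vocab, window: int = 5) -> TrainingInstance:
    return TrainingInstance(
        word_ids=rng.integers(0, vocab.n_words, window),
        char_ids=[
            list(rng.integers(0, vocab.n_chars, int(rng.integers(1, 6)))) for _ in range(window)
        ],
        lex_ids=np.asarray(rng.integers(0, 3, window)),
        y=int(rng.integers(0, 3)),
        y_aux=int(rng.integers(0, 9)),
        y_prev=int(rng.integers(0, 3)),
        y_next=int(rng.integers(0, 3)),
    )


def make_pubtator(docs: list[tuple[str, str, str, list[str]]]) -> str:
    """Build PubTator text; each doc is (pmid, title, abstract, mention
    texts).  Every occurrence of each mention text in title+" "+abstract is
    annotated, with offsets computed here rather than by hand."""
    blocks = []
    for pmid, title, abstract, mention_texts in docs:
        text = title + " " + abstract
        lines = [f"{pmid}|t|{title}", f"{pmid}|a|{abstract}"]
        anns = []
        for mt in mention_texts:
            start = 0
            while (idx := text.find(mt, start)) != -1:
                anns.append((idx, idx + len(mt), mt))
                start = idx + 1
        for s, e, mt in sorted(set(anns)):
            lines.append(f"{pmid}\t{s}\t{e}\t{mt}\tDisease")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


FIXTURE_DOCS = [
    (
        "1001",
        "Colorectal cancer risk in families.",
        "We studied colorectal cancer and anemia in 164 patients.",
        ["Colorectal cancer", "colorectal cancer", "anemia"],
    ),
    (
        "1002",
        "A study of inflammatory bowel disease (IBD) cohorts.",
        "Patients with IBD were followed. The IBD relapse rate was 81.6 percent.",
        ["inflammatory bowel disease", "IBD"],
    ),
]


@pytest.fixture
def pubtator_file(tmp_path):
    p = tmp_path / "corpus.pubtator"
    p.write_text(make_pubtator(FIXTURE_DOCS), encoding="utf-8")
    return p
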