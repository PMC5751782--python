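"""The multi-label CNN tagger: forward pass, analytic gradients, SGD training.

Architecture, per window instance of ``window`` tokens (default 13):

1. each token is the concatenation of its word embedding (200), a
   character-CNN representation (conv window 3, 20 filters, max over
   positions) and a dictionary-label embedding (5) -> 225 dims;
2. dropout on the concatenation (and on character embeddings inside the
   char-CNN), training mode only;
3. a stack of 1-D convolutions (window 3, 100 filters, valid padding, ReLU)
   with *no pooling*, shrinking 13 -> 11 -> 9 -> 7 positions for 3 layers;
4. flatten, then two affine heads: the main head scores the center token's
   B/I/O label (z=3) and the auxiliary head scores the joint
   (previous, next) label pair (k=9) — the multiple-label strategy that
   replaces a CRF decoding layer.

Training maximizes the joint log-likelihood
``J = sum_i log p_main(y_i | x_i) + sum_i log p_aux(y_aux_i | x_i)``
by mini-batch SGD on ``-J``; the auxiliary head is a training-time signal
only and is discarded at inference, where the label is the argmax of the
main head (ties broken toward O, then B).

Everything is plain numpy; gradients are derived by hand and verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .encoding import (
    ID_TO_LABEL,
    N_AUX,
    N_LABELS,
    TrainingInstance,
    Vocab,
    random_embedding,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "OutputScores",
    "Batch",
    "init_params",
    "pack_batch",
    "char_repr",
    "forward_batch",
    "forward",
    "label_probs",
    "log_likelihood",
    "loss_and_grads",
    "fit",
    "predict_label_ids",
    "predict_labels",
    "save_model",
    "load_model",
]

# argmax preference order on exact score ties: O first, then B, then I
_TIE_ORDER = np.array([2, 0, 1])


@dataclass
class ModelConfig:
    """Hyper-parameters; defaults are the published settings (3 conv layers
    for the NCBI-sized setup, 4 for CDR).  Optimizer settings (plain SGD,
    lr 0.01, batch 32) follow the framework defaults of the era; the epoch
    budget is a free parameter."""

    window: int = 13
    word_dim: int = 200
    char_dim: int = 20
    lex_dim: int = 5
    char_cnn_window: int = 3
    char_cnn_filters: int = 20
    word_conv_window: int = 3
    word_conv_filters: int = 100
    n_conv_layers: int = 3
    dropout_rate: float = 0.5
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 15
    seed: int = 1
    use_char: bool = True
    use_lexicon: bool = True
    use_mls: bool = True
    aux_mode: str = "joint"  # "joint": one 9-way head; "pair": two 3-way heads
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd and positive")
        if self.conv_out_positions < 1:
            raise ValueError(
                f"{self.n_conv_layers} conv layers of window {self.word_conv_window} "
                f"consume the whole {self.window}-token input"
            )
        if self.aux_mode not in ("joint", "pair"):
            raise ValueError(f"aux_mode must be 'joint' or 'pair', got {self.aux_mode!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def input_dim(self) -> int:
        return (
            self.word_dim
            + (self.char_cnn_filters if self.use_char else 0)
            + (self.lex_dim if self.use_lexicon else 0)
        )

    @property
    def conv_out_positions(self) -> int:
        return self.window - self.n_conv_layers * (self.word_conv_window - 1)

    @property
    def flat_dim(self) -> int:
        return self.conv_out_positions * self.word_conv_filters


@dataclass
class OutputScores:
    """Raw confidence scores of the two output heads for one instance."""

    out_main: np.ndarray  # (3,)
    out_aux: np.ndarray | None  # (9,) joint, (6,) pair [prev 3 | next 3], None if MLS off


@dataclass
class Batch:
    words: np.ndarray  # (B, W) int
    chars: np.ndarray  # (B, W, L) int, PAD-padded, L >= char_cnn_window
    lex: np.ndarray  # (B, W) int
    y: np.ndarray  # (B,) int
    y_aux: np.ndarray  # (B,) int in 0..8
    y_prev: np.ndarray  # (B,) int
    y_next: np.ndarray  # (B,) int

    def __len__(self) -> int:
        return self.words.shape[0]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_out, fan_in = shape[0], int(np.prod(shape[1:]))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_params(
    config: ModelConfig,
    vocab: Vocab,
    word_table: np.ndarray | None = None,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Initialize all learnable tensors (theta), reproducibly.

    ``word_table`` (e.g. from :func:`mcnn_ner.encoding.load_word_vectors`)
    overrides the random word-embedding initialization.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = np.dtype(config.dtype)
    p: dict[str, np.ndarray] = {}
    if word_table is not None:
        if word_table.shape != (vocab.n_words, config.word_dim):
            raise ValueError(
                f"word table shape {word_table.shape} != {(vocab.n_words, config.word_dim)}"
            )
        p["word_emb"] = word_table.astype(dt)
    else:
        p["word_emb"] = random_embedding(vocab.n_words, config.word_dim, rng).astype(dt)
    if config.use_char:
        p["char_emb"] = random_embedding(vocab.n_chars, config.char_dim, rng).astype(dt)
        p["char_W"] = _glorot(
            rng, (config.char_cnn_filters, config.char_cnn_window * config.char_dim), dt
        )
        p["char_b"] = np.zeros(config.char_cnn_filters, dtype=dt)
    if config.use_lexicon:
        p["lex_emb"] = rng.uniform(-0.05, 0.05, size=(vocab.n_lex, config.lex_dim)).astype(dt)
    c_in = config.input_dim
    for layer in range(config.n_conv_layers):
        p[f"conv{layer}_W"] = _glorot(
            rng, (config.word_conv_filters, config.word_conv_window * c_in), dt
        )
        p[f"conv{layer}_b"] = np.zeros(config.word_conv_filters, dtype=dt)
        c_in = config.word_conv_filters
    p["main_W"] = _glorot(rng, (N_LABELS, config.flat_dim), dt).T.copy()
    p["main_b"] = np.zeros(N_LABELS, dtype=dt)
    if config.use_mls:
        if config.aux_mode == "joint":
            p["aux_W"] = _glorot(rng, (N_AUX, config.flat_dim), dt).T.copy()
            p["aux_b"] = np.zeros(N_AUX, dtype=dt)
        else:
            p["prev_W"] = _glorot(rng, (N_LABELS, config.flat_dim), dt).T.copy()
            p["prev_b"] = np.zeros(N_LABELS, dtype=dt)
            p["next_W"] = _glorot(rng, (N_LABELS, config.flat_dim), dt).T.copy()
            p["next_b"] = np.zeros(N_LABELS, dtype=dt)
    return p


def pack_batch(instances: list[TrainingInstance], min_char_len: int = 3) -> Batch:
    """Stack instances into padded arrays (char sequences padded to a common
    length of at least the char-CNN window)."""
    if not instances:
        raise ValueError("empty batch")
    B = len(instances)
    W = instances[0].word_ids.shape[0]
    L = max(min_char_len, max(len(cs) for inst in instances for cs in inst.char_ids))
    words = np.stack([inst.word_ids for inst in instances])
    lex = np.stack([inst.lex_ids for inst in instances])
    chars = np.zeros((B, W, L), dtype=np.int64)
    for b, inst in enumerate(instances):
        for w, cs in enumerate(inst.char_ids):
            chars[b, w, : len(cs)] = cs
    return Batch(
        words=words,
        chars=chars,
        lex=lex,
        y=np.array([inst.y for inst in instances], dtype=np.int64),
        y_aux=np.array([inst.y_aux for inst in instances], dtype=np.int64),
        y_prev=np.array([inst.y_prev for inst in instances], dtype=np.int64),
        y_next=np.array([inst.y_next for inst in instances], dtype=np.int64),
    )


def char_repr(
    word_chars: list[int] | np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Character-CNN representation of one word: embed, 1-D conv (window 3),
    max over positions.  Returns a ``char_cnn_filters``-dim vector.  The
    char sequence is padded with the PAD character up to the conv window;
    an empty sequence is an error (callers must pad)."""
    chars = list(word_chars)
    if not chars:
        raise ValueError("empty character sequence; pad with the PAD char id")
    while len(chars) < config.char_cnn_window:
        chars.append(0)
    C = params["char_emb"][np.asarray(chars)]  # (L, Dc)
    if train_mode and config.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("train_mode dropout needs an rng")
        keep = 1.0 - config.dropout_rate
        C = C * ((rng.random(C.shape) < keep) / keep)
    k = config.char_cnn_window
    Cw = np.lib.stride_tricks.sliding_window_view(C, k, axis=0)  # (P, Dc, k)
    Cw = np.moveaxis(Cw, -1, 1).reshape(Cw.shape[0], k * config.char_dim)
    S = Cw @ params["char_W"].T + params["char_b"]  # (P, F)
    return np.maximum(S, 0.0).max(axis=0)


def _sliding(x: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Sliding windows of length k along ``axis``; window axis inserted at axis+1."""
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=axis)
    return np.moveaxis(v, -1, axis + 1)


def forward_batch(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    batch: Batch,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    want_cache: bool = False,
):
    """Run the network on a packed batch.

    Returns ``(out_main, out_aux, cache)``; ``out_aux`` is ``None`` when the
    auxiliary head is disabled, and in pair mode holds the concatenated
    ``[prev | next]`` scores (shape ``(B, 6)``).  Dropout is active only in
    ``train_mode`` (``rng`` required then if dropout_rate > 0).
    """
    B, W = batch.words.shape
    dt = np.dtype(config.dtype)
    cache: dict = {}
    keep = 1.0 - config.dropout_rate
    use_dropout = train_mode and config.dropout_rate > 0.0
    if use_dropout and rng is None:
        raise ValueError("train_mode dropout needs an rng")

    parts = [params["word_emb"][batch.words]]  # (B, W, Dw)
    if config.use_char:
        C = params["char_emb"][batch.chars]  # (B, W, L, Dc)
        if use_dropout:
            cmask = (rng.random(C.shape) < keep).astype(dt) / keep
            C = C * cmask
            cache["cmask"] = cmask
        k = config.char_cnn_window
        Cw = _sliding(C, k, axis=2)  # (B, W, P, k, Dc)
        P = Cw.shape[2]
        Cw = np.ascontiguousarray(Cw).reshape(B, W, P, k * config.char_dim)
        S = Cw @ params["char_W"].T + params["char_b"]  # (B, W, P, F)
        A = np.maximum(S, 0.0)
        char_repr = A.max(axis=2)  # (B, W, F)
        if want_cache:
            cache.update(char_Cw=Cw, char_S=S, char_A=A, char_argmax=A.argmax(axis=2))
        parts.append(char_repr)
    if config.use_lexicon:
        parts.append(params["lex_emb"][batch.lex])  # (B, W, Dl)
    feat = np.concatenate(parts, axis=-1).astype(dt, copy=False)  # (B, W, D0)
    if use_dropout:
        fmask = (rng.random(feat.shape) < keep).astype(dt) / keep
        feat = feat * fmask
        cache["fmask"] = fmask

    H = feat
    convs = []
    kw = config.word_conv_window
    for layer in range(config.n_conv_layers):
        Hw = _sliding(H, kw, axis=1)  # (B, T', kw, C)
        T2 = Hw.shape[1]
        Hw = np.ascontiguousarray(Hw).reshape(B, T2, kw * H.shape[-1])
        Z = Hw @ params[f"conv{layer}_W"].T + params[f"conv{layer}_b"]
        Hn = np.maximum(Z, 0.0)
        convs.append((Hw, Z, H.shape))
        H = Hn
    flat = H.reshape(B, -1)  # (B, flat_dim)
    out_main = flat @ params["main_W"] + params["main_b"]
    out_aux = None
    if config.use_mls:
        if config.aux_mode == "joint":
            out_aux = flat @ params["aux_W"] + params["aux_b"]
        else:
            out_aux = np.concatenate(
                [
                    flat @ params["prev_W"] + params["prev_b"],
                    flat @ params["next_W"] + params["next_b"],
                ],
                axis=1,
            )
    if want_cache:
        cache.update(feat=feat, convs=convs, flat=flat)
    return out_main, out_aux, cache


def forward(
    x: TrainingInstance,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> OutputScores:
    """Single-instance forward pass returning raw head scores."""
    batch = pack_batch([x], min_char_len=config.char_cnn_window)
    out_main, out_aux, _ = forward_batch(params, config, batch, train_mode=train_mode, rng=rng)
    return OutputScores(out_main[0], None if out_aux is None else out_aux[0])


def _softmax(scores: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    s = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def label_probs(scores: OutputScores) -> tuple[np.ndarray, np.ndarray | None]:
    """Softmax both heads (max-subtracted for stability).

    In pair mode the auxiliary scores are two independent 3-way groups and
    are normalized per group.
    """
    p_main = _softmax(scores.out_main)
    if scores.out_aux is None:
        return p_main, None
    a = scores.out_aux
    if a.shape[-1] == 2 * N_LABELS:
        p_aux = np.concatenate(
            [_softmax(a[..., :N_LABELS]), _softmax(a[..., N_LABELS:])], axis=-1
        )
    else:
        p_aux = _softmax(a)
    return p_main, p_aux


def log_likelihood(
    batch: list[TrainingInstance] | Batch,
    params: dict[str, np.ndarray],
    config: ModelConfig,
) -> float:
    """J(theta): sum over instances of log p_main(y|x) + log p_aux(y_aux|x).

    The auxiliary sum is omitted when MLS is off (plain cross-entropy); in
    pair mode it is log p_prev + log p_next.  Training minimizes -J.
    """
    if isinstance(batch, list):
        batch = pack_batch(batch, min_char_len=config.char_cnn_window)
    out_main, out_aux, _ = forward_batch(params, config, batch, train_mode=False)
    idx = np.arange(len(batch))
    J = float(np.log(_softmax(out_main))[idx, batch.y].sum())
    if out_aux is not None:
        if config.aux_mode == "joint":
            J += float(np.log(_softmax(out_aux))[idx, batch.y_aux].sum())
        else:
            J += float(np.log(_softmax(out_aux[:, :N_LABELS]))[idx, batch.y_prev].sum())
            J += float(np.log(_softmax(out_aux[:, N_LABELS:]))[idx, batch.y_next].sum())
    return J


def _head_grad(p: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d(-log p[target])/d(scores) = p - onehot, rowwise."""
    g = p.copy()
    g[np.arange(len(targets)), targets] -= 1.0
    return g


def loss_and_grads(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    batch: Batch,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """-J over the batch and its analytic gradient w.r.t. every parameter."""
    out_main, out_aux, cache = forward_batch(
        params, config, batch, train_mode=train_mode, rng=rng, want_cache=True
    )
    B = len(batch)
    idx = np.arange(B)
    p_main = _softmax(out_main)
    loss = -float(np.log(p_main)[idx, batch.y].sum())
    d_main = _head_grad(p_main, batch.y)  # (B, 3)

    grads: dict[str, np.ndarray] = {}
    flat = cache["flat"]
    grads["main_W"] = flat.T @ d_main
    grads["main_b"] = d_main.sum(axis=0)
    d_flat = d_main @ params["main_W"].T
    if config.use_mls:
        if config.aux_mode == "joint":
            p_aux = _softmax(out_aux)
            loss -= float(np.log(p_aux)[idx, batch.y_aux].sum())
            d_aux = _head_grad(p_aux, batch.y_aux)
            grads["aux_W"] = flat.T @ d_aux
            grads["aux_b"] = d_aux.sum(axis=0)
            d_flat = d_flat + d_aux @ params["aux_W"].T
        else:
            p_prev = _softmax(out_aux[:, :N_LABELS])
            p_next = _softmax(out_aux[:, N_LABELS:])
            loss -= float(np.log(p_prev)[idx, batch.y_prev].sum())
            loss -= float(np.log(p_next)[idx, batch.y_next].sum())
            d_prev = _head_grad(p_prev, batch.y_prev)
            d_next = _head_grad(p_next, batch.y_next)
            grads["prev_W"] = flat.T @ d_prev
            grads["prev_b"] = d_prev.sum(axis=0)
            grads["next_W"] = flat.T @ d_next
            grads["next_b"] = d_next.sum(axis=0)
            d_flat = d_flat + d_prev @ params["prev_W"].T + d_next @ params["next_W"].T

    # back through the conv stack
    kw = config.word_conv_window
    dH = d_flat.reshape(B, config.conv_out_positions, config.word_conv_filters)
    for layer in range(config.n_conv_layers - 1, -1, -1):
        Hw, Z, in_shape = cache["convs"][layer]
        dZ = dH * (Z > 0)
        F = dZ.shape[-1]
        grads[f"conv{layer}_W"] = dZ.reshape(-1, F).T @ Hw.reshape(-1, Hw.shape[-1])
        grads[f"conv{layer}_b"] = dZ.sum(axis=(0, 1))
        dHw = (dZ @ params[f"conv{layer}_W"]).reshape(B, Z.shape[1], kw, in_shape[-1])
        dH_in = np.zeros(in_shape, dtype=dZ.dtype)
        for o in range(kw):
            dH_in[:, o : o + Z.shape[1], :] += dHw[:, :, o, :]
        dH = dH_in
    d_feat = dH  # (B, W, D0)
    if "fmask" in cache:
        d_feat = d_feat * cache["fmask"]

    # split the concatenation
    off = config.word_dim
    d_word = d_feat[:, :, :off]
    grads["word_emb"] = np.zeros_like(params["word_emb"])
    np.add.at(grads["word_emb"], batch.words, d_word)
    if config.use_char:
        Fc = config.char_cnn_filters
        d_char_repr = d_feat[:, :, off : off + Fc]  # (B, W, Fc)
        off += Fc
        A = cache["char_A"]
        amax = cache["char_argmax"]  # (B, W, Fc)
        dA = np.zeros_like(A)
        np.put_along_axis(dA, amax[:, :, None, :], d_char_repr[:, :, None, :], axis=2)
        dS = dA * (cache["char_S"] > 0)
        Cw = cache["char_Cw"]
        grads["char_W"] = dS.reshape(-1, Fc).T @ Cw.reshape(-1, Cw.shape[-1])
        grads["char_b"] = dS.sum(axis=(0, 1, 2))
        kc = config.char_cnn_window
        P = dS.shape[2]
        dCw = (dS @ params["char_W"]).reshape(B, batch.words.shape[1], P, kc, config.char_dim)
        dC = np.zeros(
            (B, batch.words.shape[1], batch.chars.shape[2], config.char_dim), dtype=dS.dtype
        )
        for o in range(kc):
            dC[:, :, o : o + P, :] += dCw[:, :, :, o, :]
        if "cmask" in cache:
            dC = dC * cache["cmask"]
        grads["char_emb"] = np.zeros_like(params["char_emb"])
        np.add.at(grads["char_emb"], batch.chars, dC)
    if config.use_lexicon:
        d_lex = d_feat[:, :, off:]
        grads["lex_emb"] = np.zeros_like(params["lex_emb"])
        np.add.at(grads["lex_emb"], batch.lex, d_lex)
    return loss, grads


def predict_label_ids(
    params: dict[str, np.ndarray], config: ModelConfig, batch: Batch
) -> np.ndarray:
    """Main-head argmax per instance; exact ties resolved O > B > I.

    The auxiliary head is a training signal only and is ignored here.
    """
    out_main, _, _ = forward_batch(params, config, batch, train_mode=False)
    reordered = out_main[:, _TIE_ORDER]  # argmax picks the first max
    return _TIE_ORDER[np.argmax(reordered, axis=1)]


def predict_labels(
    instances: list[TrainingInstance],
    params: dict[str, np.ndarray],
    config: ModelConfig,
) -> list[str]:
    """Predict B/I/O labels for a sentence's encoded window instances."""
    if not instances:
        return []
    batch = pack_batch(instances, min_char_len=config.char_cnn_window)
    return [ID_TO_LABEL[int(i)] for i in predict_label_ids(params, config, batch)]


def fit(
    train_instances: list[TrainingInstance],
    config: ModelConfig,
    vocab: Vocab,
    dev_eval=None,
    word_table: np.ndarray | None = None,
    callback=None,
) -> dict[str, np.ndarray]:
    """Mini-batch SGD on -J; returns the best-dev parameters.

    ``dev_eval``, if given, is a callable ``(params) -> float`` returning the
    mention-level F-score on a development set; it is invoked after every
    epoch and the parameters of the best epoch are returned (ties keep the
    earlier epoch).  Without ``dev_eval`` the final-epoch parameters are
    returned.  Fully reproducible given ``config.seed``.
    """
    if not train_instances:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    params = init_params(config, vocab, word_table=word_table)
    n = len(train_instances)
    best_f = -1.0
    best_params = params
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, config.batch_size):
            chunk = [train_instances[i] for i in order[start : start + config.batch_size]]
            batch = pack_batch(chunk, min_char_len=config.char_cnn_window)
            loss, grads = loss_and_grads(params, config, batch, train_mode=True, rng=rng)
            total_loss += loss
            scale = config.learning_rate / len(batch)
            for key, g in grads.items():
                params[key] -= scale * g
        msg = f"epoch {epoch}: -J/n = {total_loss / n:.4f}"
        if dev_eval is not None:
            dev_f = float(dev_eval(params))
            msg += f", dev F = {dev_f:.4f}"
            if dev_f > best_f:
                best_f = dev_f
                best_params = copy.deepcopy(params)
        logger.info(msg)
        if callback is not None:
            callback(epoch, total_loss / n, params)
    return best_params if dev_eval is not None else params


def save_model(path, params: dict[str, np.ndarray], config: ModelConfig, vocab: Vocab) -> None:
    """Single-file checkpoint: config + vocab (JSON) + named arrays (npz)."""
    meta = {"format": "mcnn-ner-checkpoint", "version": 1}
    np.savez_compressed(
        path,
        __meta__=json.dumps(meta),
        __config__=json.dumps(asdict(config)),
        __vocab__=json.dumps(vocab.to_dict()),
        **params,
    )


def load_model(path) -> tuple[dict[str, np.ndarray], ModelConfig, Vocab]:
    with np.load(path, allow_pickle=False) as zf:
        meta = json.loads(str(zf["__meta__"]))
        if meta.get("format") != "mcnn-ner-checkpoint":
            raise ValueError(f"{path} is not a model checkpoint")
        config = ModelConfig(**json.loads(str(zf["__config__"])))
        vocab = Vocab.from_dict(json.loads(str(zf["__vocab__"])))
        params = {k: zf[k] for k in zf.files if not k.startswith("__")}
    return params, config, vocab
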