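# Methods notes

## The tagging model

Disease NER is treated as word-level classification: the label of a token
is assumed to depend on a bounded neighborhood rather than the whole
sentence, so each token is classified from a fixed odd-size window
(default 13) of surrounding tokens.  The encoder is a stack of 1-D
convolutions with **no pooling**: pooling buys shift-invariance, which
matters for images but destroys the position information that links a
window position to the center token, and the flattened feature map is small
enough (7 positions x 100 filters = 700 dims for three layers) that there
is no computational need for it.  "Valid" (no-padding) convolutions are
used so the receptive field shrinks symmetrically toward the center token;
each convolution is followed by ReLU.

Label-transition structure (e.g. `I` never follows `O`) is normally
recovered with a CRF decoding layer.  Here it is learned instead: during
training the output layer also predicts the *previous* and *next* tokens'
labels (the multiple-label strategy).  The auxiliary target is the joint
(prev, next) pair encoded as one of k = 9 classes — a single softmax over
the pair distribution, which matches the one-distribution form of the
auxiliary objective; a two-head variant (two independent 3-way softmaxes,
`aux_mode="pair"`) is available behind a config flag.  The objective is

    J(θ) = Σ_i log p_main(y_i | x_i, θ) + Σ_i log p_aux(y_aux_i | x_i, θ)

minimized as −J by plain SGD.  At inference the auxiliary head is
discarded and each token's label is the argmax of the main head; exact
score ties (e.g. an untrained all-zero model) resolve O, then B, then I, so
a degenerate model abstains rather than hallucinating spans.

Neighbor labels outside the sentence count as `O` (padding carries no
entity).  Windows never cross sentence boundaries; out-of-sentence
positions are filled with PAD word/char/lex ids.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| window | 13 tokens | context fed to the classifier |
| word embedding | 200 d | lowercased, number-normalized surface |
| char embedding / filters | 20 d / 20, window 3 | conv + max over positions |
| lexicon embedding | 5 d | learned per dictionary B/I/O label |
| word conv layers | 3 (4 for larger corpora) | window 3, 100 filters, ReLU, valid |
| dropout | 0.5 | after embedding concatenation and on char embeddings |
| optimizer | SGD, lr 0.01, batch 32 | framework defaults of the era |
| epochs | 15 | free parameter; best-dev-F checkpointing when a dev set is given |

The first six rows are the published settings of the architecture this
package implements; dropout rate, activation, padding mode, optimizer
details and the epoch budget were not specified and are package choices
(recorded here).  Batch 32 and lr 0.01 are the long-standing `fit()`/SGD
defaults of the Keras-generation frameworks; with mean-gradient SGD the
effective step scales inversely with batch size, and batch 32 converges on
the synthetic corpus in a handful of epochs where batch 128 does not.

## Preprocessing

Tokenization splits on whitespace and on a punctuation delimiter set
(`/ − - > < ; : ? [ ] { } ( ) ! @ # $ % ^ & * + , .`), *retaining* each
delimiter as a single-character token — hyphens and brackets occur inside
disease names and must survive for exact-span reconstruction.  One
exception: a period flanked by digits is part of a decimal and does not
split, so `81.6` stays one token while a sentence-final `rose.` splits.
Integer/decimal tokens (`^[+-]?\d+(\.\d+)?$`, whole token only) get the
uniform lookup surface `num`; the raw text and offsets are never modified,
so spans always resolve against the original document.  Word-level lookup
uses the lowercased normalized surface; the character CNN sees the original
cased text (case is morphology, delegated to the char level).

Sentence splitting is rule-based (sentence-final `.`/`!`/`?` followed by
whitespace and an upper-case letter or digit, with an abbreviation
exception list).  If a gold mention crosses a detected boundary the
sentences are merged, preserving exact-span evaluability.

## Dictionary matching

The lexicon (MEDIC-style TSV with pipe-separated synonyms, or a plain term
list) is normalized with the same tokenizer + number transform as the
corpus.  Matching is greedy leftmost-longest over normalized lowercased
tokens, non-overlapping, identical at train and predict time.  Matched
spans are tagged `B I ... I`; the per-token label indexes a learned 5-d
embedding.

## Post-processing

*Repair*: every `I` whose predecessor is not `B`/`I` becomes `O`,
left-to-right to a fixpoint.  `B B` is legal under standard BIO semantics
(two adjacent single-token mentions — the gold projection itself produces
it), so the printed-table reading that declares it illegal is gated behind
`strict_bb` (default off).  *Abbreviations*: parenthesized short forms
(2–10 chars, at least one letter) are aligned rightward into the preceding
tokens (Schwartz–Hearst); when a pair's long form exactly matches a
predicted mention, every whole-token occurrence of the short form in that
document is added as a mention unless it overlaps an existing prediction.
Propagation is document-scoped and never removes a mention.

## Evaluation

Mention-level exact span: a prediction is correct iff some gold mention has
the identical (doc id, char start, char end).  Counts are micro-averaged
over the corpus; duplicate predictions collapse before scoring.  Reported
percentages round half-up to 2 decimals.

## Synthetic corpus

The generator emits PubTator-format documents with exact offsets.  Disease
names (1–5 tokens, 20 % of multi-token names hyphenated) and context words
are built from *disjoint* syllable inventories, so word identity plus
context makes the task learnable — deliberately much easier than real
biomedical text.  Defaults: 0.7 mention probability per sentence, mention
length distribution (0.40, 0.30, 0.15, 0.10, 0.05) over 1–5 tokens, 70 %
lexicon coverage of the term list, 10 % abbreviation rate (definition
`(SF)` after the mention, short form reused later in the document as a gold
mention), 15 % numeric-token rate, 300 context words, 150 disease terms.
These emulate the corpus-scale facts of the public DNER releases (hundreds
of abstracts, thousands of mentions, multi-token mention lengths) at a size
a laptop trains in minutes.

A green synthetic test establishes that the implementation learns,
decodes, and scores correctly end-to-end; it does **not** establish
corpus-level performance on real abstracts, which depends on pre-trained
word vectors, real orthographic/morphological variation, annotation
idiosyncrasies, and far longer training.

## Numerical choices

* Forward/backward in float32 for training (float64 for gradient checks);
  softmax is max-subtracted; the log-likelihood is an exact sum, and SGD
  steps use the batch mean.
* Glorot-uniform initialization for conv/dense weights, uniform ±0.05 for
  embedding tables (PAD row zeroed), zero biases; all randomness flows from
  one seeded generator, so runs are bit-reproducible.
* Max-pool backprop routes the gradient to the first argmax on ties; the
  gradient check therefore perturbs parameters to a generic point first
  (ReLU kinks and pool ties are measure-zero but exactly where zero
  initialization sits).
* Character sequences are padded with the PAD character to at least the
  char-conv window (3).
* A window of w tokens supports at most (w−1)/2 valid conv layers of
  window 3; the config rejects deeper stacks.

## Known limitations

* No pre-trained word vectors are bundled; `load_word_vectors` accepts the
  standard whitespace text format, otherwise embeddings start random.
* Overlapping gold mentions cannot be encoded in BIO; the leftmost-longest
  mention wins and the loser is dropped with a warning.
* The abbreviation pairer is the standard parenthesis heuristic, not a
  learned model; nested parentheses inside short forms are not paired.
* Plain SGD has no learning-rate schedule; very small corpora may need
  more epochs (see the worked example scale in the README).
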