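# Methods

`clinevent` detects clinical event mentions — spans of one of six types
(problem, test, treatment, evidential, occurrence, clinical_department) —
in pre-tokenized clinical text, treated as BIOES sequence labeling. This
note records the model, the numerical choices, and what the synthetic test
world does and does not establish.

## Model

### Feature extraction

Each word receives two representations, concatenated per token:

* **Character-level** (width `cd`, default 30): characters are looked up in
  a trainable embedding table, passed through one relative-position
  attention block (3 heads, FFN width `cd_ff = 60`), resized by a fully
  connected layer, and max-pooled over the character axis. The word length
  is dynamic per batch (capped at `wl_cap = 24` characters); padding
  characters are masked out of both attention and pooling, so a word's
  vector is independent of batch composition.
* **Word-level** (width `wd`): a pluggable embedder. The default is a
  trainable lookup table over the training vocabulary (frequency threshold
  `min_count = 2`; rarer words share an UNK row). The interface also admits
  a contextual embedder producing 768-wide rows from a pretrained
  biomedical language model; no such weights are bundled, and that slot is
  not exercised by tests.

### Encoder: relative-position attention

The sentence encoder is a stack (default 2 layers, 8 heads) of attention
blocks whose score between query position t and key position j is

    A[t,j] = Q_t K_j^T + Q_t R_{t-j}^T + u K_j^T + v R_{t-j}^T

with R a sinusoidal embedding of the *signed* offset t−j (interleaved
sin/cos, frequencies 10000^(−2i/d_k)). The sine components are odd in the
offset and the cosines even, so the learned bias `v` can tell left context
from right. Two deliberate departures from a vanilla Transformer:

* **keys are unprojected** — K is the per-head column slice of the input;
* **attention is un-scaled** — no 1/√d_k divisor.

Both are kept exactly as designed; the oracle tests pin them down so a
future maintainer does not "fix" them.

Residual connections and post-layer-norm wrap both sub-layers. They are an
implementation necessity (a 2-layer stack does not train without them), not
part of the published equations; `layer_norm=False` disables both so the
algebraic unit tests (zero-input ⇒ zero-output, etc.) can hold exactly.
Dropout is available but defaults to 0, keeping every test deterministic.

The concatenated feature width `cd + wd` is generally not divisible by the
head count, so a learned affine projection maps it to `d_model` (default
256) before the encoder. Padding masks are additive (−1e30 pre-softmax,
which underflows to exactly zero weight in float64); padded rows are zeroed
after every block.

### Decoder: linear-chain CRF

The encoder output is mapped by a final affine layer to one emission score
per label (`d_f = 4·|types| + 1 = 25`). A linear-chain CRF adds a learned
transition table plus explicit START/STOP boundary vectors (the boundary
term is a design choice; the sequence-probability formula leaves the
initial transition undefined). Training minimizes the exact negative
log-likelihood via the forward algorithm in log space; decoding is Viterbi
with ties broken toward the lowest label index. Hard masking of
BIOES-invalid transitions at decode time is available
(`constrained_decode`) but off by default, since forgiving span decoding
already tolerates ill-formed output.

## Data augmentation

Non-event ("O"-tagged) words are replaced one-for-one from a lexicon of
five relations scanned in priority order synonyms → antonyms → hypernyms →
hyponyms → related words; only the first candidate of the first non-empty
list is used. Three regimes: replace **all** replaceable words; the same
with antonyms discarded; or antonyms discarded and **one** new sentence per
replaceable position. Because substitution is positional, every generated
sentence inherits its source tag sequence exactly — the augmentation-safety
property test checks this over thousands of random sentences. Tokens
containing digits or only punctuation are never replaced (they are mostly
dates and doses). Lexicon lookup is case-insensitive and the replacement
mirrors the source capitalization. When a sample fraction < 1 is given,
only the *generated* pool is subsampled; originals are always kept.

## Preprocessing

Long sentences are split immediately after break punctuation (default
`{",", ";"}`), then adjacent fragments are greedily re-merged left-to-right
up to the maximum length; an unbreakable over-long fragment is hard-split
at the maximum rather than truncated (truncation would silently drop gold
spans). Digits are normalized to "0" and a bare possessive token ("'s") is
spliced onto the preceding word; the spliced token must be O-tagged, or the
operation aborts rather than corrupt span alignment. No default maximum
length is claimed; it is a config field.

## Evaluation

* **Strict** P/R/F1: a prediction is correct only if (start, end, type)
  all match a gold span; micro-averaged; 0/0 ≡ 0.
* **Lenient span** F1: predictions and golds are matched one-to-one by
  greedy maximum token overlap, type ignored, ties toward the earlier gold
  span. One-to-one matching is a deliberate choice: unrestricted matching
  can push precision above 1. Strict F1 ≤ lenient F1 holds by construction
  and is property-tested.
* **Type accuracy**: among lenient-matched pairs, the fraction with equal
  type; with no pairs it is reported as 0 with a warning.

Predicted tags are decoded *forgivingly* by default (every maximal run of
same-type non-O tags is one span), since raw model output may be
ill-formed; gold is decoded strictly.

## Training

SGD with momentum 0.9, batch size 16, triangular learning-rate schedule
(linear 0 → peak over the first 1% of steps, then linear back to 0), peak
default 8e-4, 100 epochs — the published recipe. Two local choices:

* the loop minimizes the batch-**mean** NLL so the gradient scale is
  independent of batch size (the per-sequence objective is unchanged);
* gradients are clipped at global norm 5 (un-scaled attention produces
  occasional large score gradients early on).

The desk-scale experiments in the test suite use a reduced model (cd=12,
wd=16, one char layer, one encoder layer, d_model=32) and peak LR 0.02 —
the rate at which SGD converges stably on that architecture; the published
8e-4 belongs to the full-size model and moves the small one too slowly to
be useful in 30 epochs. Epoch counts in tests are scaled down for runtime;
100 remains the documented default.

## Synthetic data: the stated world

The restricted clinical corpus cannot be redistributed, so the package
generates corpora that keep what the method needs and nothing more:

* filler sentences (5–12 tokens) from a fixed 150-word vocabulary, with
  1–3-token event spans (Poisson mean 1.2 per sentence, never adjacent),
  types drawn from a configurable proportion map (uniform by default);
* a **word-shape** type signal: with probability `signal` an event token
  ends in a type-specific trigram (e.g. `…qed` for *test*). Event stems are
  random, so word identity is nearly useless for typing — the character
  encoder is the only route to the type, which is exactly what the
  char-ablation experiment needs;
* synthetic lexica keyed on filler words only, so augmentation can never
  touch an event token by construction.

What a green test on this world establishes: the architecture can recover
span boundaries and types from character-shape evidence; the CRF, metrics,
schedule and augmentation behave exactly as specified. What it does not
establish: performance on real clinical narratives, value of pretrained
embeddings, robustness to annotation noise or genuine lexical ambiguity.

## Known limitations

* No pretrained contextual embedder is included; the adapter slot exists
  but is untested.
* Augmentation is word-level only; multi-word phrases are replaced token by
  token, which can split idioms (a known limitation of the approach).
* The trainer is pure NumPy on CPU; it is sized for desk-scale experiments
  (hundreds of sentences), not corpus-scale training.
* The matching rule for lenient scoring (greedy one-to-one) is one
  reasonable reading of span-overlap evaluation; other matchers (optimal
  assignment) could differ in edge cases with nested overlaps.
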