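# clinevent

Clinical event detection as BIOES sequence labeling: a relative-position
attention (TENER-style) tagger with character-level word encoding and
linear-chain CRF decoding, plus a label-preserving lexical data-augmentation
engine and strict/lenient span evaluation.

## The problem

Clinical narratives (discharge summaries, progress notes) mention *events*
— problems, tests, treatments, evidentials, occurrences, clinical
departments — whose boundaries and types downstream systems need. Treating
this as sequence labeling, each token gets a tag from
`{B,I,E,S}-{type} ∪ {O}`. Two obstacles dominate: obscure professional
vocabulary (character shape helps: prefixes, units, abbreviation patterns)
and scarce annotated data (annotation requires clinicians and data-use
agreements).

This package addresses both. The tagger scores attention between positions
t and j as

    A[t,j] = Q_t K_j^T + Q_t R_{t−j}^T + u K_j^T + v R_{t−j}^T

where R_{t−j} is a sinusoidal embedding of the *signed* offset — sines odd,
cosines even, so direction survives — with unprojected keys and un-scaled
attention. The same block encodes characters within a word (max-pooled into
a `cd`-wide vector) and tokens within a sentence. A linear-chain CRF

    P(y|H) = exp(Σᵢ emit(i, yᵢ) + trans(yᵢ₋₁, yᵢ)) / Σ_{y'} exp(…)

decodes with Viterbi. Data scarcity is attacked by replacing non-event
words with lexicon candidates in priority order (synonyms → antonyms →
hypernyms → hyponyms → related words), which provably preserves the tag
sequence.

Everything runs on synthetic corpora shipped by the package — the
restricted clinical corpus is not required. See `docs/methods.md` for the
full model description and the limits of the synthetic world.

## Worked example

The augmentation engine on one clinical sentence, with a lexicon where
*has* has synonym *have*, *worked* has hypernym *set* (hyponym *cut*,
related word *put*), and *up* has only the antonym *down*:

```python
>>> from clinevent import worked_example, augment_sentence, AugmentationMode
>>> sent, lex = worked_example()
>>> sent.text()
'She has been worked up with barium enema 09/97 .'
>>> [s.text() for s in augment_sentence(sent, lex, AugmentationMode.ALL)]
['She have been set down with barium enema 09/97 .']
>>> [s.text() for s in augment_sentence(sent, lex, AugmentationMode.ALL_NO_ANT)]
['She have been set up with barium enema 09/97 .']
>>> [s.text() for s in augment_sentence(sent, lex, AugmentationMode.ONE_NO_ANT)]
['She have been worked up with barium enema 09/97 .',
 'She has been set up with barium enema 09/97 .']
```

Every replacement hits only O-tagged tokens ("barium enema" is the event),
so the tag sequence is identical in all outputs. With antonyms excluded,
*up* (antonym-only) is left alone.

End to end from the shell:

```bash
clinevent synth --n 500 --seed 1 --out /tmp/toy
clinevent augment --mode all_no_ant --seed 1 \
    --lexicon /tmp/toy.lexicon.json /tmp/toy.conll /tmp/aug.conll
clinevent train --train /tmp/aug.conll --seed 1 --epochs 15 \
    --config examples/small_model.yaml --out /tmp/run
clinevent predict --model /tmp/run/checkpoint.npz /tmp/toy.conll /tmp/pred.conll
clinevent evaluate /tmp/toy.conll /tmp/pred.conll
```

The evaluation report gives strict span precision/recall/F1 (boundaries and
type must match exactly), lenient span F1 (one-to-one overlap matching,
type ignored), and type accuracy (type agreement among overlap-matched
spans).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: generates a 500-sentence
word-shape-separable corpus and lexicon, augments it (all-words,
antonyms excluded), trains the small tagger with the triangular LR
schedule, and prints the held-out evaluation report (strict and lenient
span scores and type accuracy) before writing the results file.
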