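# curatext

Text-mining tools for curating experimental facts from the neuroscience
literature. Building biophysically detailed brain models requires harvesting
reported measurements (reversal potentials, conductances, firing rates) and
the entities they attach to (brain regions, neuron types, ion channels,
model organisms) from thousands of papers. `curatext` implements the full
tool chain a curation team needs to bootstrap such an effort from a very
small amount of manual annotation:

- **`corpus_io`** — tokenization with character offsets, sentence splitting,
  BIO span encoding/decoding, brat standoff and token-per-line TSV readers
  and writers. Eight entity types are supported: `BrainRegion`,
  `NeuronType`, `ModelOrganism`, `IonChannel`, `IonCurrent`,
  `IonConductance`, `ExperimentalValue`, `Unit`.
- **`rules_engine`** — a deterministic annotator: gazetteer longest-match
  over curated dictionaries, noun-phrase-scoped entity regexes, a unit
  gazetteer (24 base units × 19 SI prefixes, long and short forms), a
  numeric value detector `\d+(,\d{3})*(\.\d+)?` with negative-sign
  post-processing, value–unit linking within noun phrases, and
  document-level acronym propagation from parenthetical definitions.
- **`crf_tagger`** — one linear-chain CRF per entity type over token
  features (word, lemma, POS, chunk, dictionary BIO in a ±2 window), with
  **exact N-best decoding**: hypotheses carry true conditional
  probabilities P(y|x) = exp(score(y))/Z.
- **`active_learning`** — uncertainty sampling by *normalized N-best
  entropy*,

      H(x)    = − Σᵢ  p̃ᵢ log₂ p̃ᵢ ,   p̃ᵢ = P(y⁽ⁱ⁾|x) / Σⱼ P(y⁽ʲ⁾|x)
      score(x) = H(x) / log₂ N                     ∈ [0, 1]

  over the top-N (default N = 3) CRF hypotheses; the top-K (default 500)
  pool sentences go to the annotator.
- **`neural_tagger`** — a BiLSTM-CRF: character-level BiLSTM word encodings
  concatenated with word embeddings (optionally pretrained, word2vec binary
  format), dropout, a word-level BiLSTM, and a CRF output layer. Written in
  NumPy with hand-verified backpropagation and Adam; no GPU required.
- **`evaluation`** — strict (exact boundaries) and relaxed (any overlap)
  span matching, precision/recall/F1, inter-annotator agreement F1, and the
  70/15/15 train/test/validate split.
- **`synthetic_fixtures`** — a seeded generator of neuroscience-like
  annotated corpora (overlapping spans, acronym definitions, value ranges,
  unit-final lists), so every statistical stage is trainable and testable
  offline.

## Worked example

```python
>>> from curatext import annotate
>>> sentence = ("The effect of bicuculline (12.5 microM) on the spontaneous "
...             "firing rate of SCN neurons during the night was heterogeneous.")
>>> for s in annotate(sentence):
...     print(s.entity_type, repr(s.surface), s.begin, s.end, s.source)
ExperimentalValue '12.5 microM' 27 38 regex
Unit 'microM' 32 38 dictionary
BrainRegion 'SCN' 74 77 dictionary
NeuronType 'SCN neurons' 74 85 regex
```

The value detector finds `12.5`, the unit gazetteer recognises `microM`
(the long prefix *micro* combined with the short form of *molar*), and
noun-phrase linking merges them into one experimental value. `SCN` is a
dictionary hit, and the noun phrase containing the cue word *neurons*
becomes a neuron-type mention — note the overlapping annotations, which the
format preserves.

Uncertainty scoring works the same way top-down:

```python
>>> from curatext import normalized_entropy
>>> normalized_entropy([0.5, 0.3, 0.2], N=3)
0.9372305632161296
>>> normalized_entropy([1/3, 1/3, 1/3], N=3)
1.0
```

The same workflow is scriptable from the shell:

```bash
curatext gen-fixtures --seed 42 --out corpus/
curatext annotate-rules --in corpus/syn0000.txt --out pred.ann
curatext train-crf --train corpus/BrainRegion.tsv --type BrainRegion \
                   --model crf.json --seed 13
curatext select-al --model crf.json --pool corpus/BrainRegion.tsv \
                   --n 3 --k 500 --out ranked.tsv
curatext evaluate --gold corpus/ --pred predictions/ --mode strict --json
```

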