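# Methods

This note records the models implemented in `curatext`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Tokenization and offsets

The tokenizer is rule-based: whitespace chunks are split further by
detaching leading/trailing punctuation and splitting hyphenated compounds
*before* the hyphen ("Whole-cell" → "Whole", "-cell"). Offsets are 0-based
and end-exclusive, so `end − begin` is always the surface length. Two
conventions coexist and are explicit in the API: `raw` offsets index the
original text (used by brat standoff), while `detokenized` offsets index
the token stream re-joined with single spaces — the numbering used by the
token-per-line feature format, which is only self-consistent under
single-space joining. Sentence splitting is a rule on `. `/`? `/`! ` with
an abbreviation guard list; it is a pragmatic substitute, not a claim about
how any particular corpus drew its sentence boundaries.

BIO decoding is total: a dangling `I-` label (at the sequence start or
after `O`) is repaired to `B-` with a warning. Spans that cross a token
boundary snap outward to the covering tokens by default (a `reject` policy
raises instead).

## Linguistic backend

The CRF feature schema needs lemma, POS and chunk columns. Any provider
satisfying that contract can be plugged in; the bundled one is
dependency-light: a lexicon + suffix-heuristic POS tagger (Penn Treebank
codes, with "in vivo/vitro/situ" tagged FW), a lookup lemmatizer with
identity fallback and NNS plural stripping, and a regex-over-POS chunker.
The chunker keeps coordination and range glue (`,`, `and`/`or`, `to`, a
bare minus sign) inside a noun phrase when flanked by NP material, so
"15, 30 and 45 millimetres" and "−100 to −40 mV" each form a single NP —
the scope used for value–unit linking. This backend is adequate for
feature generation and linking scope; it is not a general parser.

## Rules and dictionaries

*Dictionaries.* Bundled per-type dictionaries are small curated snapshots
(tens of entries per type), one surface form per line. Matching is
token-aligned leftmost-longest; among candidates starting at the same
token the longest wins, and matching resumes after each match, so matches
of one type never overlap. Entries of ≤3 characters (acronyms: "VPM",
"SCN") match case-sensitively; longer entries case-insensitively — this
avoids false hits on short common words while still catching case variants
of multi-word terms. The ion-conductance dictionary is derived from the
ion-current dictionary by rewriting "current" → "conductance" and a
leading "I" → "g" in single-token acronyms ("IH" → "gH"); the bundled file
is exactly this rewrite and a test asserts it.

*Entity regexes.* Four types carry a cue-word pattern
(`neuron(e?s)?|cells?`, `currents?`, `channels?`, `conductances?`). The
pattern is evaluated against each noun phrase, and on a hit the **whole
noun phrase** becomes the span — "T-type Ca2+ channels" is one ion-channel
mention, not just the word "channels".

*Units.* The gazetteer holds 24 base units and 19 SI prefixes, each with a
long name and a short form. Only the resource's sizes and a few examples
are fixed by the recipe being reproduced, not the full inventory, so the
bundled set is a reconstruction: SI base and derived units (volt, gram, metre, second,
molar, siemens, …) and the SI prefixes minus *deca*. Expansion produces
24 × (19 + 1) = 480 long forms (bare bases plus every prefix+base),
prefixed short forms ("mV", "mg", "km"), and long-prefix + short-base
hybrids ("microM"). Long forms match case-insensitively with an optional
plural "s"; short forms match case-sensitively, with one deliberate
relaxation: the all-lowercase spelling of a short form is accepted ("mv"
for "mV", as in the range "10-20mv" that informal text produces), while a
*different* casing such as "MV" still only matches its own expansion
(mega+volt). Single-letter short forms require a directly preceding digit,
otherwise every bare "A" or "T" in prose would become a unit.

*Values.* The detector is `\d+(,\d{3})*(\.\d+)?`. A candidate is rejected
when it is embedded in malformed decimal/thousands context — immediately
preceded or followed by `.` or `,` adjacent to a digit — so "1.1.1.1" and
"1,23" yield nothing; a candidate glued to a preceding letter is also
rejected, which keeps protein names like "CaV3.1" out. Negative signs
(ASCII `-` or Unicode `−`, with at most one intervening space) are
absorbed in post-processing unless the token before the sign is itself a
number: "−100 to − 40" gives −100 and −40, while "10-20" stays a range.
Values preceded by `n =` are sample sizes, not experimental values.

*Linking.* A value links to a unit in the same noun phrase (nearest unit at
or after the value, else nearest before). When the linked unit directly
follows the value it is folded into one span ("12.5 microM"); in lists and
ranges with a trailing unit, earlier values are emitted bare but linked.
Values with no unit are still emitted, matching the annotation policy that
an experimental value includes its unit only if present.

*Acronyms.* Parenthetical definitions "long form (SF)" are detected
locally: the long form starts at the rightmost preceding word sharing the
short form's initial, and at least half the short form's letters must
appear in order in the long form. This deliberately looser-than-classical
validation accepts forms like "posterior nucleus (POm)" whose final letter
has no source word. If the long form is annotated with type T anywhere in
the document, every standalone occurrence of the short form gains a type-T
span. Propagation is per-document.

## Linear-chain CRF

One model per entity type over labels {B-T, I-T, O}. The score of a label
sequence is the sum of node potentials (linear in binary indicator
features of word/lemma/POS/chunk/dictionary in a ±2 token window, plus a
bias and explicit padding indicators) and a 3×3 transition matrix;
P(y|x) = exp(score)/Z with Z the sum over all 3^len sequences. Training
maximizes the L2-penalized conditional log-likelihood (penalty
c·‖θ‖², c = 1.0 by default) with L-BFGS from a zero start, which makes
training deterministic given the data order; the seed is stored as model
metadata. The window size, the dictionary column, and the regularizer are
configuration knobs, since the recipe being followed names the feature
columns but not the exact templates.

N-best decoding is a k-best Viterbi pass keeping the top N partial paths
per state; ties break toward the lexicographically smaller label sequence
(B < I < O). Because probabilities are normalized by the exact partition
function, requesting all 3^len hypotheses returns a distribution summing
to 1 — the test suite checks this against brute-force enumeration at
1e−9 on short sentences.

## Normalized-entropy active learning

Given the top-N hypothesis probabilities of a sentence, the scores are
renormalized by their sum, Shannon entropy is taken in base 2 with
0·log 0 ≡ 0, and the result is divided by log₂N, giving a score in [0, 1].
When a short sentence yields fewer than N hypotheses the actual count
enters the entropy sum but the normalizer stays log₂N, keeping scores
comparable across sentence lengths; a single-hypothesis sentence scores 0.
Selection returns the K highest-scoring sentences, ties broken by pool
order for determinism. Defaults are N = 3 and K = 500, the configuration
of the annotation protocol the package supports; the two-round protocol
(seed set → pool selection → re-seed) is scripted via the CLI rather than
hard-coded.

## BiLSTM-CRF

Per sentence: each word is represented by a trainable word embedding
concatenated with a character-based word embedding — the final states of a
forward and a backward LSTM over the word's characters. The concatenated
representation passes through inverted dropout, then a word-level BiLSTM;
a linear projection of the concatenated directions gives per-token label
scores, and a linear-chain CRF layer (learned 3×3 transitions) defines the
loss (negative log-likelihood) and the decode (Viterbi).

Reference hyperparameters: 20 epochs, batch size 10, character embedding
25, word embedding 200, character-based word embedding 250 (interpreted as
125 hidden units per direction; only the concatenated size is fixed by the
recipe), dropout 0.5, Adam at learning rate 0.013 with weight decay
1e−4. The word-level hidden size is left open by the recipe; the default
is 100 per direction. All of these are `NetConfig` fields.

Implementation choices:

- Everything is NumPy with hand-written backpropagation; the test suite
  validates analytic gradients against central finite differences through
  the whole network (both LSTM levels, dropout path disabled, embeddings,
  CRF loss).
- Mini-batches accumulate per-sentence gradients and take one Adam step
  per batch. There is no padding, so a sentence's loss and gradient are
  independent of its batch — asserted directly in a test.
- Weight decay is added to the gradient before the Adam update; seeding
  covers initialization, dropout masks and epoch shuffling.
- Pretrained embeddings are an optional input in word2vec C binary format
  (a minimal reader ships with the package); in-vocabulary words take the
  file's vectors, unknown words stay randomly initialized, and a *named*
  embedding file that cannot be read is an immediate error, never a silent
  fallback. Vocabulary lookup is case-sensitive first, lowercased second,
  because biomedical casing (mV, CaV3.1) is meaningful. All tests run with
  random initialization; no download is ever required.

## Evaluation

Strict matching requires exact (begin, end) equality; relaxed matching
accepts any character overlap, with each gold span consumable at most once
under greedy left-to-right pairing, so several predictions over one gold
span yield one true positive and the rest false positives (this prevents
relaxed scores from inflating; the convention is not dictated by the
protocol being followed, which leaves it open). Precision is defined as 0
when there are no predictions. Inter-annotator agreement is strict-match
F1 with one annotator as reference — symmetric in F1, with precision and
recall swapping under exchange — and only annotated spans count, so
agreement on unannotated text is never rewarded. The corpus split shuffles
sentences with a seed and partitions 70/15/15; test and validation take
their rounded shares and the rounding remainder goes to train.

## Synthetic benchmark: what it shows and what it does not

The generator draws a primary entity type per content sentence from a
configured multinomial (weights sum to 1), fills slot templates from
per-type lexicons, and records gold spans by construction, guaranteeing
token alignment and surface/offset consistency. It reproduces the
structural phenomena the pipeline must handle: overlapping annotations
(a region acronym inside "<ACRO> neurons"), parenthetical acronym
definitions, negative ranges with a trailing unit, value lists with the
unit only at the end, and entity-free distractor sentences. Lexicons are
split 3:1 into train-only and test-only surface forms so held-out scores
measure generalization from context rather than surface memorization. One
RNG seeded per run makes corpora byte-identical across repeats.

Default study conditions: 30 documents × 6 sentences, 20% distractors,
25% test-only surface forms; the active-learning protocol uses a 15-document
seed set and a 160-document pool, mirroring the annotation campaign the
package supports.

Problem sizes used by the test suite (chosen to keep the whole suite in
the minutes range on one CPU): the recovery benchmark uses 40 documents ×
5 sentences (200 sentences, 70/15/15 split); the neural tagger trains a
scaled-down architecture (12/24/24/24 dimensions, 8 epochs) that preserves
the topology; the active-learning benchmark uses a 120-document pool,
batches of K = 30, and 5 seeds with disjoint test corpora of 30 documents.

Passing these benchmarks shows the implementations can recover entity
classes from context cues and that entropy selection prefers informative
sentences under clean conditions. It does **not** show real-corpus
performance: template prose lacks the lexical variety, annotation noise,
nested syntax and class imbalance of published abstracts, and the bundled
dictionaries are snapshots rather than full terminologies. Scores on real
corpora should be expected to be substantially lower, with the rule-based
annotator degrading most.

## Known limitations

- No discontinuous (fragment) annotations; brat `;`-offset spans are out
  of scope, as are non-T brat lines.
- Experimental values are not linked to the physiological variable they
  measure, and no entity is normalized to an ontology.
- The acronym detector is local and per-document; it does not consult any
  external abbreviation resource.
- The POS/chunk backend is heuristic; swapping in a stronger parser behind
  the same column contract is expected to improve NP-dependent stages.
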