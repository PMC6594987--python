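"""Seeded generator of neuroscience-like annotated corpora.

Every statistical stage of the pipeline (CRF, neural tagger, active
learning, evaluation) is trainable and testable without downloading any
corpus: documents are built from slot templates whose typed slots are filled
from per-entity lexicons, and gold spans are recorded by construction, so
they are token-aligned and their surfaces equal the document text at their
offsets.

The generator emulates the constructs the real corpus exhibits: overlapping
annotations (a brain-region acronym inside a neuron-type mention),
parenthetical acronym definitions, negative value ranges ("−100 to −40 mV"),
lists of values with the unit only at the end, and entity-free distractor
sentences.  Per-type lexicons are split into train-only and test-only
surface forms so that held-out evaluation measures generalization to unseen
surfaces rather than memorization.  One global RNG is seeded per run; the
same seed yields a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, SpanAnnotation, spans_to_bio, write_brat


# ---------------------------------------------------------------------------
# Default lexicons (train/test split by construction)
# ---------------------------------------------------------------------------

def _brain_regions() -> list[str]:
    adjs = ["ventral", "dorsal", "medial", "lateral",
            "rostral", "caudal", "anterior", "posterior"]
    heads = ["thalamic nucleus", "geniculate nucleus", "reticular nucleus",
             "sensory cortex"]
    return [f"{a} {h}" for a in adjs for h in heads]


def _neuron_types() -> list[str]:
    adjs = ["pyramidal", "stellate", "basket", "granule",
            "relay", "spiny", "bipolar", "chandelier"]
    return [f"{a} neurons" for a in adjs] + [f"{a} cells" for a in adjs]


def _organisms() -> list[str]:
    return ["rats", "mice", "cats", "ferrets", "rabbits",
            "monkeys", "gerbils", "bats"]


def _channels() -> list[str]:
    ions = ["sodium", "potassium", "calcium", "chloride"]
    kinds = ["T-type", "L-type", "persistent", "transient"]
    return [f"{k} {i} channels" for k in kinds for i in ions]


def _currents() -> list[str]:
    ions = ["sodium", "potassium", "calcium", "chloride"]
    kinds = ["T-type", "L-type", "persistent", "transient"]
    return [f"{k} {i} current" for k in kinds for i in ions]


def _conductances() -> list[str]:
    ions = ["sodium", "potassium", "calcium", "chloride"]
    kinds = ["T-type", "L-type", "persistent", "transient"]
    return [f"{k} {i} conductance" for k in kinds for i in ions]


def _split(forms: list[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    # deterministic 3:1 train/test split of surface forms
    train = tuple(f for i, f in enumerate(forms) if i % 4 != 3)
    test = tuple(f for i, f in enumerate(forms) if i % 4 == 3)
    return train, test


@dataclass(frozen=True)
class Lexicon:
    train_forms: tuple[str, ...]
    test_forms: tuple[str, ...]

    def all_forms(self) -> tuple[str, ...]:
        return self.train_forms + self.test_forms


def default_lexicons() -> dict[str, Lexicon]:
    return {
        "BrainRegion": Lexicon(*_split(_brain_regions())),
        "NeuronType": Lexicon(*_split(_neuron_types())),
        "ModelOrganism": Lexicon(*_split(_organisms())),
        "IonChannel": Lexicon(*_split(_channels())),
        "IonCurrent": Lexicon(*_split(_currents())),
        "IonConductance": Lexicon(*_split(_conductances())),
    }


_DISTRACTORS = (
    "The results were consistent with previous reports .",
    "Data are presented as group averages across trials .",
    "These findings support the proposed mechanism of integration .",
    "Slice preparation followed standard procedures throughout .",
    "Statistical analysis used a mixed design with repeated measures .",
    "The protocol was approved by the institutional committee .",
)

_UNITS = ("mV", "ms", "Hz", "nA", "pA", "mm", "microM")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic corpus.

    ``entity_weights`` governs which entity type a content sentence is
    built around; weights must sum to 1.  ``test_form_prob`` is the chance
    a slot is filled from the lexicon's test-only surface forms.
    """
    seed: int = 0
    n_documents: int = 30
    sentences_per_document: int = 6
    lexicons: dict[str, Lexicon] = field(default_factory=default_lexicons)
    entity_weights: dict[str, float] = field(default_factory=lambda: {
        "BrainRegion": 0.22, "NeuronType": 0.18, "ModelOrganism": 0.12,
        "IonChannel": 0.12, "IonCurrent": 0.12, "IonConductance": 0.08,
        "ExperimentalValue": 0.16,
    })
    distractor_prob: float = 0.2
    test_form_prob: float = 0.25
    acronym_prob: float = 0.25    # parenthetical definition for brain regions
    overlap_prob: float = 0.25    # "<ACRO> neurons" overlap construct
    value_range: tuple[float, float] = (0.1, 500.0)
    decimals_prob: float = 0.5
    thousands_prob: float = 0.1
    units: tuple[str, ...] = _UNITS
    unit_weights: tuple[float, ...] | None = None
    distractors: tuple[str, ...] = _DISTRACTORS

    def __post_init__(self) -> None:
        total = sum(self.entity_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"entity weights sum to {total}, expected 1")
        for etype, lex in self.lexicons.items():
            if not lex.all_forms():
                raise ValueError(f"empty lexicon for {etype}")


@dataclass
class Corpus:
    documents: list[Document]
    gold: dict[str, list[SpanAnnotation]]
    #: primary entity type of every generated sentence (None = distractor)
    sentence_types: list[str | None]

    def to_brat(self) -> dict[str, tuple[str, str]]:
        """doc_id -> (.txt content, .ann content)."""
        return {
            d.doc_id: write_brat(d, self.gold[d.doc_id]) for d in self.documents
        }


# ---------------------------------------------------------------------------
# Sentence construction
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates text and records entity spans at exact offsets."""

    def __init__(self) -> None:
        self.text = ""
        self.spans: list[tuple[str, int, int]] = []

    def raw(self, piece: str) -> None:
        self.text += piece

    def entity(self, surface: str, *etypes: str) -> None:
        b = len(self.text)
        self.text += surface
        for t in etypes:
            self.spans.append((t, b, len(self.text)))


def _acronym(phrase: str) -> str:
    return "".join(w[0].upper() for w in phrase.split())


def _format_value(cfg: GeneratorConfig, rng) -> str:
    if rng.random() < cfg.thousands_prob:
        return f"{rng.integers(1, 999) * 1000 + rng.integers(0, 999):,}"
    lo, hi = cfg.value_range
    v = float(rng.uniform(lo, hi))
    if rng.random() < cfg.decimals_prob:
        return f"{v:.1f}"
    return str(int(round(v)))


def _pick_form(cfg: GeneratorConfig, etype: str, rng) -> str:
    lex = cfg.lexicons[etype]
    forms = lex.test_forms if (lex.test_forms and rng.random() < cfg.test_form_prob) \
        else lex.train_forms
    return forms[rng.integers(0, len(forms))]


def _pick_unit(cfg: GeneratorConfig, rng) -> str:
    if cfg.unit_weights is not None:
        p = np.asarray(cfg.unit_weights, dtype=float)
        return cfg.units[rng.choice(len(cfg.units), p=p / p.sum())]
    return cfg.units[rng.integers(0, len(cfg.units))]


def _build_sentence(cfg: GeneratorConfig, etype: str, rng) -> _Builder:
    b = _Builder()
    if etype == "BrainRegion":
        r = rng.random()
        if r < cfg.acronym_prob:
            form = _pick_form(cfg, etype, rng)
            acro = _acronym(form)
            b.raw("Recordings were obtained in the ")
            b.entity(form, "BrainRegion")
            b.raw(" (")
            b.entity(acro, "BrainRegion")
            b.raw(") under anaesthesia .")
        elif r < cfg.acronym_prob + cfg.overlap_prob:
            form = _pick_form(cfg, etype, rng)
            acro = _acronym(form)
            # overlapping annotations: region acronym inside a neuron mention
            b.raw("Firing of ")
            pos = len(b.text)
            b.entity(acro, "BrainRegion")
            b.raw(" neurons")
            b.spans.append(("NeuronType", pos, len(b.text)))
            b.raw(" was recorded in the ")
            b.entity(form, "BrainRegion")
            b.raw(" .")
        else:
            b.raw("Recordings were obtained in the ")
            b.entity(_pick_form(cfg, etype, rng), "BrainRegion")
            b.raw(" of anaesthetized subjects .")
    elif etype == "NeuronType":
        b.raw("Synaptic input onto ")
        b.entity(_pick_form(cfg, etype, rng), "NeuronType")
        b.raw(" was measured in vitro .")
    elif etype == "ModelOrganism":
        b.raw("Experiments were performed on adult ")
        b.entity(_pick_form(cfg, etype, rng), "ModelOrganism")
        b.raw(" under urethane anaesthesia .")
    elif etype == "IonChannel":
        b.raw("Expression of ")
        b.entity(_pick_form(cfg, etype, rng), "IonChannel")
        b.raw(" was localized by in situ hybridization .")
    elif etype == "IonCurrent":
        b.raw("The amplitude of the ")
        b.entity(_pick_form(cfg, etype, rng), "IonCurrent")
        b.raw(" increased upon depolarization .")
    elif etype == "IonConductance":
        b.raw("The model included a ")
        b.entity(_pick_form(cfg, etype, rng), "IonConductance")
        b.raw(" in distal dendrites .")
    elif etype == "ExperimentalValue":
        unit = _pick_unit(cfg, rng)
        style = rng.random()
        if style < 1 / 3:
            b.raw("The membrane potential averaged ")
            b.entity(f"{_format_value(cfg, rng)} {unit}", "ExperimentalValue")
            b.spans.append(("Unit", len(b.text) - len(unit), len(b.text)))
            b.raw(" across cells .")
        elif style < 2 / 3:
            v1, v2 = sorted(rng.integers(10, 120, size=2).tolist())
            b.raw("Responses varied from ")
            b.entity(f"−{v2} to −{v1} {unit}", "ExperimentalValue")
            b.spans.append(("Unit", len(b.text) - len(unit), len(b.text)))
            b.raw(" between conditions .")
        else:
            v1, v2, v3 = (_format_value(cfg, rng) for _ in range(3))
            b.raw("Stimuli of ")
            b.entity(v1, "ExperimentalValue")
            b.raw(" , ")
            b.entity(v2, "ExperimentalValue")
            b.raw(" and ")
            b.entity(f"{v3} {unit}", "ExperimentalValue")
            b.spans.append(("Unit", len(b.text) - len(unit), len(b.text)))
            b.raw(" were applied .")
    else:
        raise ValueError(f"no template for entity type {etype!r}")
    return b


def generate_corpus(config: GeneratorConfig | None = None,
                    rng: np.random.Generator | None = None) -> Corpus:
    """Generate annotated documents; deterministic given ``config.seed``."""
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    types = sorted(config.entity_weights)
    weights = np.array([config.entity_weights[t] for t in types])
    weights = weights / weights.sum()

    documents: list[Document] = []
    gold: dict[str, list[SpanAnnotation]] = {}
    sentence_types: list[str | None] = []
    for d in range(config.n_documents):
        doc_id = f"syn{d:04d}"
        pieces: list[str] = []
        spans: list[SpanAnnotation] = []
        offset = 0
        for _ in range(config.sentences_per_document):
            if rng.random() < config.distractor_prob:
                text = config.distractors[rng.integers(0, len(config.distractors))]
                sentence_types.append(None)
            else:
                etype = types[rng.choice(len(types), p=weights)]
                built = _build_sentence(config, etype, rng)
                text = built.text
                for t, sb, se in built.spans:
                    spans.append(SpanAnnotation(
                        t, offset + sb, offset + se, text[sb:se], "gold"))
                sentence_types.append(etype)
            pieces.append(text)
            offset += len(text) + 1  # single space between sentences
        doc = Document.from_text(doc_id, " ".join(pieces))
        documents.append(doc)
        gold[doc_id] = spans
    return Corpus(documents, gold, sentence_types)


# ---------------------------------------------------------------------------
# Active-learning pool
# ---------------------------------------------------------------------------

def generate_al_pool(
    config: GeneratorConfig | None = None,
    n_seed_documents: int = 15,
    n_pool_documents: int = 160,
) -> tuple[Corpus, Corpus]:
    """A small labelled seed corpus plus a larger pool with hidden gold.

    Defaults mirror the annotation protocol's 15 seed abstracts and
    160-abstract pool.  Seed and pool documents are disjoint (distinct ids,
    independently sampled content).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    seed_cfg = GeneratorConfig(**{**config.__dict__,
                                  "n_documents": n_seed_documents})
    pool_cfg = GeneratorConfig(**{**config.__dict__,
                                  "n_documents": n_pool_documents})
    seed_corpus = generate_corpus(seed_cfg, rng)
    pool_corpus = generate_corpus(pool_cfg, rng)
    for doc in pool_corpus.documents:
        doc.doc_id = "pool_" + doc.doc_id
    pool_corpus.gold = {
        "pool_" + k: v for k, v in pool_corpus.gold.items()
    }
    return seed_corpus, pool_corpus


# ---------------------------------------------------------------------------
# Convenience extraction for the taggers
# ---------------------------------------------------------------------------

def bio_sentences(corpus: Corpus, entity_type: str):
    """(tokens, BIO labels) for every sentence of the corpus."""
    out = []
    for doc in corpus.documents:
        spans = corpus.gold[doc.doc_id]
        for sent in doc.sentences:
            toks = sent.tokens
            if toks:
                out.append((toks, spans_to_bio(toks, spans, entity_type)))
    return out
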