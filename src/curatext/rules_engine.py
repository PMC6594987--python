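"""Deterministic rule/dictionary annotator.

Covers: gazetteer longest-match over curated entity dictionaries,
noun-phrase-scoped entity regexes, unit gazetteer expansion (prefix × base),
numeric value detection with thousands/decimal validation, value–unit linking
within noun phrases, negative-sign absorption, and document-level acronym
propagation from parenthetical abbreviation definitions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .corpus_io import Document, SpanAnnotation, Token, tokenize
from .linguistics import NounPhrase, analyse, noun_phrases

# entity types with a bundled dictionary (no valid dictionary exists for
# experimental values; units come from the gazetteer instead)
DICTIONARY_TYPES = (
    "BrainRegion", "NeuronType", "ModelOrganism",
    "IonChannel", "IonCurrent", "IonConductance",
)

#: entries this short are matched case-sensitively (acronym behaviour)
CASE_SENSITIVE_MAX_LEN = 3


class GazetteerError(ValueError):
    """Malformed dictionary or gazetteer file."""


# ---------------------------------------------------------------------------
# Entity dictionaries
# ---------------------------------------------------------------------------

@dataclass
class EntityDictionary:
    entity_type: str
    entries: list[str]
    # token-tuple lookup tables, built on construction
    _exact: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)
    _folded: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)
    _max_len: int = 0

    def __post_init__(self) -> None:
        for entry in self.entries:
            if not entry.strip():
                raise GazetteerError("empty dictionary entry")
            toks = tuple(t.surface for t in tokenize(entry))
            self._max_len = max(self._max_len, len(toks))
            if len(entry) <= CASE_SENSITIVE_MAX_LEN:
                self._exact[toks] = entry
            else:
                self._folded[tuple(s.lower() for s in toks)] = entry


def _read_entry_file(text: str) -> list[str]:
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            entries.append(line)
    return entries


def load_dictionary(entity_type: str, path=None) -> EntityDictionary:
    """Load a bundled (or external, via ``path``) dictionary for one type."""
    if path is not None:
        text = open(path, encoding="utf-8").read()
    else:
        if entity_type not in DICTIONARY_TYPES:
            raise GazetteerError(f"no bundled dictionary for {entity_type!r}")
        text = resources.files("curatext.data").joinpath(
            f"dict_{entity_type}.txt"
        ).read_text("utf-8")
    return EntityDictionary(entity_type, _read_entry_file(text))


def derive_conductance_dictionary(current_entries: list[str]) -> list[str]:
    """Rewrite an ion-current dictionary into an ion-conductance one:
    the word "current" becomes "conductance"; single-token acronyms have
    their leading "I" replaced by "g" (IH -> gH)."""
    out = []
    for entry in current_entries:
        if "current" in entry.lower():
            entry = re.sub("current", "conductance", entry, flags=re.IGNORECASE)
        elif entry.startswith("I") and " " not in entry and len(entry) > 1:
            entry = "g" + entry[1:]
        if entry not in out:
            out.append(entry)
    return out


def dict_match(
    tokens: list[Token],
    dictionary: EntityDictionary,
    text: str | None = None,
) -> list[SpanAnnotation]:
    """Token-aligned leftmost-longest gazetteer matching.

    Matches never overlap one another within the dictionary's type: after a
    match the scan resumes past it.  Entries longer than
    ``CASE_SENSITIVE_MAX_LEN`` characters match case-insensitively; short
    entries (acronyms) match exactly.
    """
    surfaces = [t.surface for t in tokens]
    spans: list[SpanAnnotation] = []
    i = 0
    while i < len(tokens):
        hit = 0
        for L in range(min(dictionary._max_len, len(tokens) - i), 0, -1):
            window = tuple(surfaces[i:i + L])
            if (window in dictionary._exact
                    or tuple(s.lower() for s in window) in dictionary._folded):
                hit = L
                break
        if hit:
            b, e = tokens[i].begin, tokens[i + hit - 1].end
            surface = text[b:e] if text is not None else " ".join(surfaces[i:i + hit])
            spans.append(SpanAnnotation(dictionary.entity_type, b, e, surface,
                                        "dictionary"))
            i += hit
        else:
            i += 1
    return spans


# ---------------------------------------------------------------------------
# Noun-phrase-scoped entity regexes
# ---------------------------------------------------------------------------

NP_PATTERNS = {
    "NeuronType": re.compile(r"\b(neuron(e?s)?|cells?)\b", re.IGNORECASE),
    "IonCurrent": re.compile(r"\bcurrents?\b", re.IGNORECASE),
    "IonChannel": re.compile(r"\bchannels?\b", re.IGNORECASE),
    "IonConductance": re.compile(r"\bconductances?\b", re.IGNORECASE),
}


def regex_np_match(
    nps: list[NounPhrase],
    entity_type: str,
    text: str | None = None,
) -> list[SpanAnnotation]:
    """If a noun phrase contains a match of the type's pattern, the *whole*
    noun phrase becomes one span of that type."""
    pattern = NP_PATTERNS[entity_type]
    spans = []
    for np in nps:
        if pattern.search(np.text):
            surface = text[np.begin:np.end] if text is not None else np.text
            spans.append(SpanAnnotation(entity_type, np.begin, np.end, surface,
                                        "regex"))
    return spans


# ---------------------------------------------------------------------------
# Unit gazetteer
# ---------------------------------------------------------------------------

@dataclass
class UnitGazetteer:
    base_units: list[tuple[str, str]]   # (long name, short form)
    prefixes: list[tuple[str, str]]     # (long prefix, short prefix)


@dataclass
class UnitLexicon:
    """Expanded unit surface forms.

    ``long_forms`` (bare bases plus every prefix+base, e.g. "milligram",
    "kilometre") match case-insensitively with an optional plural "s".
    ``short_forms`` (bare and prefixed short forms, "mg", "km", "mV", plus
    long-prefix+short-base hybrids like "microM") match case-sensitively,
    except that the all-lowercase spelling of a short form is also accepted
    ("mv" for "mV" — informal text frequently drops the case); "MV" still
    does not match "mV".  Single-letter short forms additionally require a
    directly preceding digit to avoid swallowing ordinary words.
    """
    long_forms: set[str]
    short_forms: set[str]
    _short_lower: set[str] = field(default_factory=set)
    _single: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._short_lower = {s.lower() for s in self.short_forms}
        self._single = {s for s in self.short_forms if len(s) == 1}


def load_unit_gazetteer(units_path=None, prefixes_path=None) -> UnitGazetteer:
    def load(name, path):
        if path is not None:
            text = open(path, encoding="utf-8").read()
        else:
            text = resources.files("curatext.data").joinpath(name).read_text("utf-8")
        pairs = []
        for i, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(p.strip() for p in parts):
                raise GazetteerError(f"{name} line {i}: expected 'long<TAB>short'")
            pairs.append((parts[0].strip(), parts[1].strip()))
        return pairs

    return UnitGazetteer(load("units.tsv", units_path),
                         load("prefixes.tsv", prefixes_path))


def expand_unit_gazetteer(gazetteer: UnitGazetteer) -> UnitLexicon:
    """Every prefix × base combination, long and short, plus bare forms."""
    long_forms: set[str] = set()
    short_forms: set[str] = set()
    for base_long, base_short in gazetteer.base_units:
        long_forms.add(base_long.lower())
        short_forms.add(base_short)
        for pre_long, pre_short in gazetteer.prefixes:
            long_forms.add((pre_long + base_long).lower())
            short_forms.add(pre_short + base_short)
            short_forms.add(pre_long + base_short)  # hybrids: "microM"
    return UnitLexicon(long_forms, short_forms)


_LETTER_RUN_RE = re.compile(r"[A-Za-zµΩ]+")


def find_units(text: str, lexicon: UnitLexicon) -> list[SpanAnnotation]:
    """Unit mentions as maximal letter runs matched against the lexicon."""
    spans = []
    for m in _LETTER_RUN_RE.finditer(text):
        run = m.group()
        low = run.lower()
        is_long = low in lexicon.long_forms or (
            low.endswith("s") and low[:-1] in lexicon.long_forms
        )
        is_short = run in lexicon.short_forms or (
            run.islower() and run in lexicon._short_lower
        )
        if is_short and len(run) == 1:
            # bare single letters are units only right after a number
            before = text[:m.start()]
            if before.endswith(" "):
                before = before[:-1]
            if not (before and before[-1].isdigit()):
                is_short = False
        if is_long or is_short:
            spans.append(SpanAnnotation("Unit", m.start(), m.end(), run,
                                        "dictionary"))
    return spans


# ---------------------------------------------------------------------------
# Experimental values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumericValue:
    begin: int
    end: int
    surface: str
    value: float


_VALUE_RE = re.compile(r"\d+(?:,\d{3})*(?:\.\d+)?")
_SAMPLE_SIZE_RE = re.compile(r"[nN]\s*=\s*$")
_MINUS = "-−"


def detect_values(text: str) -> list[NumericValue]:
    """Well-formed integers, thousands-grouped integers, and decimals.

    Candidates embedded in malformed decimal/thousands context ("1.1.1.1",
    "1,23") or glued to a preceding letter (gene/channel names such as
    "Cav3.1") are rejected.  A directly preceding minus sign (ASCII "-" or
    Unicode "−", up to one intervening space) is absorbed unless the token
    before it is itself a number — that situation is a range or list, not a
    negative number.
    """
    values: list[NumericValue] = []
    for m in _VALUE_RE.finditer(text):
        b, e = m.start(), m.end()
        before, after = text[:b], text[e:]
        # reject malformed decimal / thousands context
        if len(before) >= 2 and before[-1] in ".," and before[-2].isdigit():
            continue
        if len(after) >= 2 and after[0] in ".," and after[1].isdigit():
            continue
        # reject digits glued to an identifier
        if before and (before[-1].isalpha() or before[-1] == "_"):
            continue
        surface, value = m.group(), float(m.group().replace(",", ""))
        # negative-sign absorption
        stripped = before[:-1] if before.endswith(" ") else before
        if stripped and stripped[-1] in _MINUS:
            prior = stripped[:-1].rstrip()
            if not (prior and prior[-1].isdigit()):
                b = len(stripped) - 1
                surface, value = text[b:e], -value
        values.append(NumericValue(b, e, surface, value))
    return values


def is_sample_size(text: str, value: NumericValue) -> bool:
    """Sample sizes ("n = 12") are not experimental values."""
    return bool(_SAMPLE_SIZE_RE.search(text[:value.begin]))


def pair_values_units(
    values: list[NumericValue],
    units: list[SpanAnnotation],
    nps: list[NounPhrase],
) -> list[tuple[NumericValue, SpanAnnotation | None]]:
    """Link each value to a unit sharing its noun phrase (nearest unit at or
    after the value wins; otherwise nearest before)."""
    pairs: list[tuple[NumericValue, SpanAnnotation | None]] = []
    for v in values:
        np = next((p for p in nps if p.covers(v.begin, v.end)), None)
        unit: SpanAnnotation | None = None
        if np is not None:
            in_np = [u for u in units if np.covers(u.begin, u.end)]
            following = [u for u in in_np if u.begin >= v.end]
            preceding = [u for u in in_np if u.end <= v.begin]
            if following:
                unit = min(following, key=lambda u: u.begin)
            elif preceding:
                unit = max(preceding, key=lambda u: u.end)
        pairs.append((v, unit))
    return pairs


def link_value_unit(
    values: list[NumericValue],
    units: list[SpanAnnotation],
    nps: list[NounPhrase],
    text: str,
) -> list[SpanAnnotation]:
    """Emit ExperimentalValue spans (plus the Unit spans themselves).

    A value whose linked unit directly follows it (at most one intervening
    space) is emitted as one span covering value and unit ("12.5 microM");
    in ranges or lists where the unit sits only at the end, earlier values
    are emitted bare but still linked.  Values with no unit are emitted too.
    Sample sizes ("n = 12") are excluded.
    """
    spans: list[SpanAnnotation] = list(units)
    for v, unit in pair_values_units(values, units, nps):
        if is_sample_size(text, v):
            continue
        b, e = v.begin, v.end
        if unit is not None and 0 <= unit.begin - v.end <= 1 \
                and text[v.end:unit.begin] in ("", " "):
            e = unit.end
        spans.append(SpanAnnotation("ExperimentalValue", b, e, text[b:e], "regex"))
    return spans


# ---------------------------------------------------------------------------
# Abbreviations and acronym propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Abbreviation:
    short: str
    short_begin: int
    short_end: int
    long: str
    long_begin: int
    long_end: int


_PAREN_RE = re.compile(r"\(([^()]{1,12})\)")


def find_abbreviations(text: str) -> list[Abbreviation]:
    """Parenthetical "LONG FORM (SF)" definitions.

    A short-form candidate is validated by character overlap with the
    preceding words: the long form starts at the rightmost preceding word
    sharing the short form's initial letter, and at least half of the short
    form's letters must appear, in order, in the long form.
    """
    out: list[Abbreviation] = []
    for m in _PAREN_RE.finditer(text):
        sf = m.group(1).strip()
        if not (2 <= len(sf) <= 10) or not sf[0].isalpha() or " " in sf:
            continue
        prefix = text[:m.start()].rstrip()
        words = []
        for wm in re.finditer(r"\S+", prefix):
            words.append((wm.group().strip(".,;:"), wm.start()))
        words = words[-(len(sf) + 5):]
        start_idx = None
        for i in range(len(words) - 1, -1, -1):
            if words[i][0][:1].lower() == sf[0].lower():
                start_idx = i
                break
        if start_idx is None:
            continue
        lf_begin = words[start_idx][1]
        lf_end = len(prefix)
        long_form = text[lf_begin:lf_end]
        if len(long_form.split()) > len(sf) + 2:
            continue
        # in-order character overlap over at least half the short form
        matched, j = 0, 0
        low_long = long_form.lower()
        for c in sf.lower():
            k = low_long.find(c, j)
            if k >= 0:
                matched, j = matched + 1, k + 1
        if matched * 2 < len(sf):
            continue
        out.append(Abbreviation(sf, m.start(1), m.end(1),
                                long_form, lf_begin, lf_end))
    return out


def propagate_acronyms(
    text: str,
    annotations: list[SpanAnnotation],
    abbreviations: list[Abbreviation],
) -> list[SpanAnnotation]:
    """If an abbreviation's expanded form is annotated with type T anywhere
    in the document, every occurrence of the short form gains a type-T span
    (source "acronym"); existing identical spans are not duplicated."""
    out = list(annotations)
    existing = {(a.entity_type, a.begin, a.end) for a in annotations}
    for abbr in abbreviations:
        types = {
            a.entity_type for a in annotations
            if a.source != "acronym"
            and a.begin <= abbr.long_begin and abbr.long_end <= a.end
        }
        if not types:
            continue
        sf_re = re.compile(r"(?<![\w-])" + re.escape(abbr.short) + r"(?![\w-])")
        for m in sf_re.finditer(text):
            for etype in sorted(types):
                key = (etype, m.start(), m.end())
                if key in existing:
                    continue
                existing.add(key)
                out.append(SpanAnnotation(etype, m.start(), m.end(),
                                          abbr.short, "acronym"))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def load_all_dictionaries() -> dict[str, EntityDictionary]:
    return {t: load_dictionary(t) for t in DICTIONARY_TYPES}


def annotate(
    document: Document | str,
    dictionaries: dict[str, EntityDictionary] | None = None,
    unit_lexicon: UnitLexicon | None = None,
    entity_types: list[str] | None = None,
) -> list[SpanAnnotation]:
    """Run the full rule/dictionary pipeline over one document.

    Dictionary matching, NP-scoped regexes, unit and value detection with
    linking, then document-level acronym propagation.  ``entity_types``
    restricts the output (default: all eight types).
    """
    if isinstance(document, str):
        document = Document.from_text("doc", document)
    if dictionaries is None:
        dictionaries = load_all_dictionaries()
    if unit_lexicon is None:
        unit_lexicon = expand_unit_gazetteer(load_unit_gazetteer())
    text = document.text

    spans: list[SpanAnnotation] = []
    seen: set[tuple[str, int, int]] = set()

    def add(candidates):
        for s in candidates:
            key = (s.entity_type, s.begin, s.end)
            if key not in seen:
                seen.add(key)
                spans.append(s)

    for sent in document.sentences:
        tokens = sent.tokens
        _, _, chunks = analyse(tokens)
        nps = noun_phrases(tokens, chunks)
        for dictionary in dictionaries.values():
            add(dict_match(tokens, dictionary, text))
        for etype in NP_PATTERNS:
            add(regex_np_match(nps, etype, text))
        sent_text = text[sent.begin:sent.end]
        units = [
            SpanAnnotation(u.entity_type, u.begin + sent.begin,
                           u.end + sent.begin, u.surface, u.source)
            for u in find_units(sent_text, unit_lexicon)
        ]
        values = [
            NumericValue(v.begin + sent.begin, v.end + sent.begin,
                         v.surface, v.value)
            for v in detect_values(sent_text)
        ]
        add(link_value_unit(values, units, nps, text))

    spans = propagate_acronyms(text, spans, find_abbreviations(text))
    if entity_types is not None:
        spans = [s for s in spans if s.entity_type in entity_types]
    return sorted(spans, key=lambda s: (s.begin, s.end, s.entity_type))
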