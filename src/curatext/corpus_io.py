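"""Documents, tokens, typed spans, BIO sequences, and brat/TSV interchange.

Everything downstream (rules, CRF, neural tagger, evaluation) operates on the
types defined here.  Offsets are 0-based and end-exclusive throughout: for any
token, ``end - begin == len(surface)``.

Two offset conventions coexist and are explicit in the API:

* ``raw`` — offsets index into the original document text (used by brat).
* ``detokenized`` — offsets index into the token stream re-joined with single
  spaces.  Feature tables printed in the token-per-line format use this
  convention, which is only consistent under single-space joining.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger("curatext")

#: The eight entity types of the annotation scheme.
ENTITY_TYPES = (
    "BrainRegion",
    "NeuronType",
    "ModelOrganism",
    "IonChannel",
    "IonCurrent",
    "IonConductance",
    "ExperimentalValue",
    "Unit",
)

#: Provenance tags for annotations.
SOURCES = ("gold", "dictionary", "regex", "crf", "neural", "acronym")


class CorpusError(ValueError):
    """Malformed corpus input (brat/TSV grammar, misaligned labels...)."""


# ---------------------------------------------------------------------------
# Tokens and documents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    surface: str
    begin: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.begin != len(self.surface):
            raise CorpusError(
                f"token offset arithmetic broken: {self!r}"
            )


@dataclass(frozen=True)
class SpanAnnotation:
    """A typed entity mention anchored to character offsets.

    ``surface`` must equal ``text[begin:end]`` of the document the span
    belongs to.  Overlapping spans of *different* types are legal (a brain
    region acronym inside a neuron-type mention, for instance).
    """

    entity_type: str
    begin: int
    end: int
    surface: str
    source: str = "gold"

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise CorpusError(f"unknown entity type: {self.entity_type!r}")
        if self.source not in SOURCES:
            raise CorpusError(f"unknown annotation source: {self.source!r}")
        if not self.begin < self.end:
            raise CorpusError(f"empty or inverted span: {self!r}")

    def overlaps(self, other: "SpanAnnotation") -> bool:
        return self.begin < other.end and other.begin < self.end


@dataclass
class Sentence:
    begin: int
    end: int
    text: str
    tokens: list[Token] = field(default_factory=list)


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    @classmethod
    def from_text(cls, doc_id: str, text: str) -> "Document":
        doc = cls(doc_id=doc_id, text=text)
        for b, e in split_sentences(text):
            sent = Sentence(begin=b, end=e, text=text[b:e])
            sent.tokens = [
                Token(t.surface, t.begin + b, t.end + b)
                for t in tokenize(text[b:e])
            ]
            doc.sentences.append(sent)
        return doc


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_LEAD_PUNCT = set("([{\"'‘“")
_TRAIL_PUNCT = set(")]}\"'’”:;,.!?")
_CHUNK_RE = re.compile(r"\S+")
# hyphen between two letters: split *before* the hyphen ("Whole-cell")
_HYPHEN_SPLIT_RE = re.compile(r"(?<=[A-Za-z])(?=-[A-Za-z])")


def tokenize(text: str, offsets: str = "raw") -> list[Token]:
    """Rule-based tokenizer.

    Whitespace-delimited chunks are split further: leading/trailing
    punctuation becomes standalone tokens and hyphenated compounds are split
    before the hyphen.  ``offsets="raw"`` indexes into ``text``;
    ``offsets="detokenized"`` re-numbers offsets as if tokens were joined by
    single spaces.  Empty input yields an empty list.
    """
    if offsets not in ("raw", "detokenized"):
        raise ValueError(f"unknown offset convention: {offsets!r}")
    tokens: list[Token] = []
    for m in _CHUNK_RE.finditer(text):
        tokens.extend(_split_chunk(m.group(), m.start()))
    if offsets == "detokenized":
        tokens = detokenized_offsets(tokens)
    return tokens


def _split_chunk(chunk: str, start: int) -> list[Token]:
    out: list[Token] = []
    # peel leading punctuation
    while chunk and chunk[0] in _LEAD_PUNCT:
        out.append(Token(chunk[0], start, start + 1))
        chunk, start = chunk[1:], start + 1
    # peel trailing punctuation (emitted after the core, in order)
    tail: list[Token] = []
    while chunk and chunk[-1] in _TRAIL_PUNCT:
        tail.append(Token(chunk[-1], start + len(chunk) - 1, start + len(chunk)))
        chunk = chunk[:-1]
    if chunk:
        pos = start
        for piece in _HYPHEN_SPLIT_RE.split(chunk):
            out.append(Token(piece, pos, pos + len(piece)))
            pos += len(piece)
    out.extend(reversed(tail))
    return out


def detokenized_offsets(tokens: list[Token]) -> list[Token]:
    """Re-number token offsets over the single-space-joined token stream."""
    out, pos = [], 0
    for t in tokens:
        out.append(Token(t.surface, pos, pos + len(t.surface)))
        pos += len(t.surface) + 1
    return out


def detokenize(tokens: list[Token]) -> str:
    return " ".join(t.surface for t in tokens)


_ABBREV_GUARD = {
    "e.g", "i.e", "al", "fig", "figs", "vs", "ca", "cf", "approx",
    "no", "dr", "st", "etc", "resp",
}
_SENT_BOUNDARY_RE = re.compile(r"(?<=[.?!])\s+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence splitting on ``. ``/``? ``/``! `` with an
    abbreviation guard list.  Returns (begin, end) character ranges."""
    def trimmed(b: int, e: int) -> tuple[int, int]:
        while b < e and text[b].isspace():
            b += 1
        while e > b and text[e - 1].isspace():
            e -= 1
        return b, e

    bounds: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        prev = text[start:m.start()]
        last_word = prev.rsplit(None, 1)[-1] if prev.split() else ""
        if last_word.rstrip(".!?").lower() in _ABBREV_GUARD:
            continue
        if prev.strip():
            bounds.append(trimmed(start, m.start()))
        start = m.end()
    if text[start:].strip():
        bounds.append(trimmed(start, len(text)))
    return bounds


# ---------------------------------------------------------------------------
# BIO encoding / decoding
# ---------------------------------------------------------------------------

def spans_to_bio(
    tokens: list[Token],
    annotations: list[SpanAnnotation],
    entity_type: str,
    on_misaligned: str = "snap",
) -> list[str]:
    """Encode token-aligned spans of ``entity_type`` as B/I/O labels.

    Annotations of other entity types are ignored.  Spans whose boundaries
    cross a token are handled per ``on_misaligned``: ``"snap"`` (default)
    snaps outward to the covering tokens (logged), ``"reject"`` raises.
    """
    if on_misaligned not in ("snap", "reject"):
        raise ValueError(f"unknown misalignment policy: {on_misaligned!r}")
    labels = ["O"] * len(tokens)
    for ann in annotations:
        if ann.entity_type != entity_type:
            continue
        covered = [
            i for i, t in enumerate(tokens)
            if t.begin < ann.end and ann.begin < t.end
        ]
        if not covered:
            continue
        first, last = covered[0], covered[-1]
        if tokens[first].begin != ann.begin or tokens[last].end != ann.end:
            if on_misaligned == "reject":
                raise CorpusError(f"annotation crosses token boundary: {ann!r}")
            logger.warning("snapping misaligned annotation outward: %r", ann)
        labels[first] = f"B-{entity_type}"
        for i in covered[1:]:
            labels[i] = f"I-{entity_type}"
    return labels


def bio_to_spans(
    tokens: list[Token],
    labels: list[str],
    entity_type: str,
    text: str | None = None,
    source: str = "gold",
) -> list[SpanAnnotation]:
    """Decode B/I/O labels into spans (inverse of :func:`spans_to_bio`).

    A dangling ``I-`` (sequence start or preceded by ``O``) is repaired to
    ``B-`` with a warning, so decoding is total.  ``text`` recovers the exact
    surface; without it, token surfaces are joined with single spaces.
    """
    if len(labels) != len(tokens):
        raise CorpusError(
            f"label/token length mismatch: {len(labels)} vs {len(tokens)}"
        )
    spans: list[SpanAnnotation] = []
    run: list[int] = []

    def flush() -> None:
        if run:
            b, e = tokens[run[0]].begin, tokens[run[-1]].end
            surface = text[b:e] if text is not None else detokenize(
                [tokens[i] for i in run]
            )
            spans.append(SpanAnnotation(entity_type, b, e, surface, source))
            run.clear()

    prev = "O"
    for i, lab in enumerate(labels):
        kind = lab.split("-", 1)[0]
        if kind == "I" and prev == "O":
            logger.warning("dangling I- label at token %d repaired to B-", i)
            kind = "B"
        if kind == "B":
            flush()
            run.append(i)
        elif kind == "I":
            run.append(i)
        else:
            flush()
        prev = "O" if kind == "O" else kind
    flush()
    return spans


# ---------------------------------------------------------------------------
# brat standoff
# ---------------------------------------------------------------------------

_BRAT_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_brat(
    txt_content: str,
    ann_content: str,
    doc_id: str = "doc",
    unknown_types: str = "skip",
) -> tuple[Document, list[SpanAnnotation]]:
    """Parse a brat ``.txt`` + ``.ann`` pair.

    Only T-lines are consumed; other line types are ignored with a warning.
    Offsets are validated against the text; a surface/offset mismatch raises
    :class:`CorpusError` naming the line.  Unknown entity types are skipped
    with a warning (``unknown_types="error"`` raises instead).  Overlapping
    annotations of different types are preserved.
    """
    doc = Document.from_text(doc_id, txt_content)
    anns: list[SpanAnnotation] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("%s ann line %d: ignoring non-T line", doc_id, lineno)
            continue
        m = _BRAT_T_RE.match(line)
        if not m:
            raise CorpusError(f"{doc_id} ann line {lineno}: malformed T-line")
        _, etype, b, e, surface = m.groups()
        b, e = int(b), int(e)
        if etype not in ENTITY_TYPES:
            if unknown_types == "error":
                raise CorpusError(
                    f"{doc_id} ann line {lineno}: unknown type {etype!r}"
                )
            logger.warning(
                "%s ann line %d: skipping unknown type %r", doc_id, lineno, etype
            )
            continue
        if txt_content[b:e] != surface:
            raise CorpusError(
                f"{doc_id} ann line {lineno}: surface mismatch: "
                f"{surface!r} != text[{b}:{e}]={txt_content[b:e]!r}"
            )
        anns.append(SpanAnnotation(etype, b, e, surface, "gold"))
    return doc, anns


def write_brat(
    document: Document, annotations: list[SpanAnnotation]
) -> tuple[str, str]:
    """Serialize to a brat ``.txt`` + ``.ann`` content pair."""
    lines = []
    for i, ann in enumerate(
        sorted(annotations, key=lambda a: (a.begin, a.end, a.entity_type)),
        start=1,
    ):
        lines.append(f"T{i}\t{ann.entity_type} {ann.begin} {ann.end}\t{ann.surface}")
    return document.text, "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Token-per-line TSV
# ---------------------------------------------------------------------------

#: Fixed column order of the token-per-line interchange format.
TSV_COLUMNS = ("Begin", "End", "Word", "Lemma", "POS", "Chunk", "Dict", "GoldLabel")


def write_tsv(sentences: list[list[list[str]]]) -> str:
    """Write sentences of rows (each row a list of string fields) as TSV with
    a blank line between sentences.  Round-trips byte-identically."""
    blocks = []
    for rows in sentences:
        blocks.append("\n".join("\t".join(map(str, r)) for r in rows))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_tsv(content: str) -> list[list[list[str]]]:
    """Inverse of :func:`write_tsv`.  Ragged rows raise with the row index."""
    sentences: list[list[list[str]]] = []
    width: int | None = None
    current: list[list[str]] = []
    for i, line in enumerate(content.splitlines()):
        if not line.strip():
            if current:
                sentences.append(current)
                current = []
            continue
        row = line.split("\t")
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise CorpusError(f"ragged TSV row {i}: {len(row)} != {width} fields")
        current.append(row)
    if current:
        sentences.append(current)
    return sentences


__all__ = [
    "ENTITY_TYPES", "SOURCES", "CorpusError", "Token", "SpanAnnotation",
    "Sentence", "Document", "tokenize", "detokenized_offsets", "detokenize",
    "split_sentences", "spans_to_bio", "bio_to_spans", "read_brat",
    "write_brat", "TSV_COLUMNS", "write_tsv", "read_tsv",
]
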