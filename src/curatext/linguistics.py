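"""Bundled POS tagging, lemmatization, and noun-phrase chunking.

The feature schema consumed by the CRF needs, per token: a lemma, a
part-of-speech tag (Penn Treebank codes) and a syntactic chunk label (BIO
over NP/VP/PP/ADVP).  Any backend satisfying that contract can be plugged in;
this module ships a dependency-light rule-based provider: a lexicon+suffix
POS tagger, a lookup lemmatizer with identity fallback, and a regex-over-POS
chunker.  It is deliberately small — enough to drive dictionary scoping and
value–unit linking, not a general-purpose parser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .corpus_io import Token

_NUM_RE = re.compile(r"^[−-]?\d+(,\d{3})*(\.\d+)?$")

# latinisms tagged FW as a pair ("in vivo", "in vitro", "in situ")
_LATIN_SECOND = {"vivo", "vitro", "situ", "toto"}

_NP_START = {"DT", "PRP$"}
_NP_WORD = {"JJ", "JJR", "JJS", "NN", "NNS", "NNP", "NNPS", "CD"}
_VP = {"VB", "VBD", "VBZ", "VBP", "VBN", "VBG", "MD"}


def _load_lexicon(name: str) -> dict[str, str]:
    table = {}
    text = resources.files("curatext.data").joinpath(name).read_text("utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = value
    return table


_POS_LEXICON = _load_lexicon("pos_lexicon.tsv")
_LEMMA_LEXICON = _load_lexicon("lemma_lexicon.tsv")


def pos_tag(tokens: list[Token]) -> list[str]:
    """Penn-Treebank-style tags from a lexicon plus suffix heuristics."""
    tags: list[str] = []
    surfaces = [t.surface for t in tokens]
    for i, w in enumerate(surfaces):
        low = w.lower()
        if not any(c.isalnum() for c in w):
            tags.append(w if w in "():,." else "SYM")
        elif low == "in" and i + 1 < len(surfaces) and surfaces[i + 1].lower() in _LATIN_SECOND:
            tags.append("FW")
        elif low in _LATIN_SECOND and i > 0 and surfaces[i - 1].lower() == "in":
            tags.append("FW")
        elif _NUM_RE.match(w):
            tags.append("CD")
        elif low in _POS_LEXICON:
            tags.append(_POS_LEXICON[low])
        else:
            tags.append(_suffix_tag(w))
    return tags


def _suffix_tag(w: str) -> str:
    if w.startswith("-"):
        return "JJ"
    low = w.lower()
    if low.endswith("ly"):
        return "RB"
    if low.endswith(("al", "ic", "ive", "ous", "ar", "ary", "ior")):
        return "JJ"
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBD"
    if low.endswith("s") and len(low) > 3 and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def lemmatize(word: str, pos: str) -> str:
    """Base form by dictionary lookup; plural stripping for NNS; identity
    fallback (casing preserved — biomedical casing is meaningful)."""
    low = word.lower()
    if low in _LEMMA_LEXICON:
        return _LEMMA_LEXICON[low]
    if pos == "NNS":
        if low.endswith(("ches", "shes", "sses", "xes", "zes")):
            return word[:-2]
        if low.endswith("ies") and len(low) > 4:
            return word[:-3] + "y"
        if low.endswith("s"):
            return word[:-1]
    return word


def chunk_tag(tokens: list[Token], pos: list[str]) -> list[str]:
    """BIO chunk labels (NP, VP, PP, ADVP) from POS tags.

    Coordination and range glue (",", "and"/"or", "to", a bare minus sign)
    stay inside a noun phrase when flanked by NP material, so that lists like
    "15, 30 and 45 millimetres" and ranges like "−100 to −40 mV" form a
    single NP — the scope used for value–unit linking.
    """
    chunks: list[str] = []
    prev = "O"
    n = len(pos)
    for i, p in enumerate(pos):
        nxt = pos[i + 1] if i + 1 < n else None
        in_np = prev.endswith("NP")
        if p == "FW":
            label = "I-ADVP" if prev.endswith("ADVP") else "B-ADVP"
        elif p in _NP_START:
            label = "B-NP"
        elif p in _NP_WORD:
            label = "I-NP" if in_np else "B-NP"
        elif (p in {",", "CC", "TO", "SYM"} and in_np
              and (nxt in _NP_WORD or nxt == "SYM")):
            label = "I-NP"
        elif p in _VP:
            label = "I-VP" if prev.endswith("VP") else "B-VP"
        elif p in {"IN", "TO"}:
            label = "B-PP"
        elif p == "RB":
            label = "B-ADVP"
        else:
            label = "O"
        chunks.append(label)
        prev = label
    return chunks


@dataclass(frozen=True)
class NounPhrase:
    """A maximal B-NP/I-NP run, in the coordinate system of its tokens."""
    begin: int
    end: int
    tokens: tuple[Token, ...]

    @property
    def text(self) -> str:
        return " ".join(t.surface for t in self.tokens)

    def covers(self, begin: int, end: int) -> bool:
        return self.begin <= begin and end <= self.end


def noun_phrases(tokens: list[Token], chunks: list[str]) -> list[NounPhrase]:
    """Extract noun phrases from chunk BIO runs."""
    out: list[NounPhrase] = []
    run: list[Token] = []
    for t, c in zip(tokens, chunks):
        if c == "B-NP":
            if run:
                out.append(NounPhrase(run[0].begin, run[-1].end, tuple(run)))
            run = [t]
        elif c == "I-NP" and run:
            run.append(t)
        else:
            if run:
                out.append(NounPhrase(run[0].begin, run[-1].end, tuple(run)))
            run = []
    if run:
        out.append(NounPhrase(run[0].begin, run[-1].end, tuple(run)))
    return out


def analyse(tokens: list[Token]) -> tuple[list[str], list[str], list[str]]:
    """Convenience: (lemmas, POS tags, chunk labels) for a token sequence."""
    pos = pos_tag(tokens)
    lemmas = [lemmatize(t.surface, p) for t, p in zip(tokens, pos)]
    chunks = chunk_tag(tokens, pos)
    return lemmas, pos, chunks
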