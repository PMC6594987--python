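"""Dictionary matching, NP-scoped regexes, units, values, and acronyms."""

import pytest

from curatext.corpus_io import SpanAnnotation, tokenize
from curatext.linguistics import analyse, noun_phrases
from curatext import rules_engine as R


@pytest.fixture(scope="module")
def brain_dict():
    return R.load_dictionary("BrainRegion")


@pytest.fixture(scope="module")
def unit_lexicon():
    return R.expand_unit_gazetteer(R.load_unit_gazetteer())


def nps_of(text):
    toks = tokenize(text)
    _, _, chunks = analyse(toks)
    return noun_phrases(toks, chunks)


# ---------------------------------------------------------------------------
# Dictionary matching
# ---------------------------------------------------------------------------

class TestDictMatch:
    def test_finds_known_region_and_acronym_not_complex_phrase(self, brain_dict):
        """On the rostral-pole sentence the gazetteer finds only the simpler
        known term plus the acronym, not the full gold phrase."""
        text = ("curve partially around the rostral pole of the ventral "
                "posteromedial nucleus (VPM)")
        spans = R.dict_match(tokenize(text), brain_dict, text)
        assert [s.surface for s in spans] == ["ventral posteromedial nucleus",
                                              "VPM"]
        assert all(s.source == "dictionary" for s in spans)

    def test_unlisted_phrase_yields_nothing(self, brain_dict):
        text = "and the other population projected mainly to orbital or cingulate areas."
        assert R.dict_match(tokenize(text), brain_dict, text) == []

    def test_partial_coverage_of_unlisted_variants(self, brain_dict):
        """"ventrobasal complex" is known; "posterior nucleus" is not, so
        only its head noun matches; unlisted acronyms are missed."""
        text = "from the rat ventrobasal complex (VB) and posterior nucleus (POm)."
        spans = R.dict_match(tokenize(text), brain_dict, text)
        assert [s.surface for s in spans] == ["ventrobasal complex", "nucleus"]

    def test_empty_dictionary_matches_nothing(self):
        d = R.EntityDictionary("BrainRegion", [])
        assert R.dict_match(tokenize("the thalamus"), d) == []

    def test_short_entries_case_sensitive_long_entries_folded(self):
        d = R.EntityDictionary("BrainRegion", ["VPM", "Ventrobasal Complex"])
        assert R.dict_match(tokenize("the vpm region"), d) == []
        assert len(R.dict_match(tokenize("the VPM region"), d)) == 1
        assert len(R.dict_match(tokenize("the ventrobasal complex"), d)) == 1

    def test_leftmost_longest_against_brute_force(self):
        """Greedy gazetteer semantics equal an exhaustive oracle that scans
        positions left to right taking the longest entry at each start."""
        entries = ["alpha", "alpha beta", "beta gamma", "gamma", "delta"]
        d = R.EntityDictionary("NeuronType", entries)
        entry_toks = [tuple(t.surface for t in tokenize(e)) for e in entries]
        for text in [
            "alpha beta gamma delta",
            "x alpha beta beta gamma y",
            "gamma alpha alpha beta",
            "beta gamma gamma delta alpha",
        ]:
            toks = tokenize(text)
            surfaces = [t.surface for t in toks]
            expected, i = [], 0
            while i < len(surfaces):
                best = 0
                for et in entry_toks:
                    if tuple(surfaces[i:i + len(et)]) == et:
                        best = max(best, len(et))
                if best:
                    expected.append((toks[i].begin, toks[i + best - 1].end))
                    i += best
                else:
                    i += 1
            got = [(s.begin, s.end) for s in R.dict_match(toks, d)]
            assert got == expected

    def test_matches_never_overlap_within_type(self, brain_dict, synthetic_corpus):
        for doc in synthetic_corpus.documents[:8]:
            for sent in doc.sentences:
                spans = R.dict_match(sent.tokens, brain_dict)
                for a, b in zip(spans, spans[1:]):
                    assert a.end <= b.begin


class TestConductanceDerivation:
    def test_bundled_file_is_rewrite_of_current_file(self):
        currents = R.load_dictionary("IonCurrent").entries
        conductances = R.load_dictionary("IonConductance").entries
        assert R.derive_conductance_dictionary(currents) == conductances

    def test_rewrite_rules(self):
        assert R.derive_conductance_dictionary(["sodium current"]) == \
            ["sodium conductance"]
        assert R.derive_conductance_dictionary(["IH"]) == ["gH"]


# ---------------------------------------------------------------------------
# NP-scoped regexes
# ---------------------------------------------------------------------------

class TestRegexNP:
    @pytest.mark.parametrize("text,etype", [
        ("T-type Ca2+ channels", "IonChannel"),
        ("T-type Ca2+ conductance", "IonConductance"),
        ("the fast sodium currents", "IonCurrent"),
        ("SCN neurons", "NeuronType"),
    ])
    def test_whole_noun_phrase_becomes_span(self, text, etype):
        spans = R.regex_np_match(nps_of(text), etype, text)
        assert len(spans) == 1
        np = nps_of(text)[0]
        assert (spans[0].begin, spans[0].end) == (np.begin, np.end)

    def test_non_matching_phrase(self):
        assert R.regex_np_match(nps_of("membrane potential"), "IonChannel") == []

    def test_cue_must_be_whole_word(self):
        # "cellular" must not trigger the neuron pattern
        assert R.regex_np_match(nps_of("cellular cascades"), "NeuronType") == []


# ---------------------------------------------------------------------------
# Unit gazetteer
# ---------------------------------------------------------------------------

class TestUnitGazetteer:
    def test_expansion_contains_printed_examples(self, unit_lexicon):
        for form in ("milligram", "kilometre", "volt", "gram"):
            assert form in unit_lexicon.long_forms
        for form in ("mg", "km", "mm", "mV", "microM"):
            assert form in unit_lexicon.short_forms

    def test_long_form_count_is_prefixes_plus_bare_times_bases(self, unit_lexicon):
        gaz = R.load_unit_gazetteer()
        assert len(gaz.base_units) == 24
        assert len(gaz.prefixes) == 19
        assert len(unit_lexicon.long_forms) == 24 * (19 + 1)

    def test_malformed_gazetteer_file_names_line(self, tmp_path):
        bad = tmp_path / "units.tsv"
        bad.write_text("volt\tV\nbroken line without tab\n", "utf-8")
        with pytest.raises(R.GazetteerError, match="line 2"):
            R.load_unit_gazetteer(units_path=bad)

    def test_short_form_case_handling(self, unit_lexicon):
        assert [u.surface for u in R.find_units("10-20mv", unit_lexicon)] == ["mv"]
        # "MV" is not the lowercase of "mV": it is mega+volt, a distinct form
        assert [u.surface for u in R.find_units("5 MV", unit_lexicon)] == ["MV"]
        assert R.find_units("T-type", unit_lexicon) == []

    def test_single_letter_units_need_preceding_digit(self, unit_lexicon):
        assert [u.surface for u in R.find_units("5 V", unit_lexicon)] == ["V"]
        assert R.find_units("V was measured", unit_lexicon) == []

    def test_long_forms_match_plurals_case_insensitively(self, unit_lexicon):
        found = [u.surface for u in
                 R.find_units("45 Millimetres apart", unit_lexicon)]
        assert found == ["Millimetres"]


# ---------------------------------------------------------------------------
# Value detection
# ---------------------------------------------------------------------------

class TestDetectValues:
    def test_thousands_grouped_integer_is_single_span(self):
        vals = R.detect_values("23,400,500")
        assert [(v.surface, v.value) for v in vals] == [("23,400,500", 23400500.0)]

    def test_hierarchical_number_rejected(self):
        assert R.detect_values("1.1.1.1") == []

    def test_malformed_thousands_rejected(self):
        assert R.detect_values("1,23") == []
        assert R.detect_values("34,567,1") == []

    def test_negative_range_absorbs_both_signs(self):
        vals = R.detect_values("−100 to − 40 mV")
        assert [v.value for v in vals] == [-100.0, -40.0]
        assert [v.surface for v in vals] == ["−100", "− 40"]

    def test_hyphen_between_numbers_is_a_range_not_a_sign(self):
        vals = R.detect_values("10-20mv")
        assert [v.value for v in vals] == [10.0, 20.0]

    def test_digits_glued_to_identifier_rejected(self):
        assert R.detect_values("CaV3.1 channels") == []

    def test_surfaces_always_parse_as_numbers(self, synthetic_corpus):
        for doc in synthetic_corpus.documents:
            for v in R.detect_values(doc.text):
                parsed = float(
                    v.surface.replace(",", "").replace("−", "-").replace(" ", ""))
                assert parsed == v.value


# ---------------------------------------------------------------------------
# Value–unit linking
# ---------------------------------------------------------------------------

class TestLinking:
    def link(self, text, unit_lexicon):
        toks = tokenize(text)
        _, _, chunks = analyse(toks)
        nps = noun_phrases(toks, chunks)
        values = R.detect_values(text)
        units = R.find_units(text, unit_lexicon)
        return values, units, nps, R.link_value_unit(values, units, nps, text)

    def test_range_with_trailing_unit(self, unit_lexicon):
        values, units, nps, spans = self.link("10-20mv", unit_lexicon)
        pairs = R.pair_values_units(values, units, nps)
        assert all(u is not None and u.surface == "mv" for _, u in pairs)
        ev = [s.surface for s in spans if s.entity_type == "ExperimentalValue"]
        assert ev == ["10", "20mv"]

    def test_list_with_unit_only_at_end(self, unit_lexicon):
        values, units, nps, spans = self.link(
            "15, 30 and 45 millimetres", unit_lexicon)
        pairs = R.pair_values_units(values, units, nps)
        assert len(pairs) == 3
        assert all(u is not None and u.surface == "millimetres" for _, u in pairs)

    def test_parenthesized_value_with_unit(self, unit_lexicon):
        _, _, _, spans = self.link(
            "The effect of bicuculline (12.5 microM) on firing", unit_lexicon)
        assert ("Unit", "microM") in [(s.entity_type, s.surface) for s in spans]
        assert ("ExperimentalValue", "12.5 microM") in \
            [(s.entity_type, s.surface) for s in spans]

    def test_sample_sizes_excluded(self, unit_lexicon):
        _, _, _, spans = self.link("bursts ( n = 12 ) at 5 mV", unit_lexicon)
        ev = [s.surface for s in spans if s.entity_type == "ExperimentalValue"]
        assert ev == ["5 mV"]

    def test_no_value_silently_dropped(self, unit_lexicon, synthetic_corpus):
        for doc in synthetic_corpus.documents[:10]:
            text = doc.text
            values = [v for v in R.detect_values(text)
                      if not R.is_sample_size(text, v)]
            toks = tokenize(text)
            _, _, chunks = analyse(toks)
            nps = noun_phrases(toks, chunks)
            units = R.find_units(text, unit_lexicon)
            spans = R.link_value_unit(values, units, nps, text)
            n_ev = sum(s.entity_type == "ExperimentalValue" for s in spans)
            assert n_ev >= len(values)


# ---------------------------------------------------------------------------
# Abbreviations and propagation
# ---------------------------------------------------------------------------

class TestAbbreviations:
    def test_single_definition(self):
        pairs = R.find_abbreviations(
            "recordings from the suprachiasmatic nucleus (SCN) of adult rats")
        assert [(a.long, a.short) for a in pairs] == \
            [("suprachiasmatic nucleus", "SCN")]

    def test_no_parentheses(self):
        assert R.find_abbreviations("no definitions here") == []

    def test_two_definitions_in_one_sentence(self):
        pairs = R.find_abbreviations(
            "from the ventrobasal complex (VB) and posterior nucleus (POm).")
        assert [(a.long, a.short) for a in pairs] == \
            [("ventrobasal complex", "VB"), ("posterior nucleus", "POm")]

    def test_numeric_parentheticals_ignored(self):
        assert R.find_abbreviations("bicuculline (12) was applied") == []


class TestPropagation:
    def test_short_form_inherits_long_form_type(self):
        text = ("The suprachiasmatic nucleus (SCN) drives rhythm. "
                "SCN output peaks at dusk.")
        anns = [SpanAnnotation("BrainRegion", 4, 27, "suprachiasmatic nucleus",
                               "dictionary")]
        out = R.propagate_acronyms(text, anns, R.find_abbreviations(text))
        acro = [s for s in out if s.source == "acronym"]
        assert {(s.entity_type, s.surface) for s in acro} == \
            {("BrainRegion", "SCN")}
        # both occurrences, no duplicates
        assert len(acro) == 2

    def test_unannotated_long_forms_change_nothing(self):
        text = "The posterior complex (PC) was unlabelled. PC again."
        out = R.propagate_acronyms(text, [], R.find_abbreviations(text))
        assert out == []

    def test_each_acronym_gets_only_its_own_type(self):
        text = ("Input from the ventrobasal complex (VB) onto stellate "
                "interneurons (SI) was mapped. VB and SI were active.")
        anns = [
            SpanAnnotation("BrainRegion", 15, 34, "ventrobasal complex",
                           "dictionary"),
            SpanAnnotation("NeuronType", 45, 66, "stellate interneurons",
                           "regex"),
        ]
        out = R.propagate_acronyms(text, anns, R.find_abbreviations(text))
        acro = {(s.entity_type, s.surface) for s in out if s.source == "acronym"}
        assert acro == {("BrainRegion", "VB"), ("NeuronType", "SI")}


def test_annotate_full_document_end_to_end():
    """Dictionary, regex, value and acronym stages compose on one document."""
    text = ("Recordings were made in the suprachiasmatic nucleus (SCN) of "
            "adult rats. The effect of bicuculline (12.5 microM) on SCN "
            "neurons was heterogeneous.")
    spans = R.annotate(text)
    by_type = {(s.entity_type, s.surface) for s in spans}
    assert ("BrainRegion", "suprachiasmatic nucleus") in by_type
    assert ("ModelOrganism", "rats") in by_type
    assert ("Unit", "microM") in by_type
    assert ("ExperimentalValue", "12.5 microM") in by_type
    assert ("NeuronType", "SCN neurons") in by_type
    # every surface matches the text at its offsets
    for s in spans:
        assert text[s.begin:s.end] == s.surface
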