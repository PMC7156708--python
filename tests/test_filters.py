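"""Stage contracts: regex stages, age rule, POS gate, lexicon stages."""

import pytest

from phifilter.document import EXCLUDE, INCLUDE, UNMARKED, NoteDocument, tokenize
from phifilter.filters import (
    AgeRuleConfig,
    RegexEntry,
    RegexLibrary,
    RuleBasedTagger,
    apply_age_rule,
    apply_initials,
    apply_name_blacklist,
    apply_name_context,
    apply_phi_regex,
    apply_safe_regex,
    apply_whitelist,
    pos_tag,
    sentence_initial_flags,
)
from phifilter.lexicons import Lexicon
from phifilter.pipeline import DATA_DIR
from phifilter import filters

import re


def prepared(text):
    doc = NoteDocument("t", text)
    return doc, tokenize(doc)


def lib(pattern, polarity, category=None):
    return RegexLibrary(
        entries=[RegexEntry(pattern=re.compile(pattern), polarity=polarity, category=category)]
    )


DOSAGE = r"(?i)\b\d+\s?mg\b"


class TestRegexStages:
    def test_safe_match_marks_include(self):
        doc, tokens = prepared("Given 50 mg of aspirin")
        apply_safe_regex(doc, tokens, lib(DOSAGE, "SAFE"))
        by = {t.surface: t.label for t in tokens}
        assert by["50"] == INCLUDE and by["mg"] == INCLUDE
        assert by["aspirin"] == UNMARKED

    def test_first_writer_wins_over_safe(self):
        doc, tokens = prepared("50 mg")
        tokens[0].label = EXCLUDE
        tokens[0].stage = "earlier"
        apply_safe_regex(doc, tokens, lib(DOSAGE, "SAFE"))
        assert tokens[0].label == EXCLUDE and tokens[0].stage == "earlier"
        assert tokens[1].label == INCLUDE

    def test_empty_library_is_identity(self):
        doc, tokens = prepared("anything at all")
        apply_safe_regex(doc, tokens, RegexLibrary())
        assert all(t.label == UNMARKED for t in tokens)

    def test_phi_match_sets_category(self):
        doc, tokens = prepared("email jsmith@example.org please")
        shipped = filters.load_regex_library(DATA_DIR / "regex" / "phi_regex.tsv")
        apply_phi_regex(doc, tokens, shipped)
        hit = [t for t in tokens if t.category == "Email"]
        assert {t.surface for t in hit} == {"jsmith", "example", "org"}

    def test_ssn_pattern(self):
        doc, tokens = prepared("SSN 123-45-6789 recorded")
        shipped = filters.load_regex_library(DATA_DIR / "regex" / "phi_regex.tsv")
        apply_phi_regex(doc, tokens, shipped)
        by = {t.surface: t for t in tokens}
        assert by["123"].label == EXCLUDE
        assert by["123"].category == "Patient_Social_Security_Number"

    def test_polarity_enforced(self):
        doc, tokens = prepared("x")
        with pytest.raises(ValueError):
            apply_safe_regex(doc, tokens, lib(r"x", "PHI", "Name"))
        with pytest.raises(ValueError):
            apply_phi_regex(doc, tokens, lib(r"x", "SAFE"))


class TestAgeRule:
    @pytest.mark.parametrize(
        "text, token, label, category",
        [
            ("age 92 noted", "92", EXCLUDE, "Age >= 90"),
            ("age 89 noted", "89", INCLUDE, None),
            ("aged 101 today", "101", EXCLUDE, "Age >= 90"),
            ("92 years old", "92", EXCLUDE, "Age >= 90"),
            ("walked 92 steps", "92", UNMARKED, None),
        ],
    )
    def test_age_decisions(self, text, token, label, category):
        doc, tokens = prepared(text)
        apply_age_rule(doc, tokens, AgeRuleConfig())
        tok = next(t for t in tokens if t.surface == token)
        assert tok.label == label and tok.category == category

    def test_dosage_number_untouched(self):
        """A number already claimed as a dosage is not reinterpreted as age."""
        doc, tokens = prepared("age 95 mg dose")
        apply_safe_regex(doc, tokens, lib(DOSAGE, "SAFE"))
        apply_age_rule(doc, tokens, AgeRuleConfig())
        tok = next(t for t in tokens if t.surface == "95")
        assert tok.label == INCLUDE  # claimed by the safe stage, not the age rule


@pytest.fixture(scope="module")
def tagger():
    return RuleBasedTagger.from_tsv(DATA_DIR / "tagger" / "tagger_lexicon.tsv")


class TestRuleBasedTagger:
    def tags_for(self, tagger, text):
        doc, tokens = prepared(text)
        pos_tag(doc, tokens, tagger)
        return {t.surface: t.pos_tag for t in tokens}

    def test_capitalized_mid_sentence_is_proper_noun(self, tagger):
        tags = self.tags_for(tagger, "Patient John White presents with pain")
        assert tags["White"] == "NNP" and tags["John"] == "NNP"
        assert tags["Patient"] != "NNP"  # known sentence opener

    def test_sentence_initial_known_adjective(self, tagger):
        tags = self.tags_for(tagger, "White fluid found at the site")
        assert tags["White"] == "JJ"

    def test_digits_are_cd(self, tagger):
        assert self.tags_for(tagger, "value 92 noted")["92"] == "CD"

    def test_sentence_boundaries_reset_after_period(self, tagger):
        doc, tokens = prepared("Stable today. White fluid seen.")
        flags = sentence_initial_flags(doc, tokens)
        assert flags == [True, False, True, False, False]
        pos_tag(doc, tokens, tagger)
        assert tokens[2].pos_tag == "JJ"

    def test_wrong_length_tagger_rejected(self):
        class Broken:
            def tag(self, surfaces, flags):
                return ["NN"]

        doc, tokens = prepared("two tokens")
        with pytest.raises(RuntimeError):
            pos_tag(doc, tokens, Broken())


class TestNameStages:
    def setup_tokens(self, text, tagger=None):
        doc, tokens = prepared(text)
        pos_tag(doc, tokens, tagger or RuleBasedTagger({"white": "JJ", "patient": "NN"}))
        return doc, tokens

    def test_blacklist_requires_nnp(self):
        surnames = Lexicon(tokens={"white"})
        _, tokens = self.setup_tokens("Patient John White presents")
        apply_name_blacklist(tokens, surnames, stage="bl")
        by = {t.surface: t.label for t in tokens}
        assert by["White"] == EXCLUDE
        _, tokens = self.setup_tokens("White fluid found")
        apply_name_blacklist(tokens, surnames, stage="bl")
        assert all(t.label == UNMARKED for t in tokens)

    def test_blacklist_needs_tags(self):
        doc, tokens = prepared("Some Words")
        with pytest.raises(RuntimeError):
            apply_name_blacklist(tokens, Lexicon(tokens={"words"}))

    def test_name_context_requires_adjacent_blacklist_hit(self):
        pattern = lib(r"\b[A-Z][a-z]+\s+[A-Z][a-z]+\b", "PHI", "Name")
        doc, tokens = self.setup_tokens("met Jane Doe today")
        # no prior blacklist hit: untouched
        apply_name_context(doc, [t.copy() for t in tokens], pattern, {"bl"})
        assert all(t.label == UNMARKED for t in tokens)
        # with "Jane" excluded by a blacklist, "Doe" follows
        jane = next(t for t in tokens if t.surface == "Jane")
        jane.label, jane.stage, jane.category = EXCLUDE, "bl", "Name"
        apply_name_context(doc, tokens, pattern, {"bl"})
        doe = next(t for t in tokens if t.surface == "Doe")
        assert doe.label == EXCLUDE and doe.category == "Name"

    def test_whitelist_passes_known_skips_numeric(self):
        wl = Lexicon(tokens={"aspirin", "92"})
        doc, tokens = self.setup_tokens("aspirin 92 Xq9z given")
        apply_whitelist(tokens, wl)
        by = {t.surface: t.label for t in tokens}
        assert by["aspirin"] == INCLUDE
        assert by["92"] == UNMARKED  # numeric POS never whitelisted
        assert by["Xq9z"] == UNMARKED  # safety net: will be obfuscated

    def test_initials_condition(self):
        pattern = lib(r"\b[A-Z][a-z]+,\s*(?:[A-Z]\.?\s*){1,3}", "PHI", "Initials")
        doc, tokens = self.setup_tokens("seen Doe, J. here")
        apply_initials(doc, [t.copy() for t in tokens], pattern, {"bl"})
        assert all(t.label == UNMARKED for t in tokens)
        doe = next(t for t in tokens if t.surface == "Doe")
        doe.label, doe.stage, doe.category = EXCLUDE, "bl", "Name"
        apply_initials(doc, tokens, pattern, {"bl"})
        j = next(t for t in tokens if t.surface == "J")
        assert j.label == EXCLUDE and j.category == "Initials"


def test_monotone_labeling_through_shipped_cascade(default_cfg):
    """The count of UNMARKED tokens never increases across stages and no
    label flips once set (the pipeline asserts this internally too)."""
    from phifilter.pipeline import run_note

    doc = NoteDocument(
        "t", "Patient John White presents. MRN: 4721938. Call 415-555-0134 at age 92."
    )
    result = run_note(doc, default_cfg)
    # every excluded token carries a category and a stage
    for t in result.token_labels:
        if t.label == EXCLUDE:
            assert t.category is not None and t.stage is not None
        if t.label == INCLUDE:
            assert t.category is None


def test_stage_order_decides_contested_tokens():
    """Swapping a SAFE stage before/after a PHI stage flips only the tokens
    both match."""
    text = "shared 42 token"
    safe = lib(r"\b42\b", "SAFE")
    phi = lib(r"\b42\b", "PHI", "Date")
    doc, tokens = prepared(text)
    apply_safe_regex(doc, tokens, safe)
    apply_phi_regex(doc, tokens, phi)
    assert next(t for t in tokens if t.surface == "42").label == INCLUDE

    doc, tokens = prepared(text)
    apply_phi_regex(doc, tokens, phi)
    apply_safe_regex(doc, tokens, safe)
    assert next(t for t in tokens if t.surface == "42").label == EXCLUDE
    # tokens matched by neither are identical under both orders
    assert [t.label for t in tokens if t.surface != "42"] == [UNMARKED, UNMARKED]
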