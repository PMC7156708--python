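"""Detection stages of the de-identification cascade.

Every stage shares one contract: it may move a token's label from UNMARKED
to EXCLUDE (PHI) or from UNMARKED to INCLUDE (safe), and it never overwrites
a label set by an earlier stage.  Priority between stages is therefore
purely their order in the pipeline configuration (first-writer-wins).

Regex stages run their patterns over the *raw note text*, not over the
token stream, and project each match onto tokens via interval intersection;
a partial character overlap claims the whole token, the privacy-conservative
choice.  A pattern may confine its effective span to a named group ``m`` so
that lookaround-free context (e.g. a salutation before a name) can be
matched without claiming the context tokens.

The statistical gate is part-of-speech tagging: name blacklists only fire
on tokens tagged NNP (proper noun), which is what lets "White" survive in
"White fluid found at..." while being redacted in "Patient John White
presents with...".  A deterministic rule-based tagger is shipped so the
cascade needs no third-party model; any tagger implementing the same
contract is pluggable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .document import (
    EXCLUDE,
    INCLUDE,
    UNMARKED,
    NoteDocument,
    TokenSpan,
    adjacent_tokens,
    span_to_tokens,
)
from .lexicons import Lexicon

__all__ = [
    "RegexEntry",
    "RegexLibrary",
    "AgeRuleConfig",
    "Tagger",
    "RuleBasedTagger",
    "load_regex_library",
    "apply_safe_regex",
    "apply_phi_regex",
    "apply_age_rule",
    "pos_tag",
    "apply_name_blacklist",
    "apply_name_context",
    "apply_whitelist",
    "apply_initials",
]

log = logging.getLogger(__name__)

SAFE = "SAFE"
PHI = "PHI"


@dataclass(frozen=True)
class RegexEntry:
    pattern: re.Pattern
    polarity: str
    category: str | None
    description: str = ""

    def match_spans(self, text: str) -> list[tuple[int, int]]:
        """Spans claimed by this entry; group ``m`` confines the span if present."""
        spans = []
        for m in self.pattern.finditer(text):
            if "m" in self.pattern.groupindex and m.group("m") is not None:
                spans.append(m.span("m"))
            else:
                spans.append(m.span())
        return [(s, e) for s, e in spans if s < e]


@dataclass
class RegexLibrary:
    entries: list[RegexEntry] = field(default_factory=list)
    name: str = ""

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def load_regex_library(path: str | Path) -> RegexLibrary:
    """Load a TSV regex library: polarity <TAB> category <TAB> description <TAB> pattern.

    Lines starting with ``#`` are comments; the category column is ``-`` for
    safe entries.  Every pattern must compile; a PHI entry must carry a
    category.
    """
    p = Path(path)
    entries: list[RegexEntry] = []
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t", 3)
        if len(parts) != 4:
            raise ValueError(f"{p}:{lineno}: expected 4 tab-separated fields")
        polarity, category, description, pattern = parts
        polarity = polarity.strip().upper()
        if polarity not in (SAFE, PHI):
            raise ValueError(f"{p}:{lineno}: polarity must be SAFE or PHI")
        cat = None if category.strip() in ("-", "") else category.strip()
        if polarity == PHI and cat is None:
            raise ValueError(f"{p}:{lineno}: PHI entry requires a category")
        entries.append(
            RegexEntry(
                pattern=re.compile(pattern),
                polarity=polarity,
                category=cat,
                description=description.strip(),
            )
        )
    return RegexLibrary(entries=entries, name=p.stem)


def _mark(token: TokenSpan, label: str, stage: str, category: str | None = None) -> bool:
    """First-writer-wins label assignment; returns True if the label was set."""
    if token.label != UNMARKED:
        return False
    token.label = label
    token.stage = stage
    if label == EXCLUDE:
        token.category = category
    return True


def apply_safe_regex(
    doc: NoteDocument,
    tokens: list[TokenSpan],
    library: RegexLibrary,
    stage: str = "safe_regex",
) -> list[TokenSpan]:
    """Mark tokens intersecting any SAFE pattern match as INCLUDE."""
    for entry in library:
        if entry.polarity != SAFE:
            raise ValueError(f"non-SAFE entry in safe library: {entry.description!r}")
        for s, e in entry.match_spans(doc.text):
            for tok in span_to_tokens(tokens, s, e):
                _mark(tok, INCLUDE, stage)
    return tokens


def apply_phi_regex(
    doc: NoteDocument,
    tokens: list[TokenSpan],
    library: RegexLibrary,
    stage: str = "phi_regex",
) -> list[TokenSpan]:
    """Mark tokens intersecting any PHI pattern match as EXCLUDE."""
    for entry in library:
        if entry.polarity != PHI:
            raise ValueError(f"non-PHI entry in PHI library: {entry.description!r}")
        for s, e in entry.match_spans(doc.text):
            for tok in span_to_tokens(tokens, s, e):
                _mark(tok, EXCLUDE, stage, entry.category)
    return tokens


@dataclass
class AgeRuleConfig:
    trigger_words: tuple[str, ...] = ("age", "aged", "years", "old", "yo", "y.o.")
    threshold: int = 90
    context_radius: int = 2

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("age threshold must be >= 0")


def apply_age_rule(
    doc: NoteDocument,
    tokens: list[TokenSpan],
    cfg: AgeRuleConfig | None = None,
    stage: str = "age_rule",
) -> list[TokenSpan]:
    """HIPAA age rule: a number near an age trigger word is an age.

    Ages at or above the threshold (default 90) are PHI; younger ages are
    explicitly safe.  Numbers already labeled by an earlier stage (e.g. a
    dosage caught by a safe regex) are untouched.
    """
    cfg = cfg or AgeRuleConfig()
    triggers = {w.lower().strip(".") for w in cfg.trigger_words}
    for i, tok in enumerate(tokens):
        if tok.label != UNMARKED or not tok.surface.isdigit():
            continue
        neighbors = adjacent_tokens(tokens, i, cfg.context_radius)
        if not any(n.surface.lower().strip(".") in triggers for n in neighbors):
            continue
        try:
            value = int(tok.surface)
        except ValueError:  # pragma: no cover - isdigit guards this
            log.warning("unparseable numeric token %r skipped by age rule", tok.surface)
            continue
        if value > 200:
            # absurd as an age; leave for other stages
            continue
        if value >= cfg.threshold:
            _mark(tok, EXCLUDE, stage, "Age >= 90")
        else:
            _mark(tok, INCLUDE, stage)
    return tokens


# ---------------------------------------------------------------------------
# Part-of-speech tagging


class Tagger(Protocol):
    """Contract: equal-length Penn-Treebank-style tags for a token sequence.

    ``sentence_initial[i]`` is True when token i opens a sentence; taggers
    that model context themselves may ignore it.
    """

    def tag(self, surfaces: Sequence[str], sentence_initial: Sequence[bool]) -> list[str]: ...


_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "no": "DT", "any": "DT", "some": "DT",
    "each": "DT", "every": "DT", "all": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "to": "TO", "for": "IN",
    "with": "IN", "without": "IN", "by": "IN", "from": "IN", "as": "IN",
    "into": "IN", "over": "IN", "under": "IN", "after": "IN", "before": "IN",
    "during": "IN", "per": "IN", "via": "IN", "since": "IN", "within": "IN",
    "if": "IN", "while": "IN", "than": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "is": "VBZ", "was": "VBD", "are": "VBP", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD", "do": "VBP", "does": "VBZ",
    "did": "VBD", "will": "MD", "would": "MD", "can": "MD", "could": "MD",
    "should": "MD", "may": "MD", "might": "MD", "must": "MD",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "we": "PRP",
    "you": "PRP", "i": "PRP", "who": "WP", "which": "WDT", "what": "WP",
    "his": "PRP$", "her": "PRP$", "their": "PRP$", "its": "PRP$",
    "my": "PRP$", "our": "PRP$", "your": "PRP$",
    "not": "RB", "also": "RB", "very": "RB", "too": "RB", "then": "RB",
    "now": "RB", "here": "RB", "there": "EX", "when": "WRB", "where": "WRB",
    "how": "WRB", "why": "WRB",
}


class RuleBasedTagger:
    """Deterministic context-aware tagger for the blacklist NNP gate.

    Rules, in order: digit strings are CD; closed-class words get their
    fixed tags; a capitalized word *inside* a sentence is NNP; a capitalized
    word at a sentence start falls back to its lexical tag when the
    lowercase form is a known common word, otherwise NNP (an unknown
    capitalized sentence opener is most plausibly a name); lowercase words
    use the lexicon, then suffix heuristics, defaulting to NN.
    """

    def __init__(self, lexicon: dict[str, str] | None = None) -> None:
        self.lexicon = dict(lexicon or {})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RuleBasedTagger":
        lexicon: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            word, tag = line.split("\t")
            lexicon[word.strip().lower()] = tag.strip()
        return cls(lexicon)

    def _suffix_tag(self, lower: str) -> str:
        if lower.endswith("ly"):
            return "RB"
        if lower.endswith("ing") and len(lower) > 4:
            return "VBG"
        if lower.endswith("ed") and len(lower) > 3:
            return "VBN"
        if lower.endswith("s") and not lower.endswith("ss") and len(lower) > 3:
            return "NNS"
        return "NN"

    def tag(self, surfaces: Sequence[str], sentence_initial: Sequence[bool]) -> list[str]:
        if len(surfaces) != len(sentence_initial):
            raise ValueError("surfaces and sentence_initial must align")
        tags: list[str] = []
        for surface, initial in zip(surfaces, sentence_initial):
            lower = surface.lower()
            capitalized = surface[:1].isupper()
            if any(ch.isdigit() for ch in surface):
                tags.append("CD")
            elif capitalized and not initial:
                # a capitalized word inside a sentence is a proper noun;
                # "May" the month outranks "may" the modal here
                tags.append("NNP")
            elif lower in _CLOSED_CLASS:
                tags.append(_CLOSED_CLASS[lower])
            elif capitalized:
                lexical = self.lexicon.get(lower)
                tags.append(lexical if lexical else "NNP")
            else:
                lexical = self.lexicon.get(lower)
                tags.append(lexical if lexical else self._suffix_tag(lower))
        return tags


_SENTENCE_BREAK = re.compile(r"[.!?\n\r:;]")


def sentence_initial_flags(doc: NoteDocument, tokens: list[TokenSpan]) -> list[bool]:
    """A token opens a sentence when only sentence-ending punctuation or the
    document start precedes it."""
    flags: list[bool] = []
    prev_end = 0
    for i, tok in enumerate(tokens):
        gap = doc.text[prev_end : tok.start]
        flags.append(i == 0 or bool(_SENTENCE_BREAK.search(gap)))
        prev_end = tok.end
    return flags


def pos_tag(doc: NoteDocument, tokens: list[TokenSpan], tagger: Tagger) -> list[TokenSpan]:
    """Assign a POS tag to every token; labels are untouched."""
    surfaces = [t.surface for t in tokens]
    flags = sentence_initial_flags(doc, tokens)
    tags = tagger.tag(surfaces, flags)
    if len(tags) != len(tokens):
        raise RuntimeError(
            f"tagger returned {len(tags)} tags for {len(tokens)} tokens"
        )
    for tok, tag in zip(tokens, tags):
        tok.pos_tag = tag
    return tokens


# ---------------------------------------------------------------------------
# Name stages


def apply_name_blacklist(
    tokens: list[TokenSpan],
    *lexicons: Lexicon,
    stage: str = "name_blacklist",
    category: str = "Name",
) -> list[TokenSpan]:
    """Proper-noun gate: an UNMARKED NNP token found in any blacklist is PHI.

    The cascade cannot tell patients from providers, so the generic Name
    category is assigned; gold category mapping happens at evaluation time.
    """
    for tok in tokens:
        if tok.pos_tag == "UNSET":
            raise RuntimeError("POS tagging must run before the name blacklist stage")
        if tok.label != UNMARKED or tok.pos_tag != "NNP":
            continue
        if any(tok.surface.lower() in lex.tokens for lex in lexicons):
            _mark(tok, EXCLUDE, stage, category)
    return tokens


def _adjacent_blacklist_hit(
    tokens: list[TokenSpan], index: int, blacklist_stages: set[str], radius: int
) -> bool:
    for n in adjacent_tokens(tokens, index, radius):
        if n.label == EXCLUDE and n.stage in blacklist_stages:
            return True
    return False


def apply_name_context(
    doc: NoteDocument,
    tokens: list[TokenSpan],
    patterns: RegexLibrary,
    blacklist_stages: set[str],
    stage: str = "name_context",
    radius: int = 1,
) -> list[TokenSpan]:
    """Pattern-shaped names ("Jane Doe", "Doe, Jane") become PHI only when an
    adjacent token was already excluded by a blacklist stage."""
    index_of = {id(t): i for i, t in enumerate(tokens)}
    for entry in patterns:
        for s, e in entry.match_spans(doc.text):
            for tok in span_to_tokens(tokens, s, e):
                if tok.label != UNMARKED:
                    continue
                i = index_of[id(tok)]
                if _adjacent_blacklist_hit(tokens, i, blacklist_stages, radius):
                    _mark(tok, EXCLUDE, stage, "Name")
    return tokens


def apply_whitelist(
    tokens: list[TokenSpan],
    whitelist: Lexicon,
    stage: str = "whitelist",
) -> list[TokenSpan]:
    """Safety net: UNMARKED non-numeric tokens found in the whitelist are
    safe; everything else stays UNMARKED and is obfuscated at disposition.

    Numeric-tagged (CD) tokens never pass through the whitelist — an
    unexplained number is always redacted.  Single-letter proper-noun
    tokens are also skipped: a lone capital letter is a candidate initial,
    and the initials stage (which runs later and cannot overwrite an
    INCLUDE) or the safety-net default must decide its fate.
    """
    for tok in tokens:
        if tok.pos_tag == "UNSET":
            raise RuntimeError("POS tagging must run before the whitelist stage")
        if tok.label != UNMARKED or tok.pos_tag == "CD":
            continue
        if len(tok.surface) == 1 and tok.surface.isupper() and tok.pos_tag == "NNP":
            continue
        if tok.surface.lower() in whitelist.tokens:
            _mark(tok, INCLUDE, stage)
    return tokens


def apply_initials(
    doc: NoteDocument,
    tokens: list[TokenSpan],
    patterns: RegexLibrary,
    blacklist_stages: set[str],
    stage: str = "initials",
    radius: int = 1,
) -> list[TokenSpan]:
    """Initials patterns ("Doe, J.", "Jane S. Doe"): single-letter tokens in
    a match are PHI iff adjacent to a blacklist exclusion."""
    index_of = {id(t): i for i, t in enumerate(tokens)}
    for entry in patterns:
        for s, e in entry.match_spans(doc.text):
            for tok in span_to_tokens(tokens, s, e):
                if tok.label != UNMARKED or len(tok.surface) != 1 or not tok.surface.isalpha():
                    continue
                i = index_of[id(tok)]
                if _adjacent_blacklist_hit(tokens, i, blacklist_stages, radius):
                    _mark(tok, EXCLUDE, stage, "Initials")
    return tokens
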