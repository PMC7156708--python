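"""Note representation and character-exact tokenization.

A clinical note is held as an immutable string; every downstream decision is
expressed in 0-based half-open character offsets into that string, so that
redaction can reproduce the note structure byte for byte. The tokenizer
splits on whitespace and a configurable set of separator symbols; any
character that is neither alphanumeric nor an explicit separator is also
treated as a separator, which keeps stray control characters in clinical
exports from gluing tokens together.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "EXCLUDE",
    "INCLUDE",
    "UNMARKED",
    "DEFAULT_SEPARATORS",
    "NoteDocument",
    "TokenSpan",
    "PhiCategoryRegistry",
    "DEFAULT_CATEGORIES",
    "tokenize",
    "adjacent_tokens",
    "span_to_tokens",
    "read_note",
    "read_corpus",
]

# Token label states.
EXCLUDE = "EXCLUDE"
INCLUDE = "INCLUDE"
UNMARKED = "UNMARKED"

# Separator symbols split tokens in addition to whitespace.  The set expands
# the canonical "-, /, #, &, periods" list to a documented full set; it is
# overridable through the pipeline configuration.
DEFAULT_SEPARATORS = frozenset("-/#&.,:;()[]{}<>\"'`!?*@%+=|\\^~_$–—‘’“”")


@dataclass(frozen=True)
class NoteDocument:
    """One clinical note: an opaque id plus immutable raw text."""

    note_id: str
    text: str

    def __post_init__(self) -> None:
        # NFC normalization on load keeps offsets stable across platforms.
        object.__setattr__(self, "text", unicodedata.normalize("NFC", self.text))

    @property
    def length(self) -> int:
        return len(self.text)


@dataclass
class TokenSpan:
    """A single token with provenance of the labeling decision.

    ``start``/``end`` are 0-based half-open character offsets into the
    owning document; ``surface`` is exactly ``text[start:end]``.  ``label``
    is one of EXCLUDE / INCLUDE / UNMARKED and, once set by a stage, is
    never overwritten (first-writer-wins across the cascade).
    """

    start: int
    end: int
    surface: str
    pos_tag: str = "UNSET"
    label: str = UNMARKED
    category: str | None = None
    stage: str | None = None

    def intersects(self, start: int, end: int) -> bool:
        """True when the half-open interval [start, end) overlaps this token."""
        return self.start < end and start < self.end

    def copy(self) -> "TokenSpan":
        return replace(self)


class PhiCategoryRegistry:
    """Closed registry of PHI category names, extensible at run time.

    Detection stages assign the generic ``Name`` / ``Initials`` categories
    because the cascade cannot distinguish patients from providers; the
    patient/provider split exists only in gold annotations.
    """

    def __init__(self, names: Iterable[str] = ()) -> None:
        self._names: set[str] = set(names)

    def register(self, name: str) -> str:
        self._names.add(name)
        return name

    def __contains__(self, name: str) -> bool:
        return name in self._names

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._names))


#: Category taxonomy used by the gold annotation dialects and leakage reports.
DEFAULT_CATEGORIES = PhiCategoryRegistry(
    [
        "Age >= 90",
        "Patient_Vehicle_or_Device_Id",
        "Patient_Account_Number",
        "Patient_Medical_Record_Id",
        "Patient_Social_Security_Number",
        "Patient_Phone_Fax",
        "Patient_Initials",
        "Patient_Name_or_Family_Member_Name",
        "Patient_Address",
        "Patient_Unique_ID",
        "Email",
        "URL_IP",
        "Date",
        "Provider_Certificate_or_License",
        "Provider_Name",
        "Provider_Initials",
        "Provider_Address_or_Location",
        "Provider_Phone_Fax",
        # generic categories assigned by detection stages
        "Name",
        "Initials",
    ]
)


def _is_token_char(ch: str, separators: frozenset[str]) -> bool:
    if ch in separators:
        return False
    if ch.isspace():
        return False
    # anything non-alphanumeric that is not an explicit separator still splits
    return ch.isalnum()


def tokenize(doc: NoteDocument, separators: frozenset[str] = DEFAULT_SEPARATORS) -> list[TokenSpan]:
    """Split a note into tokens on whitespace and separator symbols.

    Every maximal run of non-separator characters becomes exactly one token;
    offsets index the original text, so writing each surface back at its
    offsets reconstructs the note exactly.
    """
    tokens: list[TokenSpan] = []
    text = doc.text
    i, n = 0, len(text)
    while i < n:
        if _is_token_char(text[i], separators):
            j = i + 1
            while j < n and _is_token_char(text[j], separators):
                j += 1
            tokens.append(TokenSpan(start=i, end=j, surface=text[i:j]))
            i = j
        else:
            i += 1
    return tokens


def adjacent_tokens(tokens: list[TokenSpan], index: int, radius: int) -> list[TokenSpan]:
    """Tokens within ``radius`` stream positions of ``index``, excluding it."""
    if not 0 <= index < len(tokens):
        raise IndexError(f"token index {index} out of range for {len(tokens)} tokens")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    lo = max(0, index - radius)
    hi = min(len(tokens), index + radius + 1)
    return [tokens[k] for k in range(lo, hi) if k != index]


def span_to_tokens(tokens: list[TokenSpan], start: int, end: int) -> list[TokenSpan]:
    """All tokens whose interval intersects [start, end).

    A partial character overlap includes the whole token — the privacy-
    conservative projection of a raw-text regex match onto the token stream.
    """
    if start > end:
        raise ValueError(f"invalid span: start {start} > end {end}")
    return [t for t in tokens if t.intersects(start, end)]


def read_note(path: str | Path) -> NoteDocument:
    """Load one UTF-8 plain-text note; the file stem is the note id."""
    p = Path(path)
    return NoteDocument(note_id=p.stem, text=p.read_text(encoding="utf-8"))


def read_corpus(directory: str | Path) -> list[NoteDocument]:
    """Load every ``.txt`` note in a directory, sorted by note id."""
    return [read_note(p) for p in sorted(Path(directory).glob("*.txt"))]
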