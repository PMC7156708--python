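"""Name blacklists and the safe whitelist.

The cascade's statistical gate works on two lexicon families:

* **blacklists** — surnames from a census-style frequency table (kept when a
  surname occurs at least ``surname_min_count`` times, default 100) and
  first names from an SSA-style name-by-birth-year table (kept when a name
  occurs at least ``firstname_min_count`` times, default 5, in any birth
  year inside the configured range, default 1879-2017).  A curated exclusion
  list removes names that are overwhelmingly common words ("new", "walks",
  "knee", ...), which would otherwise destroy precision.
* **whitelist** — the union of medical vocabularies and common-English word
  lists, minus every token present in any blacklist, plus a small add-back
  list of ambiguous words whose removal costs too much precision ("white",
  "young", ...).  Unlabeled tokens not found here are obfuscated: the
  whitelist is the safety net, so absence means redaction.

All lexicon members are lowercased and tokenized with the note tokenizer, so
multi-word names contribute each part separately and membership tests are
exact-string after lowercasing.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .document import DEFAULT_SEPARATORS, NoteDocument, tokenize

__all__ = [
    "Lexicon",
    "BlacklistBuildConfig",
    "build_last_name_blacklist",
    "build_first_name_blacklist",
    "build_whitelist",
    "save_lexicon",
    "load_lexicon",
    "read_frequency_table",
    "name_vocab_overlap",
]

log = logging.getLogger(__name__)


@dataclass
class Lexicon:
    """A normalized token set with build metadata."""

    tokens: set[str] = field(default_factory=set)
    meta: dict[str, str] = field(default_factory=dict)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass
class BlacklistBuildConfig:
    surname_min_count: int = 100
    firstname_min_count: int = 5
    birth_year_range: tuple[int, int] = (1879, 2017)
    exclusion_words: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.surname_min_count < 1 or self.firstname_min_count < 1:
            raise ValueError("minimum counts must be >= 1")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError("birth year range is empty")
        self.exclusion_words = frozenset(w.lower() for w in self.exclusion_words)


def _name_parts(name: str) -> list[str]:
    """Tokenize a name the same way notes are tokenized; lowercase parts."""
    return [t.surface.lower() for t in tokenize(NoteDocument("lex", name))]


def build_last_name_blacklist(
    census_rows: Iterable[tuple[str, int]], cfg: BlacklistBuildConfig
) -> Lexicon:
    """Surnames at or above the frequency threshold, minus exclusions."""
    tokens: set[str] = set()
    for row in census_rows:
        try:
            surname, count = row[0], int(row[1])
        except (TypeError, ValueError, IndexError):
            log.warning("skipping malformed census row: %r", row)
            continue
        if count < 0:
            log.warning("skipping negative-count census row: %r", row)
            continue
        if count >= cfg.surname_min_count:
            tokens.update(_name_parts(surname))
    tokens -= cfg.exclusion_words
    return Lexicon(
        tokens=tokens,
        meta={
            "kind": "last_name_blacklist",
            "surname_min_count": str(cfg.surname_min_count),
            "built": datetime.date.today().isoformat(),
        },
    )


def build_first_name_blacklist(
    ssa_rows: Iterable[tuple[str, int, int]], cfg: BlacklistBuildConfig
) -> Lexicon:
    """First names meeting the per-birth-year threshold inside the year range."""
    lo, hi = cfg.birth_year_range
    tokens: set[str] = set()
    for row in ssa_rows:
        try:
            name, year, count = row[0], int(row[1]), int(row[2])
        except (TypeError, ValueError, IndexError):
            log.warning("skipping malformed SSA row: %r", row)
            continue
        if not lo <= year <= hi:
            continue
        if count >= cfg.firstname_min_count:
            tokens.update(_name_parts(name))
    tokens -= cfg.exclusion_words
    return Lexicon(
        tokens=tokens,
        meta={
            "kind": "first_name_blacklist",
            "firstname_min_count": str(cfg.firstname_min_count),
            "birth_year_range": f"{lo}-{hi}",
            "built": datetime.date.today().isoformat(),
        },
    )


def build_whitelist(
    vocab_sources: Sequence[Iterable[str]],
    name_blacklists: Sequence[Lexicon],
    add_back: Iterable[str] = (),
) -> Lexicon:
    """Union of vocabularies, minus blacklisted names, plus the add-back set."""
    tokens: set[str] = set()
    for source in vocab_sources:
        for word in source:
            tokens.update(_name_parts(word))
    blacklisted: set[str] = set()
    for bl in name_blacklists:
        blacklisted |= bl.tokens
    add_back_tokens = {p for w in add_back for p in _name_parts(w)}
    tokens = (tokens - blacklisted) | add_back_tokens
    lex = Lexicon(
        tokens=tokens,
        meta={
            "kind": "whitelist",
            "size": str(len(tokens)),
            "add_back_size": str(len(add_back_tokens)),
            "built": datetime.date.today().isoformat(),
        },
    )
    # by construction, any residual overlap with the blacklists is the add-back set
    assert lex.tokens & blacklisted <= add_back_tokens
    return lex


def name_vocab_overlap(vocab_sources: Sequence[Iterable[str]], name_blacklists: Sequence[Lexicon]) -> int:
    """Count vocabulary tokens that are also names — the ambiguity statistic
    motivating both the exclusion list and the add-back list."""
    vocab: set[str] = set()
    for source in vocab_sources:
        for word in source:
            vocab.update(_name_parts(word))
    names: set[str] = set()
    for bl in name_blacklists:
        names |= bl.tokens
    return len(vocab & names)


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    """One token per line, with a ``#``-prefixed metadata header block."""
    p = Path(path)
    lines = [f"# {k}: {v}" for k, v in sorted(lex.meta.items())]
    lines.extend(sorted(lex.tokens))
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_lexicon(path: str | Path) -> Lexicon:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"lexicon file not found: {p}")
    tokens: set[str] = set()
    meta: dict[str, str] = {}
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        tokens.add(line.lower())
    return Lexicon(tokens=tokens, meta=meta)


def read_frequency_table(path: str | Path) -> list[tuple]:
    """Read a TSV frequency table: (name, count) or (name, year, count)."""
    rows: list[tuple] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            rows.append((parts[0], int(parts[1])))
        elif len(parts) == 3:
            rows.append((parts[0], int(parts[1]), int(parts[2])))
        else:
            log.warning("skipping malformed frequency row: %r", line)
    return rows
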