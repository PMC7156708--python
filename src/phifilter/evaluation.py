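"""Gold-standard parsing and token-level performance metrics.

Evaluation compares the de-identified note with the original at the
character level, then aggregates to tokens, the unit at which privacy risk
accrues: a token is *predicted PHI* when any of its characters was
obfuscated, and *gold PHI* when it intersects any annotated span.  From the
resulting TP/FP/TN/FN contingency:

    recall    = TP / (TP + FN)        (fraction of PHI removed — privacy)
    precision = TP / (TP + FP)        (fraction of removals justified)
    F2        = 5·P·R / (4·P + R)     (recall weighted twice as heavily)

all reported on the percentage scale.  Corpus numbers are micro-averaged
(counts summed over notes before the ratios are taken).  Per-category
false-negative counts — PHI token instances that leaked through — drive the
leakage report.

Two gold XML dialects are read: MAE-style (tag name is the category, a
``spans="start~end"`` attribute) and i2b2-2014-style (``<TAGS>`` children
with ``start``/``end``/``TYPE`` attributes).  i2b2 annotations are stricter
than Safe Harbor, so a normalization pass can relabel years in isolation,
seasons, weekdays, isolated single letters, country names and ages under
90 as safe, and drop unrealistically short surrogate patient IDs.
"""

from __future__ import annotations

import difflib
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .document import DEFAULT_CATEGORIES, NoteDocument, TokenSpan, tokenize

__all__ = [
    "GoldSpan",
    "GoldAnnotation",
    "MetricsResult",
    "read_gold",
    "normalize_i2b2_gold",
    "evaluate_note",
    "f2_score",
    "corpus_report",
    "align_external_output",
]

log = logging.getLogger(__name__)

#: XML element names cannot contain spaces or ">=", so the age category is
#: aliased in MAE-style files and mapped back on read.
XML_TAG_ALIASES = {"Age >= 90": "Age_GE_90"}
XML_TAG_REVERSE = {v: k for k, v in XML_TAG_ALIASES.items()}


@dataclass(frozen=True)
class GoldSpan:
    start: int
    end: int
    category: str
    surface: str = ""


@dataclass
class GoldAnnotation:
    note_id: str
    spans: list[GoldSpan] = field(default_factory=list)
    source_dialect: str = "MAE"


def _merge_overlapping(spans: list[GoldSpan]) -> list[GoldSpan]:
    """Merge overlapping gold spans; the earlier span's category wins."""
    merged: list[GoldSpan] = []
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        if merged and span.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = GoldSpan(
                start=prev.start,
                end=max(prev.end, span.end),
                category=prev.category,
                surface=prev.surface,
            )
        else:
            merged.append(span)
    return merged


def read_gold(path: str | Path, dialect: str = "MAE") -> GoldAnnotation:
    """Parse a gold annotation file in the MAE or I2B2 XML dialect.

    Offsets are converted to the internal 0-based half-open convention
    (both dialects already use character offsets with an exclusive end).
    Unknown categories are registered dynamically with a warning.
    """
    path = Path(path)
    dialect = dialect.upper()
    try:
        root = ET.fromstring(path.read_text(encoding="utf-8"))
    except ET.ParseError as err:
        raise ValueError(f"malformed gold XML in {path}: {err}") from err

    spans: list[GoldSpan] = []
    tags_parent = root.find("TAGS")
    elements = list(tags_parent) if tags_parent is not None else [
        el for el in root if el.tag not in ("TEXT", "TAGS")
    ]
    for el in elements:
        if dialect == "I2B2":
            if el.get("start") is None:
                continue
            start, end = int(el.get("start")), int(el.get("end"))
            category = el.get("TYPE") or el.tag
        else:
            spans_attr = el.get("spans")
            if spans_attr is None:
                continue
            start_s, end_s = spans_attr.split("~")
            start, end = int(start_s), int(end_s)
            category = XML_TAG_REVERSE.get(el.tag, el.tag)
        if category not in DEFAULT_CATEGORIES:
            log.warning("registering unknown PHI category %r from %s", category, path.name)
            DEFAULT_CATEGORIES.register(category)
        spans.append(GoldSpan(start=start, end=end, category=category, surface=el.get("text", "")))

    return GoldAnnotation(
        note_id=path.stem, spans=_merge_overlapping(spans), source_dialect=dialect
    )


_YEAR_RE = re.compile(r"^(?:1[89]\d\d|20\d\d)$")
_SEASONS = {"winter", "spring", "summer", "fall", "autumn"}
_WEEKDAYS = {
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday",
    "mon", "tue", "tues", "wed", "thu", "thur", "thurs", "fri", "sat", "sun",
}
_COUNTRIES = {
    "usa", "america", "canada", "mexico", "england", "britain", "france",
    "germany", "spain", "italy", "china", "japan", "india", "brazil", "russia",
    "australia", "ireland", "scotland", "portugal", "greece", "poland",
    "vietnam", "korea", "philippines", "cuba", "colombia", "peru", "argentina",
}
_ID_CATEGORIES = {"IDNUM", "MEDICALRECORD", "ID"}


def normalize_i2b2_gold(gold: GoldAnnotation, doc: NoteDocument) -> GoldAnnotation:
    """Relabel i2b2 annotations that exceed Safe Harbor from PHI to safe.

    Removed from gold: years in isolation, season words, days of the week,
    single letters with no adjacent PHI content, country names, ages under
    90, and surrogate patient ID numbers of four digits or less.
    """
    if gold.source_dialect != "I2B2":
        raise ValueError("normalization applies to the I2B2 dialect only")

    def surface(span: GoldSpan) -> str:
        return span.surface or doc.text[span.start : span.end]

    kept: list[GoldSpan] = []
    for span in gold.spans:
        s = surface(span).strip()
        lower = s.lower()
        cat = span.category.upper()
        if _YEAR_RE.match(s):
            continue
        if lower in _SEASONS or lower in _WEEKDAYS or lower in _COUNTRIES:
            continue
        if cat == "AGE" and s.isdigit() and int(s) < 90:
            continue
        if cat in _ID_CATEGORIES and s.isdigit() and len(s) <= 4:
            continue
        kept.append(span)

    # single letters with no adjacent gold content: a one-letter span whose
    # neighboring tokens are not themselves gold PHI
    tokens = tokenize(doc)
    final: list[GoldSpan] = []
    for span in kept:
        s = surface(span).strip()
        if len(s) == 1 and s.isalpha():
            others = [o for o in kept if o is not span]
            idx = next(
                (i for i, t in enumerate(tokens) if t.intersects(span.start, span.end)), None
            )
            adjacent_gold = False
            if idx is not None:
                for j in (idx - 1, idx + 1):
                    if 0 <= j < len(tokens) and any(
                        tokens[j].intersects(o.start, o.end) for o in others
                    ):
                        adjacent_gold = True
                        break
            if not adjacent_gold:
                continue
        final.append(span)

    return GoldAnnotation(note_id=gold.note_id, spans=final, source_dialect="I2B2")


def f2_score(precision: float, recall: float) -> float:
    """F2 on the percentage scale, rounded to 2 decimals for reports."""
    denom = 4.0 * precision + recall
    if denom == 0:
        raise ValueError("F2 undefined when 4*precision + recall = 0")
    return round(5.0 * precision * recall / denom, 2)


@dataclass
class MetricsResult:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    per_category_fn: dict[str, int] = field(default_factory=dict)

    @property
    def total_tokens(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 100.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else 100.0

    @property
    def f2(self) -> float:
        if self.precision == 0.0 and self.recall == 0.0:
            return 0.0
        return f2_score(self.precision, self.recall)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "recall": round(self.recall, 2),
            "precision": round(self.precision, 2),
            "f2": round(self.f2, 2),
            "per_category_fn": dict(sorted(self.per_category_fn.items())),
        }


def evaluate_note(
    original: NoteDocument,
    deid_output: str,
    gold: GoldAnnotation,
    obfuscation_char: str = "*",
) -> MetricsResult:
    """Token-level contingency of a de-identified note against gold.

    Requires character alignment (equal lengths); external tools that do
    not preserve length must first go through align_external_output.
    """
    if len(deid_output) != len(original.text):
        raise ValueError(
            f"alignment broken for {original.note_id}: output length "
            f"{len(deid_output)} != input length {len(original.text)}"
        )
    tokens = tokenize(original)
    result = MetricsResult()
    for tok in tokens:
        predicted = any(
            deid_output[i] == obfuscation_char for i in range(tok.start, tok.end)
        )
        hits = [sp for sp in gold.spans if tok.intersects(sp.start, sp.end)]
        is_gold = bool(hits)
        if predicted and is_gold:
            result.tp += 1
        elif predicted:
            result.fp += 1
        elif is_gold:
            result.fn += 1
            cat = hits[0].category
            result.per_category_fn[cat] = result.per_category_fn.get(cat, 0) + 1
        else:
            result.tn += 1
    return result


def corpus_report(per_note: Sequence[MetricsResult]) -> tuple[MetricsResult, pd.DataFrame]:
    """Micro-averaged corpus metrics plus the per-category leakage table."""
    if not per_note:
        raise ValueError("corpus_report requires at least one note")
    total = MetricsResult()
    for m in per_note:
        total.tp += m.tp
        total.fp += m.fp
        total.tn += m.tn
        total.fn += m.fn
        for cat, n in m.per_category_fn.items():
            total.per_category_fn[cat] = total.per_category_fn.get(cat, 0) + n
    table = pd.DataFrame(
        sorted(total.per_category_fn.items()),
        columns=["PHI category", "Instances of PHI remaining"],
    )
    return total, table


def align_external_output(original_text: str, external_text: str) -> str:
    """Recover a character-aligned output from a tool that altered lengths.

    Matches the token sequences of the two texts; original tokens without a
    matching counterpart are treated as redacted.  The result has exactly
    the original length and can be fed to evaluate_note.
    """
    orig_doc = NoteDocument("align", original_text)
    orig_tokens = tokenize(orig_doc)
    ext_tokens = [t.surface for t in tokenize(NoteDocument("ext", external_text))]
    matcher = difflib.SequenceMatcher(
        a=[t.surface for t in orig_tokens], b=ext_tokens, autojunk=False
    )
    kept = set()
    for block in matcher.get_matching_blocks():
        kept.update(range(block.a, block.a + block.size))
    out = [" " if ch == "*" else ch for ch in orig_doc.text]
    for i, tok in enumerate(orig_tokens):
        if i not in kept:
            for k in range(tok.start, tok.end):
                out[k] = "*"
    return "".join(out)
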