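"""Seeded synthetic clinical-note generator with exact gold annotations.

Real de-identification corpora cannot be redistributed, so the test bed is
generated: medical-flavored safe sentences interleaved with sentences that
embed PHI of every category in the taxonomy, with the exact character span
of each injected PHI surface recorded as gold.  The generator deliberately
reproduces the failure modes that make de-identification hard — surnames
that are also common words ("White", "Stone"), misspelled names that no
lexicon contains, dates and identifiers in several formats — at
configurable rates.

Notes are written as plain ``.txt`` and gold as MAE-style XML, so tests
exercise the real reader path rather than a private shortcut.  One global
seed drives all randomness.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import pipeline
from .document import EXCLUDE, INCLUDE, NoteDocument, tokenize
from .evaluation import XML_TAG_ALIASES, GoldAnnotation, GoldSpan
from .lexicons import (
    BlacklistBuildConfig,
    load_lexicon,
    read_frequency_table,
)

__all__ = ["SynthConfig", "SynthNote", "generate_corpus", "oracle_filter", "write_corpus"]

DATA_DIR = Path(__file__).parent / "data"

#: Expected PHI instances per note, per category.  These defaults produce
#: notes in which dates and names dominate, identifiers and contact details
#: are common, and rare categories still appear across a modest corpus.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "Date": 2.0,
    "Patient_Name_or_Family_Member_Name": 1.5,
    "Provider_Name": 1.0,
    "Patient_Phone_Fax": 0.5,
    "Provider_Phone_Fax": 0.3,
    "Patient_Social_Security_Number": 0.2,
    "Patient_Address": 0.4,
    "Provider_Address_or_Location": 0.3,
    "Email": 0.3,
    "URL_IP": 0.3,
    "Patient_Medical_Record_Id": 0.6,
    "Patient_Account_Number": 0.3,
    "Patient_Unique_ID": 0.4,
    "Provider_Certificate_or_License": 0.2,
    "Patient_Vehicle_or_Device_Id": 0.2,
    "Age >= 90": 0.3,
    "Patient_Initials": 0.3,
    "Provider_Initials": 0.3,
}

SAFE_SENTENCES = [
    "The patient reports feeling much better today.",
    "Denies fever, chills, or night sweats.",
    "Blood pressure was 128/76 and heart rate was 72 bpm.",
    "Continue aspirin 81 mg daily for prevention.",
    "Physical exam revealed clear lungs and regular heart sounds.",
    "Assessment and plan were discussed in detail.",
    "The wound is healing well without signs of infection.",
    "Started metformin 500 mg twice daily with meals.",
    "Follow up in 2 weeks for repeat labs.",
    "Creatinine was 1.1 and potassium was 4.2 today.",
    "No acute distress was noted during the visit.",
    "The abdomen was soft and nontender on palpation.",
    "Reviewed the medication list and updated allergies.",
    "Pain score was 3/10 at rest.",
    "Temperature was 98.6 and pulse was 68 today.",
    "The patient tolerated the procedure well without complications.",
    "Discussed risks and benefits of continued therapy.",
    "Gait was steady and strength was symmetric.",
    "Chest radiograph showed no acute findings.",
    "Increased lisinopril to 20 mg daily for hypertension.",
    "White fluid was noted at the wound site.",
    "Edema was absent and pulses were regular.",
    "Will continue current medications and review labs in 1 month.",
    "Glucose was 104 and a1c was 6.8 this visit.",
    "The patient denies nausea, vomiting, or diarrhea.",
]

_MONTHS = [
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
]

_AMBIGUOUS_SURNAMES = [
    "White", "Green", "Young", "Stone", "Snow", "Rice", "Banks", "King",
    "Marshall", "Woods", "Fisher", "Brown",
]


@dataclass
class SynthConfig:
    seed: int = 0
    n_notes: int = 50
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    ambiguous_fraction: float = 0.15
    misspelling_rate: float = 0.02
    safe_sentences_per_note: tuple[int, int] = (4, 10)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.category_mix.values()):
            raise ValueError("category_mix values must be >= 0")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ValueError("ambiguous_fraction must lie in [0, 1]")


@dataclass
class SynthNote:
    doc: NoteDocument
    gold: GoldAnnotation


def _name_pools() -> tuple[list[str], list[str]]:
    """Capitalized first/last name pools from the fixture frequency tables,
    restricted to names the default blacklists will actually contain."""
    exclusions = frozenset(
        load_lexicon(DATA_DIR / "lexicons" / "blacklist_exclusions.txt").tokens
    )
    cfg = BlacklistBuildConfig(exclusion_words=exclusions)
    firsts, lasts = [], []
    for row in read_frequency_table(DATA_DIR / "lexicons" / "ssa_firstnames_synthetic.tsv"):
        name, year, count = row
        lo, hi = cfg.birth_year_range
        if lo <= year <= hi and count >= cfg.firstname_min_count:
            if name.lower() not in exclusions:
                firsts.append(name)
    for name, count in read_frequency_table(
        DATA_DIR / "lexicons" / "census_surnames_synthetic.tsv"
    ):
        if count >= cfg.surname_min_count and name.lower() not in exclusions:
            lasts.append(name)
    return sorted(set(firsts)), sorted(set(lasts))


class _Realizer:
    """PHI surface realizers; all randomness flows through one generator."""

    def __init__(self, rng: np.random.Generator, cfg: SynthConfig):
        self.rng = rng
        self.cfg = cfg
        self.firsts, self.lasts = _name_pools()
        self.ambiguous = [s for s in _AMBIGUOUS_SURNAMES if s in self.lasts]

    def _choice(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def _digits(self, n: int) -> str:
        return "".join(str(int(d)) for d in self.rng.integers(0, 10, size=n))

    def _misspell(self, name: str) -> str:
        if len(name) < 4:
            return name
        i = int(self.rng.integers(1, len(name) - 1))
        repl = self._choice("aeiouy")
        return name[:i] + repl + name[i + 1 :]

    def surname(self) -> str:
        if self.ambiguous and self.rng.random() < self.cfg.ambiguous_fraction:
            name = self._choice(self.ambiguous)
        else:
            name = self._choice(self.lasts)
        if self.rng.random() < self.cfg.misspelling_rate:
            name = self._misspell(name)
        return name

    def first_name(self) -> str:
        name = self._choice(self.firsts)
        if self.rng.random() < self.cfg.misspelling_rate:
            name = self._misspell(name)
        return name

    def full_name(self) -> str:
        return f"{self.first_name()} {self.surname()}"

    def date(self) -> str:
        y = int(self.rng.integers(1995, 2020))
        m = int(self.rng.integers(1, 13))
        d = int(self.rng.integers(1, 29))
        style = int(self.rng.integers(4))
        if style == 0:
            return f"{m:02d}/{d:02d}/{y}"
        if style == 1:
            return f"{y}-{m:02d}-{d:02d}"
        if style == 2:
            return f"{_MONTHS[m - 1]} {d}, {y}"
        return f"{d} {_MONTHS[m - 1]} {y}"

    def phone(self) -> str:
        area, mid, last = self._digits(3), self._digits(3), self._digits(4)
        if self.rng.random() < 0.5:
            return f"({area}) {mid}-{last}"
        return f"{area}-{mid}-{last}"

    def ssn(self) -> str:
        return f"{self._digits(3)}-{self._digits(2)}-{self._digits(4)}"

    def email(self) -> str:
        first, last = self.first_name().lower(), self.surname().lower()
        domain = self._choice(["example.org", "mailhost.net", "webmail.com"])
        return f"{first}.{last}@{domain}"

    def url_or_ip(self) -> str:
        if self.rng.random() < 0.5:
            host = self._choice(["healthportal", "clinicnet", "labresults"])
            return f"www.{host}.org/visit{self._digits(3)}"
        return ".".join(str(int(self.rng.integers(1, 255))) for _ in range(4))

    def street_address(self) -> str:
        number = str(int(self.rng.integers(10, 9999)))
        street = self._choice(["Maple", "Oak", "Cedar", "Pine", "Elm", "Lake"])
        kind = self._choice(["Street", "Avenue", "Road", "Drive", "Lane"])
        return f"{number} {street} {kind}"


def _phi_sentence(cat: str, rz: _Realizer) -> list[tuple[str, str | None]]:
    """Sentence template for one PHI category: (text, category) parts."""
    if cat == "Patient_Name_or_Family_Member_Name":
        name = rz.full_name()
        return [
            ("The patient ", None),
            (name, cat),
            (" was seen in clinic today.", None),
        ]
    if cat == "Provider_Name":
        return [("Seen by Dr. ", None), (rz.surname(), cat), (" for followup.", None)]
    if cat == "Date":
        return [("The patient returned on ", None), (rz.date(), cat), (" for review.", None)]
    if cat == "Patient_Phone_Fax":
        return [("Contact number ", None), (rz.phone(), cat), (" was confirmed.", None)]
    if cat == "Provider_Phone_Fax":
        return [("Office fax ", None), (rz.phone(), cat), (" is on file.", None)]
    if cat == "Patient_Social_Security_Number":
        return [("Social security number ", None), (rz.ssn(), cat), (" is on file.", None)]
    if cat == "Patient_Address":
        return [("The patient lives at ", None), (rz.street_address(), cat), (" with family.", None)]
    if cat == "Provider_Address_or_Location":
        return [("The clinic is at ", None), (rz.street_address(), cat), (" on campus.", None)]
    if cat == "Email":
        return [("Results were sent to ", None), (rz.email(), cat), (" today.", None)]
    if cat == "URL_IP":
        return [("Portal access at ", None), (rz.url_or_ip(), cat), (" was reviewed.", None)]
    if cat == "Patient_Medical_Record_Id":
        return [("MRN: ", None), (rz._digits(7), cat), (".", None)]
    if cat == "Patient_Account_Number":
        return [("Account number ", None), (rz._digits(8), cat), (" was billed.", None)]
    if cat == "Patient_Unique_ID":
        return [("Patient ID ", None), (rz._digits(6), cat), (" was verified.", None)]
    if cat == "Provider_Certificate_or_License":
        return [("License number ", None), ("MD" + rz._digits(6), cat), (" is current.", None)]
    if cat == "Patient_Vehicle_or_Device_Id":
        return [
            ("Pacemaker serial number ", None),
            ("SN" + rz._digits(6), cat),
            (" was checked.", None),
        ]
    if cat == "Age >= 90":
        return [
            ("The patient is age ", None),
            (str(int(rz.rng.integers(90, 106))), cat),
            (" and lives alone.", None),
        ]
    if cat == "Patient_Initials":
        last = rz.surname()
        init = rz._choice("ABCDEFGHJKLMPRSTW")
        return [
            ("Patient ", None),
            (last, "Patient_Name_or_Family_Member_Name"),
            (", ", None),
            (init, cat),
            (". signed the consent form.", None),
        ]
    if cat == "Provider_Initials":
        last = rz.surname()
        init = rz._choice("ABCDEFGHJKLMPRSTW")
        return [
            ("Countersigned by Dr. ", None),
            (last, "Provider_Name"),
            (", ", None),
            (init, cat),
            (".", None),
        ]
    raise ValueError(f"no template for category {cat!r}")


def generate_corpus(cfg: SynthConfig) -> list[SynthNote]:
    """Generate a deterministic corpus of annotated synthetic notes."""
    if cfg.n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    if not SAFE_SENTENCES:
        raise ValueError("safe sentence pool is empty")
    rng = np.random.default_rng(cfg.seed)
    rz = _Realizer(rng, cfg)
    notes: list[SynthNote] = []
    for k in range(cfg.n_notes):
        lo, hi = cfg.safe_sentences_per_note
        n_safe = int(rng.integers(lo, hi + 1))
        sentences: list[list[tuple[str, str | None]]] = [
            [(SAFE_SENTENCES[int(rng.integers(len(SAFE_SENTENCES)))], None)]
            for _ in range(n_safe)
        ]
        for cat in sorted(cfg.category_mix):
            for _ in range(int(rng.poisson(cfg.category_mix[cat]))):
                sentences.append(_phi_sentence(cat, rz))
        order = rng.permutation(len(sentences))
        text_parts: list[str] = []
        spans: list[GoldSpan] = []
        offset = 0
        for idx in order:
            for part, cat in sentences[int(idx)]:
                if cat is not None:
                    spans.append(
                        GoldSpan(start=offset, end=offset + len(part), category=cat, surface=part)
                    )
                text_parts.append(part)
                offset += len(part)
            sep = "\n" if rng.random() < 0.4 else " "
            text_parts.append(sep)
            offset += len(sep)
        note_id = f"synth_{k:04d}"
        doc = NoteDocument(note_id=note_id, text="".join(text_parts))
        notes.append(
            SynthNote(
                doc=doc,
                gold=GoldAnnotation(note_id=note_id, spans=spans, source_dialect="MAE"),
            )
        )
    return notes


def oracle_filter(note: SynthNote, obfuscation_char: str = "*") -> str:
    """Perfect-knowledge reference: obfuscate exactly the gold spans."""
    tokens = tokenize(note.doc)
    for tok in tokens:
        hit = any(tok.intersects(sp.start, sp.end) for sp in note.gold.spans)
        tok.label = EXCLUDE if hit else INCLUDE
    shim = pipeline.PipelineConfig(name="oracle", stages=[], obfuscation_char=obfuscation_char)
    return pipeline.obfuscate(note.doc, tokens, shim)


def _xml_tag(category: str) -> str:
    tag = XML_TAG_ALIASES.get(category, category)
    return re.sub(r"[^A-Za-z0-9_]", "_", tag)


def write_corpus(notes: list[SynthNote], out_dir: str | Path) -> None:
    """Write notes/ (.txt) and gold/ (MAE-style .xml) under out_dir."""
    out_dir = Path(out_dir)
    notes_dir, gold_dir = out_dir / "notes", out_dir / "gold"
    notes_dir.mkdir(parents=True, exist_ok=True)
    gold_dir.mkdir(parents=True, exist_ok=True)
    for note in notes:
        (notes_dir / f"{note.doc.note_id}.txt").write_text(note.doc.text, encoding="utf-8")
        root = ET.Element("NoteAnnotations")
        text_el = ET.SubElement(root, "TEXT")
        text_el.text = note.doc.text
        tags_el = ET.SubElement(root, "TAGS")
        for i, sp in enumerate(note.gold.spans):
            ET.SubElement(
                tags_el,
                _xml_tag(sp.category),
                id=f"P{i}",
                spans=f"{sp.start}~{sp.end}",
                text=sp.surface,
            )
        ET.indent(root)
        (gold_dir / f"{note.doc.note_id}.xml").write_text(
            ET.tostring(root, encoding="unicode"), encoding="utf-8"
        )
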