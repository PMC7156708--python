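"""Pipeline orchestration: configured stage cascade, final disposition,
and length-preserving obfuscation.

The cascade is driven entirely by a JSON configuration whose ``stages``
array fixes both which stages run and their priority (first-writer-wins:
whichever stage labels a token first owns that decision).  After the last
stage, disposition is privacy-conservative — only tokens explicitly marked
for inclusion are retained; excluded *and still-unmarked* tokens are
replaced character-for-character with the obfuscation character, so the
output note has exactly the original length and structure.  Asterisks
already present in the source text are replaced with spaces so that an
asterisk in the output always means "redacted here".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

from . import filters, lexicons
from .document import (
    DEFAULT_SEPARATORS,
    EXCLUDE,
    INCLUDE,
    UNMARKED,
    NoteDocument,
    TokenSpan,
    read_corpus,
    tokenize,
)

__all__ = ["PipelineConfig", "DeidResult", "run_note", "obfuscate", "run_corpus"]

log = logging.getLogger(__name__)

DATA_DIR = Path(__file__).parent / "data"

STAGE_KINDS = {
    "safe_regex",
    "phi_regex",
    "age_rule",
    "pos_tag",
    "name_blacklist",
    "name_context",
    "whitelist",
    "initials",
}


def _resolve(resource: str, base: Path | None) -> Path:
    """Resolve a stage resource path: config-relative first, then shipped data."""
    if base is not None and (base / resource).exists():
        return base / resource
    if (DATA_DIR / resource).exists():
        return DATA_DIR / resource
    p = Path(resource)
    if p.exists():
        return p
    raise FileNotFoundError(f"pipeline resource not found: {resource}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with all resources loaded."""

    name: str
    stages: list[dict[str, Any]]
    obfuscation_char: str = "*"
    separators: frozenset[str] = DEFAULT_SEPARATORS
    adjacency_radius: int = 1
    tagger: filters.Tagger | None = None
    _runners: list[tuple[str, Callable]] = field(default_factory=list, repr=False)
    _blacklist_stages: set[str] = field(default_factory=set, repr=False)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = json.loads(path.read_text(encoding="utf-8"))
        return cls.from_dict(raw, base=path.parent)

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls.from_json(DATA_DIR / "config" / "default.json")

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base: Path | None = None) -> "PipelineConfig":
        stages = raw.get("stages")
        if not isinstance(stages, list):
            raise ValueError("config must contain a 'stages' array")
        names = [s.get("name") for s in stages]
        if len(names) != len(set(names)):
            raise ValueError("stage names must be unique")
        obf = raw.get("obfuscation_char", "*")
        if len(obf) != 1:
            raise ValueError("obfuscation_char must be a single character")
        separators = frozenset(raw["separators"]) if raw.get("separators") else DEFAULT_SEPARATORS

        tagger: filters.Tagger
        if raw.get("pos_tagger", "rule") == "rule":
            lex_path = raw.get("tagger_lexicon")
            if lex_path:
                tagger = filters.RuleBasedTagger.from_tsv(_resolve(lex_path, base))
            else:
                tagger = filters.RuleBasedTagger()
        else:
            raise ValueError(f"unknown pos_tagger: {raw['pos_tagger']!r}")

        cfg = cls(
            name=raw.get("name", "unnamed"),
            stages=stages,
            obfuscation_char=obf,
            separators=separators,
            adjacency_radius=int(raw.get("adjacency_radius", 1)),
            tagger=tagger,
        )
        cfg._compile(base)
        return cfg

    # -- stage compilation ---------------------------------------------------

    def _compile(self, base: Path | None) -> None:
        """Validate every stage and bind its resources before any note runs."""
        self._runners = []
        self._blacklist_stages = set()
        tags_available = False
        for spec in self.stages:
            kind = spec.get("kind")
            name = spec.get("name", kind)
            if kind not in STAGE_KINDS:
                raise ValueError(f"unknown stage kind: {kind!r}")
            if kind in ("name_blacklist", "whitelist") and not tags_available:
                raise ValueError(f"stage {name!r} requires a preceding pos_tag stage")
            runner = self._build_runner(kind, name, spec, base)
            self._runners.append((name, runner))
            if kind == "pos_tag":
                tags_available = True
            if kind == "name_blacklist":
                self._blacklist_stages.add(name)

    def _build_runner(
        self, kind: str, name: str, spec: dict[str, Any], base: Path | None
    ) -> Callable:
        if kind == "safe_regex":
            lib = filters.load_regex_library(_resolve(spec["library"], base))
            return lambda doc, toks: filters.apply_safe_regex(doc, toks, lib, stage=name)
        if kind == "phi_regex":
            lib = filters.load_regex_library(_resolve(spec["library"], base))
            return lambda doc, toks: filters.apply_phi_regex(doc, toks, lib, stage=name)
        if kind == "age_rule":
            params = spec.get("params", {})
            age_cfg = filters.AgeRuleConfig(
                threshold=int(params.get("threshold", 90)),
                context_radius=int(params.get("context_radius", 2)),
            )
            return lambda doc, toks: filters.apply_age_rule(doc, toks, age_cfg, stage=name)
        if kind == "pos_tag":
            return lambda doc, toks: filters.pos_tag(doc, toks, self.tagger)
        if kind == "name_blacklist":
            lex = self._load_blacklist(spec, base)
            return lambda doc, toks: filters.apply_name_blacklist(toks, lex, stage=name) and toks
        if kind == "name_context":
            lib = filters.load_regex_library(_resolve(spec["library"], base))
            return lambda doc, toks: filters.apply_name_context(
                doc, toks, lib, self._blacklist_stages, stage=name, radius=self.adjacency_radius
            )
        if kind == "whitelist":
            lex = self._load_whitelist(spec, base)
            return lambda doc, toks: filters.apply_whitelist(toks, lex, stage=name) and toks
        if kind == "initials":
            lib = filters.load_regex_library(_resolve(spec["library"], base))
            return lambda doc, toks: filters.apply_initials(
                doc, toks, lib, self._blacklist_stages, stage=name, radius=self.adjacency_radius
            )
        raise AssertionError(kind)

    def _load_blacklist(self, spec: dict[str, Any], base: Path | None) -> lexicons.Lexicon:
        if "lexicon" in spec:
            return lexicons.load_lexicon(_resolve(spec["lexicon"], base))
        exclusions: frozenset[str] = frozenset()
        if spec.get("exclusions"):
            exclusions = frozenset(
                lexicons.load_lexicon(_resolve(spec["exclusions"], base)).tokens
            )
        bcfg = lexicons.BlacklistBuildConfig(exclusion_words=exclusions)
        rows = lexicons.read_frequency_table(_resolve(spec["table"], base))
        if spec.get("table_kind", "census") == "census":
            return lexicons.build_last_name_blacklist(rows, bcfg)
        return lexicons.build_first_name_blacklist(rows, bcfg)

    def _load_whitelist(self, spec: dict[str, Any], base: Path | None) -> lexicons.Lexicon:
        if "lexicon" in spec:
            return lexicons.load_lexicon(_resolve(spec["lexicon"], base))
        sources = [
            lexicons.load_lexicon(_resolve(s, base)).tokens for s in spec.get("sources", [])
        ]
        add_back: list[str] = []
        if spec.get("add_back"):
            add_back = sorted(lexicons.load_lexicon(_resolve(spec["add_back"], base)).tokens)
        blacklists = [
            self._load_blacklist(s, base) for s in self.stages if s.get("kind") == "name_blacklist"
        ]
        return lexicons.build_whitelist(sources, blacklists, add_back)


@dataclass
class DeidResult:
    note_id: str
    output_text: str
    token_labels: list[TokenSpan]
    stage_log: dict[str, dict[str, int]]


def obfuscate(doc: NoteDocument, final_tokens: list[TokenSpan], cfg: PipelineConfig) -> str:
    """Replace every character of non-included tokens with the obfuscation
    character; replace original asterisks with spaces; preserve everything
    else in place.  Output length equals input length."""
    out = [" " if ch == "*" else ch for ch in doc.text]
    for tok in final_tokens:
        if tok.label != INCLUDE:
            for i in range(tok.start, tok.end):
                out[i] = cfg.obfuscation_char
    return "".join(out)


def run_note(doc: NoteDocument, cfg: PipelineConfig) -> DeidResult:
    """Run the configured cascade over one note and obfuscate."""
    tokens = tokenize(doc, cfg.separators)
    stage_log: dict[str, dict[str, int]] = {}
    unmarked_before = len(tokens)
    for name, runner in cfg._runners:
        runner(doc, tokens)
        counts = {EXCLUDE: 0, INCLUDE: 0}
        for t in tokens:
            if t.stage == name and t.label in counts:
                counts[t.label] += 1
        stage_log[name] = counts
        unmarked_now = sum(1 for t in tokens if t.label == UNMARKED)
        assert unmarked_now <= unmarked_before, "labels must be monotone"
        unmarked_before = unmarked_now
    output = obfuscate(doc, tokens, cfg)
    return DeidResult(
        note_id=doc.note_id, output_text=output, token_labels=tokens, stage_log=stage_log
    )


def run_corpus(
    input_dir: str | Path, output_dir: str | Path, cfg: PipelineConfig
) -> dict[str, Any]:
    """De-identify every ``.txt`` note in a directory.

    Writes one output note per input under the same filename plus a
    ``manifest.json`` with per-note stage summaries.  Notes are independent,
    so processing order cannot affect any output.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": cfg.name, "notes": {}, "skipped": []}
    for path in sorted(input_dir.glob("*.txt")):
        try:
            text = path.read_text(encoding="utf-8")
        except (OSError, UnicodeDecodeError) as err:
            log.warning("skipping unreadable note %s: %s", path.name, err)
            manifest["skipped"].append(path.name)
            continue
        result = run_note(NoteDocument(note_id=path.stem, text=text), cfg)
        (output_dir / path.name).write_text(result.output_text, encoding="utf-8")
        manifest["notes"][path.stem] = {
            "tokens": len(result.token_labels),
            "stage_log": result.stage_log,
            "obfuscated_tokens": sum(
                1 for t in result.token_labels if t.label != INCLUDE
            ),
        }
    (output_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
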