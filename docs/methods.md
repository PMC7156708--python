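# Methods

## Model of the problem

De-identification is cast as token labeling: a note is an immutable
character string, tokens are maximal runs of alphanumeric characters
(whitespace and a configurable separator set — `-`, `/`, `#`, `&`,
periods, commas, colons, quotes, brackets, and any other non-alphanumeric
character — split tokens), and each token ends the pipeline in one of
three states: *excluded* (PHI), *included* (safe), or *unmarked*. The
final disposition obfuscates everything not explicitly included. This
asymmetry is deliberate: the cost of a leaked identifier (a privacy
violation) is far higher than the cost of an over-redacted word, so the
default for unknown tokens is redaction, and the whitelist — not a PHI
detector — is what earns a token its survival.

All offsets are 0-based half-open intervals into the original text. Text
is NFC-normalized on load. Regex stages match on the raw text and are
projected onto tokens by interval intersection; a partial overlap claims
the whole token (privacy-conservative). Obfuscation rewrites each claimed
token character as `*` in place, preserving inter-token characters, so
`len(output) == len(input)` always holds; original asterisks become
spaces so an asterisk in output unambiguously means "redacted".

## Stage semantics and priority

Stages run in configuration order under first-writer-wins: a stage may
move a token only out of the *unmarked* state. Consequences worth noting:

* Safe regexes run before PHI regexes in the default order, so "50 mg"
  is claimed as a dosage before any numeric PHI pattern can touch it.
* The whitelist runs before the initials stage, so the whitelist must not
  pass single-letter proper-noun tokens ("J" in "Doe, J."); a lone capital
  letter is a candidate initial and is left for the initials stage or the
  safety-net default. Lowercase single letters (the article "a") pass
  normally.
* Whitelist inclusions are final; no later stage overrides them.

"Adjacent" in the name-context and initials conditions means stream
distance 1 (configurable via `adjacency_radius`); the minimal reading of
adjacency.

## POS tagging

The blacklist gate needs Penn-Treebank tags, specifically NNP. The
package ships a deterministic rule-based tagger: digit-bearing tokens are
CD; a capitalized word inside a sentence is NNP; a capitalized sentence
opener falls back to a lexical table (so "White fluid ..." opens with an
adjective, not a proper noun) and defaults to NNP when unknown — an
unknown capitalized sentence opener is most plausibly a name, and
guessing NNP errs toward privacy; lowercase words use a closed-class
table, the lexical table, then suffix heuristics (default NN). Sentence
openers are detected from the separator text between tokens
(`.!?:;` or a newline). The tagger contract (equal-length tag sequence
for a token sequence, sentence-initial flags supplied) is pluggable, so a
statistical tagger can replace the rule tagger without touching any stage.
The rule tagger's known failure mode is shared with statistical taggers:
capitalized non-names mid-sentence are called NNP, which costs precision,
not recall.

## Lexicons

* **Surname blacklist**: census-style rows kept at count ≥ 100.
* **First-name blacklist**: SSA-style rows kept at count ≥ 5 in at least
  one birth year in 1879–2017.
* Both are tokenized (multi-word names contribute each part), lowercased,
  and reduced by a curated exclusion list of name tokens whose
  common-word sense dominates ("new", "walks", "knee", "home", "child",
  months, virtue names). The exclusion list protects precision at a known,
  bounded recall cost.
* **Whitelist**: union of a common-English list and a medical-term list,
  minus every blacklist token, plus an add-back list of ambiguous words
  whose loss is too costly ("white", "young", "stone", ...). The
  whitelist ∩ blacklist residue equals the add-back set by construction,
  asserted at build time. Numeric-tagged tokens never consult the
  whitelist: an unexplained number is always redacted.

The shipped frequency tables and vocabularies are synthetic fixtures
(named `*_synthetic` in `data/lexicons/`), a few hundred rows each, in the
exact shape of the real sources; the build code is the real build code.
Production deployments should rebuild from the full census/SSA files and
a real medical vocabulary, via the same `lexicons` functions.

## Regex libraries

The shipped safe library (15 entries) and PHI library (19 entries) cover
every category the cascade targets — dosages/vitals/labs/durations on the
safe side; emails, SSNs, phones, dates in five formats, URLs/IPs, MRN /
account / patient-ID / license / device numbers with label context,
salutation-attached names, and street/ZIP addresses on the PHI side. They
are curated representatives, not an entry-for-entry reproduction of any
production library; the TSV format (`polarity, category, description,
pattern`) is the extension point, and a named group `m` in a pattern
confines the claimed span so trigger context ("MRN:") is not redacted.

## Evaluation

A token is predicted-PHI iff any of its characters is the obfuscation
character in the output; it is gold-PHI iff it intersects any gold span
(whole-token counting on both sides — the token-instance convention).
Character alignment is required and enforced; an alignment-recovery
adapter (`align_external_output`, token-sequence matching via longest
matching blocks) scores external tools that do not preserve length.
Corpus metrics are micro-averaged (counts summed before ratios). Recall
and precision of an empty denominator are reported as 100 (nothing to
find / nothing removed); F2 of P=R=0 is reported as 0. Report values are
percentages rounded to two decimals.

The i2b2-2014 normalization (annotations stricter than Safe Harbor
relabeled as safe) removes: 4-digit years in isolation, season words,
weekdays, country names, ages under 90, one-letter spans whose radius-1
token neighbors are not gold PHI, and digit-only patient-ID spans of ≤ 4
digits (unrealistic surrogates).

## Synthetic corpus generator

The generator emulates the *structure* of annotated clinical corpora:
template sentences of medical-flavored safe text interleaved with
PHI-bearing sentences, one exact gold span per injected surface, written
as `.txt` + MAE-style XML so tests exercise the real reader. Per-note
category counts are Poisson with configurable means (defaults: dates 2.0
and names 1.5 per note dominating, identifiers and contact details 0.2–
0.6 — the mix skews toward the categories that dominate real corpora).
Deliberate hard cases: a configurable fraction (default 0.15) of surnames
drawn from the name/common-word overlap pool ("White", "Stone", ...), and
a misspelling rate (default 0.02) producing names no lexicon contains.
One `numpy` generator seeded from the single config seed drives all
randomness; categories are iterated in sorted order, so equal seeds give
byte-identical corpora.

What passing on synthetic data does **not** show: real notes have
headers, tables, OCR noise, ungrammatical fragments, and PHI in contexts
the templates do not model; synthetic recall/precision are upper bounds,
useful for catching regressions and contract violations, not for
certifying real-world performance. The published corpus-level results
cannot be recomputed here because the underlying corpora are private or
DUA-gated; the acceptance script therefore recomputes exactly the numbers
derivable from printed inputs (the six F2 values from their printed
precision/recall pairs).

## Numerical and degenerate-input choices

* Empty note → empty token list, empty output.
* Age rule ignores numbers > 200 near age triggers (not plausibly an age)
  and never relabels tokens already claimed (e.g. by a dosage pattern).
* Overlapping gold spans are merged on load; the earlier span's category
  wins ties.
* Problem sizes in the test suite (30–200 synthetic notes, 10,000-document
  obfuscation fuzz, 1,000 random lexicon tables) were chosen to give the
  property checks real coverage while keeping the whole suite near a
  couple of minutes on one CPU.

## Known limitations

* The patient/provider distinction is not decidable at detection time;
  detection assigns generic `Name`/`Initials` categories, and the split
  exists only in gold annotations.
* Possessives tokenize as two tokens ("Smith's" → "Smith", "s"); the
  apostrophe is a separator by default.
* The rule tagger's NNP default for unknown capitalized words trades
  precision for recall by design.
* No surrogate generation: PHI is obfuscated, never replaced with
  realistic fake values.
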