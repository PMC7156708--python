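# phifilter

Rule-cascade de-identification of free-text clinical notes, with a
token-level evaluation framework and a synthetic annotated-note generator.

Clinical notes are the richest record of a patient's course, but they are
full of Protected Health Information (PHI) — names, dates, phone numbers,
medical record numbers, addresses — and cannot be shared for research until
that PHI is removed. `phifilter` is for informatics teams who need a
transparent, configurable, offline-capable de-identifier whose behavior can
be audited stage by stage, and who need to *measure* how much PHI a filter
misses before trusting it.

## Method

The pipeline is an ordered cascade over a tokenized note, driven by a JSON
configuration. Each stage may mark an unlabeled token *include* (safe) or
*exclude* (PHI); a label, once set, is never overwritten, so stage order is
priority (first-writer-wins). The shipped default order is:

1. **safe regexes** — phrases that are very unlikely to be PHI (dosages
   "50 mg", vitals "BP 128/76", lab values, durations, scores);
2. **PHI regexes** — predictable identifiers matched on raw text (emails,
   SSNs, phone/fax, dates, MRNs, account and license numbers, addresses,
   URLs/IPs, salutation-attached names);
3. **age rule** — a number near "age"/"years old" is an age: ≥ 90 is PHI
   (HIPAA Safe Harbor), < 90 is safe;
4. **POS tagging** — a deterministic rule-based Penn-Treebank tagger (any
   tagger honoring the same contract is pluggable);
5. **name blacklists** — census-style surnames (count ≥ 100) and SSA-style
   first names (count ≥ 5 in any birth year 1879–2017), lowercased, minus a
   curated common-word exclusion list; a blacklisted token is PHI **only if
   tagged NNP** — this gate is what redacts "White" in *"Patient John White
   presents with..."* while keeping it in *"White fluid found at..."*;
6. **name context** — name-shaped patterns ("Jane Doe", "Doe, Jane") fire
   only next to a prior blacklist hit;
7. **whitelist safety net** — ~medical + common-English vocabulary, minus
   all blacklist names, plus a small add-back list; unlabeled non-numeric
   tokens not found here stay unlabeled;
8. **initials** — "Doe, J." shapes, again gated on adjacent blacklist hits.

At disposition, **only tokens marked include survive**; excluded *and
still-unmarked* tokens are replaced character-for-character with `*`
("John Smith" → `**** *****`), so output length and structure match the
input exactly; asterisks already in the source become spaces.

Performance is scored at the token level: with TP = PHI tokens obfuscated,
FP = safe tokens obfuscated, FN = PHI tokens leaked,

```
Recall = TP/(TP+FN)   Precision = TP/(TP+FP)   F2 = 5·P·R/(4·P+R)
```

Recall is the privacy-critical metric; F2 weights it twice as heavily as
precision. Per-category FN counts give the leakage report.

## Worked example

```
phifilter synth --out demo --seed 7 --n-notes 25
phifilter run   --input demo/notes --output demo/deid
phifilter eval  --gold demo/gold --original demo/notes --deid demo/deid --dialect mae
```

prints

```
wrote 25 synthetic notes to demo
de-identified 25 notes -> demo/deid
P 100.00  R 100.00  F2 100.00  (TP 523 FP 0 TN 2676 FN 0)
```

A note in `demo/notes` reading

```
The patient Gragory Davis was seen in clinic today. ... White fluid was noted at the wound site.
Results were sent to zachary.stone@example.org today. ... returned on 2001-12-13 for review.
```

comes out as

```
The patient ******* ***** was seen in clinic today. ... White fluid was noted at the wound site.
Results were sent to *******.*****@*******.*** today. ... returned on ****-**-** for review.
```

Every gold PHI token was obfuscated (recall 100), no safe token was lost
(precision 100) on this synthetic corpus — note that the misspelled first
name "Gragory", absent from every lexicon, was still caught by the
whitelist safety net, while sentence-initial "White" (an adjective here)
survived the name blacklist thanks to the POS gate. Synthetic notes are
far easier than real ones; see `docs/methods.md` for what these numbers do
and do not show.

The library surface mirrors the CLI: `phifilter.run_note`,
`phifilter.evaluate_note`, `phifilter.generate_corpus`, etc.

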