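# Initials library: a single pattern over the shapes initials take.
# Single-letter tokens in a match are PHI iff adjacent to a blacklist hit.
PHI	Initials	Last, F. / F. Last / First M. Last	\b[A-Z][a-z]+,\s*(?:[A-Z]\.?\s*){1,3}|\b(?:[A-Z]\.\s*){1,3}[A-Z][a-z]+\b|\b[A-Z][a-z]+\s+[A-Z]\.\s+[A-Z][a-z]+\b
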