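# Name-context library: shapes that common names take in clinical notes.
# These are only applied to tokens adjacent to a prior blacklist exclusion.
PHI	Name	First Last, mid-sentence	(?<=[a-z,]\s)[A-Z][a-z]+\s+[A-Z][a-z]+\b
PHI	Name	Last, First	\b[A-Z][a-z]+,\s*[A-Z][a-z]+\b
PHI	Name	First M. Last	\b[A-Z][a-z]+\s+[A-Z]\.\s*[A-Z][a-z]+\b
PHI	Name	hyphenated surname	\b[A-Z][a-z]+-[A-Z][a-z]+\b
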