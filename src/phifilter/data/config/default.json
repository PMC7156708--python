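{
  "name": "default",
  "obfuscation_char": "*",
  "pos_tagger": "rule",
  "tagger_lexicon": "tagger/tagger_lexicon.tsv",
  "adjacency_radius": 1,
  "stages": [
    {"name": "safe_regex", "kind": "safe_regex",
     "library": "regex/safe_regex.tsv"},
    {"name": "phi_regex", "kind": "phi_regex",
     "library": "regex/phi_regex.tsv"},
    {"name": "age_rule", "kind": "age_rule",
     "params": {"threshold": 90, "context_radius": 2}},
    {"name": "pos_tag", "kind": "pos_tag"},
    {"name": "last_name_blacklist", "kind": "name_blacklist",
     "table": "lexicons/census_surnames_synthetic.tsv", "table_kind": "census",
     "exclusions": "lexicons/blacklist_exclusions.txt"},
    {"name": "first_name_blacklist", "kind": "name_blacklist",
     "table": "lexicons/ssa_firstnames_synthetic.tsv", "table_kind": "ssa",
     "exclusions": "lexicons/blacklist_exclusions.txt"},
    {"name": "name_context", "kind": "name_context",
     "library": "regex/name_context.tsv"},
    {"name": "whitelist", "kind": "whitelist",
     "sources": ["lexicons/english_words_synthetic.txt",
                 "lexicons/medical_terms_synthetic.txt"],
     "add_back": "lexicons/whitelist_addback.txt"},
    {"name": "initials", "kind": "initials",
     "library": "regex/initials.tsv"}
  ]
}
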