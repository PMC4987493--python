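# Question-word patterns, in precedence order (first match wins).
#
# Classification runs two passes over this list: first each category is
# tried anchored at the start of the sentence, then (for categories
# without `anchored_only: true`) anywhere in the sentence.  Multi-word
# categories such as "how-frequent" and "what-quantity" precede the bare
# "how" / "what" so that "how often" is never swallowed by "how";
# "whose" / "whom" precede "who" for the same reason.  A sentence that
# matches nothing falls into "others".
- category: how-frequent
  patterns:
    - 'how\s+often'
    - 'how\s+frequent(?:ly)?'
- category: what-quantity
  patterns:
    - 'how\s+(?:much|many)'
    - 'what\s+(?:amount|percentage|quantity)'
- category: yes-no
  anchored_only: true
  patterns:
    - '(?:is|are|was|were|am|do|does|did|can|could|will|would|should|shall|has|have|had|may|might|must)\b'
- category: when
  patterns:
    - '\bwhen\b'
- category: why
  patterns:
    - '\bwhy\b'
- category: where
  patterns:
    - '\bwhere\b'
- category: whose
  patterns:
    - '\bwhose\b'
- category: whom
  patterns:
    - '\bwhom\b'
- category: who
  patterns:
    - '\bwho\b'
- category: which
  patterns:
    - '\bwhich\b'
- category: what
  patterns:
    - '\bwhat\b'
- category: how
  patterns:
    - '\bhow\b'
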