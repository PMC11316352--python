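# Per-subtype CRISPR-Cas gene requirements.  Adaptation genes are shared
# across subtypes; interference gene sets are subtype-specific.  A list
# entry that is itself a list means "any one of these synonyms".
adaptation:
  - cas1
  - cas2
interference:
  I-E:
    - cas3
    - cse1
    - cse2
    - cas7
    - cas5
    - cas6e
  I-G:
    - cas3
    - [cas8u2, csb]
    - cas7
    - cas5
  III-B:
    - cas10
    - cmr1
    - cmr3
    - cmr4
    - cmr5
    - cmr6
  I-C:
    - cas3
    - cas5
    - cas7
    - cas8c
  I-D:
    - cas3d
    - cas10d
    - cas7
    - cas5
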