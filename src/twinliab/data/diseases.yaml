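# Illustrative register-based case definitions for seven organ-specific
# autoimmune diseases.  Code lists are editable configuration with
# representative ICD-10 / ICD-8/9 prefixes, not a canonical register
# extract; the ascertainment RULES (prefix matching, >=2-code exclusion
# logic, prescription requirements) are what the engine implements.
diseases:
  - name: hashimoto_thyroiditis
    inclusion_codes:
      ICD8: ["245.03"]
      ICD9: ["245A"]
      ICD10: ["E06.3"]
    exclusion_codes:
      ICD9: ["244"]
      ICD10: ["E03.1", "E89.0"]   # congenital / post-procedural hypothyroidism
    min_inclusion_count: 1
    required_atc:
      atc_prefix: "H03AA"         # levothyroxine
      min_dispensations: 2
      applies_if_alive_after: "2005-12-31"

  - name: atrophic_gastritis
    inclusion_codes:
      ICD8: ["281.00", "535.00"]
      ICD9: ["281A", "535A"]
      ICD10: ["D51.0", "K29.4"]   # pernicious anemia coded jointly
    exclusion_codes:
      ICD10: ["D51.1", "D51.2"]   # non-autoimmune B12 deficiency
    min_inclusion_count: 1
    required_atc:
      atc_prefix: "B03BA"         # vitamin B12
      min_dispensations: 2
      applies_if_alive_after: "2005-12-31"

  - name: celiac_disease
    inclusion_codes:
      ICD8: ["269.00"]
      ICD9: ["579A"]
      ICD10: ["K90.0"]
    exclusion_codes:
      ICD10: ["K90.1", "K90.4"]   # tropical sprue, other malabsorption
    min_inclusion_count: 1

  - name: graves_disease
    inclusion_codes:
      ICD8: ["242.00"]
      ICD9: ["242A"]
      ICD10: ["E05.0"]
    exclusion_codes:
      ICD10: ["E05.1", "E05.2"]   # toxic nodule / multinodular goitre
    min_inclusion_count: 1

  - name: type1_diabetes
    inclusion_codes:
      ICD9: ["250"]
      ICD10: ["E10"]
    exclusion_codes:
      ICD10: ["E11", "E13"]       # type 2 / other specified diabetes
    min_inclusion_count: 1
    include_registers: ["diabetes_register"]

  - name: vitiligo
    inclusion_codes:
      ICD8: ["709.01"]
      ICD9: ["709A"]
      ICD10: ["L80"]
    exclusion_codes: {}
    min_inclusion_count: 1

  - name: addison_disease
    inclusion_codes:
      ICD8: ["255.10"]
      ICD9: ["255E"]
      ICD10: ["E27.1", "E27.2"]
    exclusion_codes:
      ICD10: ["E27.3", "A18.7"]   # drug-induced / tuberculous adrenal failure
    min_inclusion_count: 2        # rare disease: stricter inclusion
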