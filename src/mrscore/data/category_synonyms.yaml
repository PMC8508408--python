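# Raw point-of-interest category labels -> the 8 canonical analysis
# categories (plus the "animal medical" contaminant removed in cleaning).
# Matching is done on the subcategory first, then the major category, after
# trimming and case-folding. Editable: source feeds use untidy, multilingual
# labels, so extend this table as needed; the canonical names on the left
# are fixed.
3a hospital:
  - 3a hospital
  - tertiary grade a hospital
  - grade iii level a hospital
general hospital:
  - general hospital
specialized hospital:
  - specialized hospital
  - specialty hospital
  - dental hospital
  - stomatological hospital
  - eye hospital
  - maternity hospital
  - maternal and child health hospital
  - children's hospital
  - tumor hospital
  - oncology hospital
  - mental health hospital
  - psychiatric hospital
  - infectious disease hospital
  - traditional chinese medicine hospital
disease prevention institution:
  - disease prevention institution
  - disease control center
  - cdc
  - center for disease control
first aid center:
  - first aid center
  - emergency center
  - emergency rescue center
rural hospital:
  - rural hospital
  - township hospital
  - township health center
  - community health station
clinic:
  - clinic
  - outpatient department
pharmacy:
  - pharmacy
  - drugstore
  - dispensary
animal medical:
  - animal medical
  - animal hospital
  - veterinary clinic
  - veterinary hospital
  - pet hospital
  - pet clinic
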