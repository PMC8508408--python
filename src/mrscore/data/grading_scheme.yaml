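# Default Delphi grading of the 8 canonical institution categories into
# three levels with expert-consensus weights. An alternative elicitation
# outcome (0.5 / 0.3 / 0.2) can be used by editing the weights; weights must
# be positive and sum to 1.
levels:
  1: [3a hospital]
  2: [general hospital, specialized hospital, disease prevention institution,
      first aid center]
  3: [rural hospital, clinic, pharmacy]
weights:
  1: 0.6
  2: 0.3
  3: 0.1
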