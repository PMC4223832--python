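# Gene-name normalization: annotation dialects vary across pipelines.
# Matching is case-insensitive; each key maps an observed name to the
# canonical vocabulary used by the subtype signatures.
aliases:
  cas8e: cse1
  casa: cse1
  casb: cse2
  csd1: cas8c
  cst1-like: cst1
  cas8b: cst1
  cse3: cas6
  cas6e: cas6
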