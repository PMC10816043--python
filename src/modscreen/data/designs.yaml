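# The two analysis designs of the MEN1 modifier screen: positive subgroups
# are all affected members of one family, or one unrelated patient; negatives
# are symptom-free patients aged >= 40, at most one per family.
analyses:
  - name: pituitary
    phenotype: pituitary
    positive_subgroups:
      - [A4, A8]
      - [X5]
      - [X15]
    negatives: [A2, X11, X12]
  - name: adrenocortical
    phenotype: adrenocortical
    positive_subgroups:
      - [A4]
      - [C3, C9]
      - [X11]
      - [X15]
    negatives: [X5, A8, X10, X12]
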