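# Ordered first-match marker rules defining the ten T cell subsets.
# "positive" requires count above the positivity threshold, "zero" requires
# count at or below it.  "ccr7" lists admissible Ccr7 tertile levels
# (low/int/high) and is enforced only in strict mode: every pair of subsets
# already differs in at least one binary marker, so the binary rules are
# total on their own.
version: 1
rules:
  - label: gdT
    positive: [Tcrg-C1, Trdc]
    zero: [Cd4, Cd8a]
  - label: eTreg
    positive: [Cd4, Foxp3, Cd44]
    zero: [Sell]
    ccr7: [low]
  - label: cTreg
    positive: [Cd4, Foxp3]
    zero: []
    ccr7: [low]
  - label: NKT_CD8_Tcm
    positive: [Cd8a, Cd44, Sell, Klrb1c]
    zero: []
    ccr7: [int]
  - label: CD8_Tcm
    positive: [Cd8a, Cd44, Sell]
    zero: []
    ccr7: [int]
  - label: CD8_Tem
    positive: [Cd8a, Cd44]
    zero: [Sell]
    ccr7: [low]
  - label: CD8_naive
    positive: [Cd8a, Sell]
    zero: [Cd44]
    ccr7: [high]
  - label: CD4_Tcm
    positive: [Cd4, Cd44, Sell, Ly6c1]
    zero: []
    ccr7: [high]
  - label: CD4_Tem
    positive: [Cd4, Cd44]
    zero: [Sell]
    ccr7: [low]
  - label: CD4_naive
    positive: [Cd4, Sell]
    zero: [Cd44, Ly6c1]
    ccr7: [high]
default: unassigned
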