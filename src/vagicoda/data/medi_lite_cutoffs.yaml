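# Default MEDI-LITE component cutoffs (g/day unless noted).
#
# Nine components, each scored 0/1/2; total 0-18.  Positive components
# score ascending (below lo -> 0, lo..hi -> 1, >= hi -> 2), negative
# components descending (<= lo -> 2, lo..hi -> 1, > hi -> 0).  Alcohol is
# peaked at moderate intake in alcoholic units (AU, 1 AU = 10 g ethanol):
# below the window scores `below_score` (1 by default, as in the
# published score, so abstainers get 1), inside scores 2, above scores 0.
#
# The bands are the package's operationalization of the published
# serving thresholds, converted to g/day; they are data, not code, and
# fully overridable.
components:
  cereals:
    groups: ["cereals and derived products", "bakery products"]
    kind: positive
    lo: 100
    hi: 250
  legumes:
    groups: ["legumes"]
    kind: positive
    lo: 10
    hi: 25
  fruits:
    groups: ["fruits"]
    kind: positive
    lo: 150
    hi: 300
  vegetables:
    groups: ["vegetables"]
    kind: positive
    lo: 100
    hi: 250
  nuts:
    groups: ["dried fruits and seeds"]
    kind: positive
    lo: 5
    hi: 15
  olive_oil:
    groups: ["olive oil"]
    kind: positive
    lo: 10
    hi: 30
  dairy:
    groups: ["milk and yogurt", "cheese"]
    kind: negative
    lo: 150
    hi: 300
  red_meat:
    groups: ["red and processed meat"]
    kind: negative
    lo: 50
    hi: 100
  alcohol:
    kind: alcohol
    lo: 1.2   # AU/day
    hi: 2.5   # AU/day
    below_score: 1
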