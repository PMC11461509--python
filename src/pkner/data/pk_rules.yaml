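# Default PK entity ruleset.
#
# Schema: each rule has a unique `id`, a `label` (default PK), a `pattern`
# (list of token constraints applied to consecutive tokens) and an optional
# `context` gate.  A token constraint carries exactly one of:
#   text:      exact, case-sensitive token match
#   lower:     case-insensitive token match
#   lower_in:  case-insensitive membership in a list
#   regex:     full-match regular expression on the raw token text
# plus `optional: true` to make the position skippable.  The context gate
# fires the rule only when at least one `require` term (and no `forbid`
# term) appears within `window` tokens on either side of the match.
#
# Overlapping matches are resolved longest-first (ties: leftmost, then
# lowest rule id).  Short acronyms match case-sensitively: lowercase "f",
# "cl" etc. are overwhelmingly non-entities.
version: "1.0"
rules:
  # ---- long forms with complementary modifiers -------------------------
  - id: pk-clearance
    label: PK
    pattern:
      - {lower_in: [total, body, apparent, oral, plasma], optional: true}
      - {lower_in: [total, body, apparent, oral, plasma], optional: true}
      - {lower: clearance}
  - id: pk-volume-of-distribution
    label: PK
    pattern:
      - {lower_in: [apparent, steady-state], optional: true}
      - {lower: volume}
      - {lower: of}
      - {lower: distribution}
  - id: pk-half-life
    label: PK
    pattern:
      - {lower_in: [terminal, elimination, absorption], optional: true}
      - {lower_in: [terminal, elimination, absorption], optional: true}
      - {lower: half-life}
  - id: pk-bioavailability
    label: PK
    pattern:
      - {lower_in: [absolute, oral], optional: true}
      - {lower: bioavailability}
  - id: pk-auc-curve-long
    label: PK
    pattern:
      - {lower: area}
      - {lower: under}
      - {lower: the}
      - {lower: concentration-time}
      - {lower: curve}
  - id: pk-auc-curve
    label: PK
    pattern:
      - {lower: area}
      - {lower: under}
      - {lower: the}
      - {lower: curve}
  - id: pk-rate-constant
    label: PK
    pattern:
      - {lower_in: [elimination, absorption]}
      - {lower: rate}
      - {lower: constant}
  - id: pk-peak-concentration
    label: PK
    pattern:
      - {lower_in: [peak, maximum]}
      - {lower: plasma}
      - {lower: concentration}
  # ---- acronyms (case-sensitive) ---------------------------------------
  - id: pk-acr-cl
    label: PK
    pattern: [{text: CL}]
  - id: pk-acr-cl-f
    label: PK
    pattern: [{text: CL/F}]
  - id: pk-acr-auc
    label: PK
    pattern: [{regex: 'AUC(?:0-(?:[0-9]+|t|inf|∞))?'}]
  - id: pk-acr-cmax
    label: PK
    pattern: [{text: Cmax}]
  - id: pk-acr-tmax
    label: PK
    pattern: [{text: Tmax}]
  - id: pk-acr-thalf
    label: PK
    pattern: [{text: t1/2}]
  - id: pk-acr-vd
    label: PK
    pattern: [{text: Vd}]
  - id: pk-acr-vss
    label: PK
    pattern: [{text: Vss}]
  - id: pk-acr-ka
    label: PK
    pattern: [{text: ka}]
  - id: pk-acr-ke
    label: PK
    pattern: [{text: ke}]
  - id: pk-acr-kel
    label: PK
    pattern: [{text: kel}]
  # ---- context-gated ambiguous acronym ---------------------------------
  - id: pk-acr-f-gated
    label: PK
    pattern: [{text: F}]
    context:
      window: 5
      require: [bioavailability, oral, orally, dose, dosing, dosed,
                administration, administered, fraction, '%']
      forbid: [statistic, ratio, test]
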