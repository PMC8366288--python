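name: demo-medinfo-rules
version: "1"

# Two-level taxonomy: 23 trainable subcategories under 5 root categories.
tree:
  Safety Data: Safety
  Adverse Event Report: Safety
  Contraindication: Safety
  Drug Interaction: Safety
  Pregnancy and Lactation: Safety
  Formulation: Dosage and Formulation
  Dosage and Administration: Dosage and Formulation
  Administration Device: Dosage and Formulation
  Storage and Stability: Dosage and Formulation
  Efficacy: Clinical Evidence
  Real world evidence: Clinical Evidence
  Clinical Trial Information: Clinical Evidence
  Comparative Effectiveness: Clinical Evidence
  Publication Request: Scientific Exchange
  Meeting Request: Scientific Exchange
  Mechanism of Action: Scientific Exchange
  Pharmacokinetics: Scientific Exchange
  Sample Request: Product Support
  Product Complaint: Product Support
  Availability and Supply: Product Support
  Pricing and Reimbursement: Product Support
  Off-label Use: Product Support
  Patient Education: Product Support

fallback: General or Other

relation_config:
  window: 6
  connectives: [of, on, for, with, to, in, about, after, taking, between,
                during, while, by]
  modifier_tokens: [available]
  verb_tokens: [meet, visit, call, contact]

# Lower priority number = higher precedence.
rules:
  - id: pub-request-available-doc
    priority: 10
    label: Publication Request
    conditions:
      - {pred: REL, kind: modifies, a: "token:available", b: "entity:Document"}

  - id: safety-adverse-pair
    priority: 20
    label: Safety Data
    conditions:
      - {pred: REL, kind: modifies, a: "entity:Condition", b: "entity:Treatment"}
      - {pred: KB_PAIR, relation: adverse_effect, type_a: Condition, type_b: Treatment}

  - id: meeting-professional-meet
    priority: 30
    label: Meeting Request
    conditions:
      - {pred: REL, kind: subject, a: "entity:Professional", b: "token:meet"}
  - id: meeting-professional-visit
    priority: 31
    label: Meeting Request
    conditions:
      - {pred: REL, kind: subject, a: "entity:Professional", b: "token:visit"}

  - id: ae-report-side-effect
    priority: 40
    label: Adverse Event Report
    conditions:
      - {pred: LEXICAL, anchor: report}
      - {pred: LEXICAL, anchor: side effect}
  - id: contraindication-anchor
    priority: 41
    label: Contraindication
    conditions:
      - {pred: LEXICAL, anchor: contraindicated}
  - id: interaction-anchor
    priority: 42
    label: Drug Interaction
    conditions:
      - {pred: LEXICAL, anchor: interaction}
      - {pred: ENTITY, type: Treatment}
  - id: pregnancy-anchor
    priority: 43
    label: Pregnancy and Lactation
    conditions:
      - {pred: LEXICAL, anchor: pregnancy}
  - id: lactation-anchor
    priority: 44
    label: Pregnancy and Lactation
    conditions:
      - {pred: LEXICAL, anchor: breastfeeding}

  - id: formulation-anchor
    priority: 45
    label: Formulation
    conditions:
      - {pred: LEXICAL, anchor: formulation}
  - id: formulation-tablet
    priority: 46
    label: Formulation
    conditions:
      - {pred: LEXICAL, anchor: tablet}
  - id: dosage-dose
    priority: 47
    label: Dosage and Administration
    conditions:
      - {pred: LEXICAL, anchor: dose}
      - {pred: ENTITY, type: Treatment}
  - id: dosage-administered
    priority: 48
    label: Dosage and Administration
    conditions:
      - {pred: LEXICAL, anchor: administered}
  - id: device-anchor
    priority: 49
    label: Administration Device
    conditions:
      - {pred: LEXICAL, anchor: device}
  - id: storage-stored
    priority: 50
    label: Storage and Stability
    conditions:
      - {pred: LEXICAL, anchor: stored}
  - id: storage-room-temperature
    priority: 51
    label: Storage and Stability
    conditions:
      - {pred: LEXICAL, anchor: room temperature}

  - id: efficacy-effective
    priority: 52
    label: Efficacy
    conditions:
      - {pred: LEXICAL, anchor: effective}
      - {pred: ENTITY, type: Treatment}
  - id: efficacy-response-rate
    priority: 53
    label: Efficacy
    conditions:
      - {pred: LEXICAL, anchor: response rate}
  - id: rwe-anchor
    priority: 54
    label: Real world evidence
    conditions:
      - {pred: LEXICAL, anchor: real world}
  - id: trial-anchor
    priority: 55
    label: Clinical Trial Information
    conditions:
      - {pred: LEXICAL, anchor: clinical trial}
  - id: comparative-anchor
    priority: 56
    label: Comparative Effectiveness
    conditions:
      - {pred: LEXICAL, anchor: compare}

  - id: moa-anchor
    priority: 57
    label: Mechanism of Action
    conditions:
      - {pred: LEXICAL, anchor: mechanism}
  - id: pk-half-life
    priority: 58
    label: Pharmacokinetics
    conditions:
      - {pred: LEXICAL, anchor: half-life}
  - id: pk-metabolized
    priority: 59
    label: Pharmacokinetics
    conditions:
      - {pred: LEXICAL, anchor: metabolized}

  - id: sample-anchor
    priority: 60
    label: Sample Request
    conditions:
      - {pred: LEXICAL, anchor: samples}
  - id: complaint-anchor
    priority: 61
    label: Product Complaint
    conditions:
      - {pred: LEXICAL, anchor: complaint}
  - id: availability-stock
    priority: 62
    label: Availability and Supply
    conditions:
      - {pred: LEXICAL, anchor: stock}
  - id: availability-supply
    priority: 63
    label: Availability and Supply
    conditions:
      - {pred: LEXICAL, anchor: supply}
  - id: pricing-price
    priority: 64
    label: Pricing and Reimbursement
    conditions:
      - {pred: LEXICAL, anchor: price}
  - id: pricing-reimbursement
    priority: 65
    label: Pricing and Reimbursement
    conditions:
      - {pred: LEXICAL, anchor: reimbursement}
  - id: off-label-anchor
    priority: 66
    label: Off-label Use
    conditions:
      - {pred: LEXICAL, anchor: off label}
  - id: patient-education-anchor
    priority: 67
    label: Patient Education
    conditions:
      - {pred: LEXICAL, anchor: patient education}
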