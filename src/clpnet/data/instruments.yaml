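# Built-in scale definitions.  Users can register additional scales at
# runtime (clpnet.instruments.register_instrument) or load a file of the
# same shape (load_instruments).
#
# Each entry: items (ordered), response_min/response_max (inclusive ordinal
# range), node_labels (short per-item labels used as network node names),
# subscales (named item groupings; every item in at most one subscale).

ITQ:
  description: International Trauma Questionnaire, 12 items, 5-point scale (0-4),
    six two-item dimensions (PTSD re-experiencing, avoidance, sense of threat;
    DSO negative self-concept, affective dysregulation, disturbances in
    relationships).
  items: [itq1, itq2, itq3, itq4, itq5, itq6, itq7, itq8, itq9, itq10, itq11, itq12]
  node_labels: [RE1, RE2, AV1, AV2, TH1, TH2, NSC1, NSC2, AD1, AD2, DR1, DR2]
  response_min: 0
  response_max: 4
  subscales:
    re_experiencing: [itq1, itq2]
    avoidance: [itq3, itq4]
    sense_of_threat: [itq5, itq6]
    negative_self_concept: [itq7, itq8]
    affective_dysregulation: [itq9, itq10]
    disturbed_relationships: [itq11, itq12]

PHQ-9:
  description: Patient Health Questionnaire-9, depressive symptoms over the
    past two weeks, 9 items, 4-point scale (0-3).
  items: [phq1, phq2, phq3, phq4, phq5, phq6, phq7, phq8, phq9]
  node_labels: [dep1, dep2, dep3, dep4, dep5, dep6, dep7, dep8, dep9]
  response_min: 0
  response_max: 3
  subscales: {}

GAD-7:
  description: Generalized Anxiety Disorder questionnaire, 7 items, 4-point
    scale (0-3).
  items: [gad1, gad2, gad3, gad4, gad5, gad6, gad7]
  node_labels: [anx1, anx2, anx3, anx4, anx5, anx6, anx7]
  response_min: 0
  response_max: 3
  subscales: {}

BPBQ-victim:
  description: Bullying Participant Behavior Questionnaire, victim subscale,
    10 items, 5-point frequency scale 0 (never) to 4 (7 or more times).
  items: [bpbq1, bpbq2, bpbq3, bpbq4, bpbq5, bpbq6, bpbq7, bpbq8, bpbq9, bpbq10]
  node_labels: [v1, v2, v3, v4, v5, v6, v7, v8, v9, v10]
  response_min: 0
  response_max: 4
  subscales: {}

Delaware:
  description: Delaware Peer Victimization Scale for retrospective report of
    peer victimization before age 18; 17 items, 6-point frequency scale
    1 (never) to 6 (every day); physical, verbal, relational subscales.
  items: [dpv1, dpv2, dpv3, dpv4, dpv5, dpv6, dpv7, dpv8, dpv9, dpv10, dpv11,
          dpv12, dpv13, dpv14, dpv15, dpv16, dpv17]
  node_labels: [pv1, pv2, pv3, pv4, pv5, pv6, pv7, pv8, pv9, pv10, pv11,
                pv12, pv13, pv14, pv15, pv16, pv17]
  response_min: 1
  response_max: 6
  subscales:
    physical: [dpv1, dpv2, dpv3, dpv4, dpv5, dpv6]
    verbal: [dpv7, dpv8, dpv9, dpv10, dpv11, dpv12]
    relational: [dpv13, dpv14, dpv15, dpv16, dpv17]
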