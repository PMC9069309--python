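# Default diagnostic rule table: 10 disorders, each a conjunction of
# (a) required elements that must all be clinically significant symptoms and
# (b) k-of-set clauses (at least `min_count` symptomatic elements in `elements`).
#
# The table is an editable reconstruction mapping items to the symptom content
# of the corresponding diagnostic criteria; the rule engine, the symptom
# thresholds (rating >= 8 on problem elements, <= 1 on spectrum elements) and
# the k-of-n combinator are the fixed machinery. Duration/timing criteria are
# deliberately out of scope: the instrument measures current perception only.
rules:
  - disorder: depression
    required: [sadness]
    clauses:
      - min_count: 5
        elements: [sadness, guilt_blame, suicidal_thoughts, motivation, energy,
                   sleep_quality, appetite, focus, self_worth]
  - disorder: anxiety
    required: [anxiety_worry]
    clauses:
      - min_count: 3
        elements: [restlessness, fear, focus, sleep_quality, somatic, stability]
  - disorder: bipolar_disorder
    required: []
    clauses:
      - min_count: 2
        elements: [mood_swings, restlessness, self_control]
      - min_count: 2
        elements: [sadness, energy, sleep_quality]
  - disorder: adhd
    required: []
    clauses:
      - min_count: 4
        elements: [focus, restlessness, planning, self_control, decision_making, memory]
  - disorder: ptsd
    required: [trauma_flashbacks]
    clauses:
      - min_count: 3
        elements: [nightmares, avoidance, anxiety_worry, emotional_control,
                   sleep_quality, anger]
  - disorder: ocd
    required: [repetitive_thoughts, compulsions]
    clauses:
      - min_count: 2
        elements: [anxiety_worry, fear, self_control]
  - disorder: addiction
    required: [addiction_cravings]
    clauses:
      - min_count: 3
        elements: [self_control, decision_making, guilt_blame, relationships, motivation]
  - disorder: schizophrenia
    required: []
    clauses:
      - min_count: 1
        elements: [hallucinations, dissociation]
      - min_count: 3
        elements: [speech, social_interaction, motivation, emotional_control,
                   repetitive_thoughts]
  - disorder: eating_disorder
    required: [disordered_eating]
    clauses:
      - min_count: 3
        elements: [self_image, self_worth, appetite, guilt_blame, anxiety_worry]
  - disorder: autism_spectrum_disorder
    required: []
    clauses:
      - min_count: 4
        elements: [social_interaction, empathy, speech, sensory, adaptability, compulsions]
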