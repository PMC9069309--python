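# Default item bank: 47 elements, 27 spectrum + 20 problem.
#
# Spectrum elements span positive-to-negative mental function (a rating of 9
# is the healthy pole); problem elements are pure detractions (a rating of 9
# is the unhealthy pole). `seriousness` drives the nonlinear weighting in the
# score transform; `related_group` tags semantically related items that share
# an extra latent factor in the synthetic generator and are used by the
# internal-consistency checks.
elements:
  # --- spectrum (27) ---
  - {element_id: adaptability,      label: "Adaptability to change",              format: spectrum, seriousness: mild}
  - {element_id: emotional_control, label: "Emotional control",                   format: spectrum, seriousness: moderate}
  - {element_id: self_image,        label: "Self-image",                          format: spectrum, seriousness: moderate, related_group: self_regard}
  - {element_id: self_worth,        label: "Self-worth & confidence",             format: spectrum, seriousness: moderate, related_group: self_regard}
  - {element_id: outlook,           label: "Outlook & optimism",                  format: spectrum, seriousness: mild}
  - {element_id: motivation,        label: "Drive & motivation",                  format: spectrum, seriousness: moderate}
  - {element_id: focus,             label: "Focus & concentration",               format: spectrum, seriousness: moderate}
  - {element_id: planning,          label: "Planning & organisation",             format: spectrum, seriousness: mild}
  - {element_id: decision_making,   label: "Decision-making",                     format: spectrum, seriousness: mild}
  - {element_id: memory,            label: "Memory",                              format: spectrum, seriousness: mild}
  - {element_id: learning,          label: "Ability to learn new things",         format: spectrum, seriousness: mild}
  - {element_id: creativity,        label: "Creativity & problem-solving",        format: spectrum, seriousness: mild}
  - {element_id: speech,            label: "Speech & language",                   format: spectrum, seriousness: mild}
  - {element_id: coordination,      label: "Coordination",                        format: spectrum, seriousness: mild}
  - {element_id: sleep_quality,     label: "Sleep quality",                       format: spectrum, seriousness: moderate, related_group: sleep}
  - {element_id: appetite,          label: "Appetite regulation",                 format: spectrum, seriousness: mild}
  - {element_id: energy,            label: "Energy level",                        format: spectrum, seriousness: moderate}
  - {element_id: physical_intimacy, label: "Physical intimacy",                   format: spectrum, seriousness: mild}
  - {element_id: relationships,     label: "Relationships with others",           format: spectrum, seriousness: moderate}
  - {element_id: social_interaction, label: "Social interaction & cooperation",   format: spectrum, seriousness: mild}
  - {element_id: empathy,           label: "Empathy",                             format: spectrum, seriousness: mild}
  - {element_id: resilience,        label: "Emotional resilience",                format: spectrum, seriousness: moderate}
  - {element_id: self_control,      label: "Self-control & impulsivity",          format: spectrum, seriousness: moderate}
  - {element_id: curiosity,         label: "Curiosity & interest",                format: spectrum, seriousness: mild}
  - {element_id: sensory,           label: "Sensory sensitivity",                 format: spectrum, seriousness: mild}
  - {element_id: stability,         label: "Stability & calmness",                format: spectrum, seriousness: moderate}
  - {element_id: purpose,           label: "Sense of purpose",                    format: spectrum, seriousness: mild}
  # --- problem (20) ---
  - {element_id: sadness,           label: "Feelings of sadness, distress or hopelessness", format: problem, seriousness: moderate, related_group: mood}
  - {element_id: anxiety_worry,     label: "Feelings of anxiety, worry or panic", format: problem, seriousness: moderate}
  - {element_id: avoidance,         label: "Avoidance & withdrawal",              format: problem, seriousness: moderate}
  - {element_id: mood_swings,       label: "Extreme mood swings",                 format: problem, seriousness: moderate}
  - {element_id: anger,             label: "Anger & irritability",                format: problem, seriousness: mild}
  - {element_id: repetitive_thoughts, label: "Strange, unwanted or obsessive thoughts", format: problem, seriousness: moderate}
  - {element_id: compulsions,       label: "Repetitive or compulsive actions",    format: problem, seriousness: moderate}
  - {element_id: fear,              label: "Unexplained fears & phobias",         format: problem, seriousness: mild}
  - {element_id: trauma_flashbacks, label: "Traumatic flashbacks",                format: problem, seriousness: moderate}
  - {element_id: nightmares,        label: "Nightmares",                          format: problem, seriousness: mild}
  - {element_id: guilt_blame,       label: "Guilt & self-blame",                  format: problem, seriousness: moderate}
  - {element_id: self_harm,         label: "Self-harm",                           format: problem, seriousness: severe}
  - {element_id: suicidal_thoughts, label: "Suicidal thoughts or intentions",     format: problem, seriousness: severe}
  - {element_id: hallucinations,    label: "Hallucinations",                      format: problem, seriousness: severe}
  - {element_id: dissociation,      label: "Sense of detachment from reality",    format: problem, seriousness: severe}
  - {element_id: addiction_cravings, label: "Cravings & addictions",              format: problem, seriousness: moderate}
  - {element_id: disordered_eating, label: "Binge or restrictive eating",         format: problem, seriousness: moderate}
  - {element_id: aggression,        label: "Aggression towards others",           format: problem, seriousness: mild}
  - {element_id: restlessness,      label: "Restlessness & hyperactivity",        format: problem, seriousness: mild}
  - {element_id: somatic,           label: "Unexplained physical aches & pains",  format: problem, seriousness: mild}
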