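# Roster CSV schema

One row per assessment attempt; UTF-8, comma-separated, header row,
RFC-4180 quoting. Respondent ids may repeat (retakes).

## Metadata columns

| column | type | values |
| --- | --- | --- |
| respondent_id | string | opaque anonymized id |
| attempt_day | int | day offset of the attempt (day resolution is all the retest gap rule needs) |
| age | int | years, 18-85 |
| gender | string | `female`, `male`, `nonbinary` |
| country | string | survey country name |
| employment_status | string | `employed`, `homemaker`, `unemployed`, `retired`, `studying`, `not_able_to_work` |
| easy_to_understand | bool | answer to "Did you find this assessment easy to understand?"; rows with `False` are excluded from all analyses |
| sleep_sufficiency | string | `all the time`, `most of the time`, `some of the time`, `hardly ever` (recoded 7/5/3/1 for the consistency battery) |
| current_mood | int | 1-9, very negative to very positive |

## Rating columns

One integer column (1-9) per element id of the bank, in bank order — 27
spectrum then 20 problem elements; ids and labels in
`src/mhq/data/elements.yaml`.

## Auxiliary files

- `probes.csv`: `respondent_id`, `life_impact` (5-9), `frequency` (0-7
  days last week), `severity` (1-5).
- `productivity.csv`: `respondent_id`, `days_missed` (0-31),
  `reduced_days` (0-31).
- `retests.csv`: same schema as the cohort roster (second attempts).
- Scored output: `respondent_id`, `mhq_score`, `category`.
- Diagnoses output: `respondent_id`, one boolean column per disorder,
  `n_symptoms`, `n_disorders`, `any_disorder`.
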