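# Data dictionary

All files are plain CSV with a header row; ages are integer days since
birth; heights are cm; times are minutes.

## cohort.csv (synthetic_cohort / `labgrowth simulate`)
| column | meaning |
|---|---|
| dog_id | dog identifier, stable across cohort sizes for a given seed |
| sex | `female` or `male` |
| age_days | age at the visit |
| height_recorded_cm | stored height as the database would hold it (unit errors included) |
| household_type | `family`, `more_than_one_adult`, `retired`, `single_adult`, `not_reported` |

## truth.csv
| column | meaning |
|---|---|
| dog_id, age_days | as above |
| class_label | true unit-error class: `cm2in`, `ok`, `in2cm` |
| true_height_cm | expected true height mu(age) before noise and distortion |

## posterior.csv
One row per retained MCMC iteration and sex: `sex, iteration, a, b, c,
tau, sd, pi_cm2in, pi_ok, pi_in2cm`.

## posterior_summary.csv
Posterior mean and central 95% credible interval per parameter and sex.

## class_posteriors.csv
| column | meaning |
|---|---|
| dog_id, age_days | observation key |
| p_cm2in, p_ok, p_in2cm | posterior class-membership frequencies (rows sum to 1) |
| assigned_class | class after the tie/threshold rules |

## heights_corrected.csv
Input observation columns plus `class_label`, `multiplier_applied`
(1/2.54, 1 or 2.54) and `height_corrected_cm = height_recorded_cm x
multiplier_applied`.

## exercise_tde.csv
`dog_id, age_days`, one `{activity}_weekday` and `{activity}_weekend` bin
label per activity (`on_lead`, `off_lead`, `fetching`, `other`),
`restriction`, then the derived `tde_min` and `ttde`.

## follow_up.csv
`dog_id, age_at_last_entry_days, days_since_last_entry` — the columns the
assumed-loss rule and a survival fit consume.

## stats.json / manifest.json
Run-level summaries (retention rate, TDE summary, filter and misreport
counts) and the reproducibility manifest (seed, config digest, SHA-256 of
every output).
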