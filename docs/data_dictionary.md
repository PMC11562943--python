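# Cohort CSV data dictionary

One row per treatment episode.  Empty string encodes a missing value.

| column | type | values / units |
|---|---|---|
| `client_id` | string | opaque identifier, unique per episode |
| `age_at_admission` | float | years |
| `sex` | string | `male`, `female` |
| `employment` | string | `employed`, `not_employed`, empty = missing |
| `living_arrangement` | string | `by_self`, `with_children`, `with_non_family`, `with_other_relatives`, `with_parents`, `with_spouse_partner`, `with_spouse_partner_roommate`, empty = missing |
| `instability_q` | int | residential-instability quintile 1–5, empty = missing |
| `deprivation_q` | int | material-deprivation quintile 1–5, empty = missing |
| `dependency_q` | int | dependency quintile 1–5, empty = missing |
| `ethnic_concentration_q` | int | ethnic-concentration quintile 1–5, empty = missing |
| `modality` | string | `HICBT`, `stepped`, `LICBT` (initial intensity stream) |
| `delivery_format` | string | `individual`, `group`, `ecbt`; drives the completion window (98 days for eCBT, 147 otherwise); empty = infer from modality |
| `admission_date` | date | ISO `YYYY-MM-DD` |
| `phq9_scores` | string | `;`-separated `date=score` pairs, date-sorted, scores 0–27 |
| `gad7_scores` | string | `;`-separated `date=score` pairs, date-sorted, scores 0–21 |

# Ground-truth CSV (synthetic cohorts only)

| column | type | meaning |
|---|---|---|
| `client_id` | string | matches the cohort CSV |
| `expected_change_phq9` | float | latent mean first-minus-last PHQ-9 decrease (linear predictor) |
| `expected_change_gad7` | float | latent mean GAD-7 decrease |
| `true_rcsi_phq9` | 0/1 | RCSI rule applied to the realised PHQ-9 score pair |
| `true_rcsi_gad7` | 0/1 | RCSI rule applied to the realised GAD-7 score pair |
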