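# Table schemas

All interchange files are tab-separated with a header row. Angles are degrees
counter-clockwise from the positive x-axis, screen center origin, y up, stored
in [0, 360); amplitudes are degrees of visual angle (°va).

## trials.tsv (raw or annotated trial table)

| column | type | meaning |
|---|---|---|
| study_id | str | study key |
| participant_id | str | participant key, unique across studies |
| trial | int | trial index within participant |
| target_angle_deg | float | target angle mu, never on a cardinal axis |
| target_amp_dva | float | target amplitude, constant per participant |
| response_angle_deg | float | response angle |
| response_amp_dva | float | response amplitude |
| is_injected_outlier | bool | generator flag (synthetic cohorts only) |

Annotation (`compute_trial_errors`) adds: `angular_error` (signed, (-180, 180],
positive = counter-clockwise), `amplitude_ratio`, `quadrant` (1-4),
`prototype_angle` (45/135/225/315), `response_quadrant` (0 when the response
sits on a cardinal axis), `boundary_distance`.

## filter_report.json

`n_input`, `n_kept`, `n_excluded`, `rule_counts` per rule
(`angular_error_gt_max`, `amplitude_ratio_out_of_range`,
`response_outside_target_quadrant`), `mean_exclusion_pct`, and
`per_participant` records with `n_input` / `n_excluded` / `exclusion_pct`.

## bias_by_angle.tsv

`study_id?`, `target_angle_deg`, `n_trials`, `mean_bias_toward_prototype`
(degrees, positive = toward the quadrant diagonal), `mean_angular_error`.

## behavioral_measures.tsv

`study_id`, `participant_id`, `memory_inexactness` (posterior mean sigma_M,
degrees), `prototype_bias` (1 - posterior mean lambda, unitless in (0,1)).

## activity.tsv (BetaTable)

`participant_id`, `study_id`, `network` (or `unit` for region-level tables),
`phase` (encoding/delay/response/cue), `beta` (arbitrary BOLD units; the
association stage standardizes).

## cam_draws.tsv

Long-format posterior draws: `parameter`, `chain`, `iteration`, `value`,
`study_id`. Per-participant parameters are named `sigma_m[<participant_id>]`,
`sigma_p[...]`, `lambda[...]`; `nu` is shared per study.

## brain_behavior_summary.tsv

`network`, `phase`, `coefficient` (`b_inexactness` / `b_bias`), `mean`,
`ci_low`, `ci_high` (95% posterior interval), `p_positive`, `p_negative`
(posterior sign probabilities), `predictor_correlation`.

## power_curve.tsv / power_stability.tsv

`size`, `coefficient`, `power`, `est_mean`, `ci_low`, `ci_hi`
(across-resample 2.5/97.5 percentiles of posterior-mean estimates),
`n_failed_fits`, `valid`; stability: `coefficient`, `smallest_stable_n`
(integer or `not reached`).

## GLM inputs (per participant, in `bold_dir`)

`<pid>_bold.tsv` (frames x regions, header = region names),
`<pid>_events.tsv` (`trial_index`, `phase`, `onset` s, `duration` s,
`is_outlier_trial`), optional `<pid>_motion.tsv` (6 columns), and
`<pid>_meta.json` (`participant_id`, `study_id`, `tr`).
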