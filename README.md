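# ecoassess

Ecological autonomy assessment from tracked-person streams.

The package re-implements a video-based assessment pipeline for instrumental
activities of daily living (IADL) and walking tasks, starting from tracked
person streams (per-frame floor-plane position, posture and foot coordinates)
rather than raw video:

* **events** — constraint-based recognition: primitive states (zone
  occupancy, posture) and composite activity models (overlap +
  minimum-duration constraints, evaluated on the frame grid with half-open
  intervals), plus interval-matching precision/recall evaluation.
* **gait** — step detection from the inter-feet distance signal and
  kinematic parameters (duration, cadence, step-length statistics, stride,
  distance, speed, tracking-gap duration) for the single and dual walking
  tasks.
* **profiles** — behavioral profiles: per-activity frequency, duration,
  omissions and repetitions against the 13-unit protocol, and autonomy
  staging (completed ≥ 8 → good, 4–7 → intermediate, < 4 → poor).
* **classify** — Gaussian Naive Bayes (log-space posteriors, variance
  floor), stratified 20-fold cross-validation, and forward best-first
  wrapper feature selection; the published autonomy and diagnosis feature
  lists ship as defaults.
* **simulate** — a synthetic scene simulator standing in for the original
  recordings: per-class schedules calibrated to the published cohort
  statistics, rendered to track streams with configurable dropout/jitter
  noise and exact ground-truth event intervals.
* **stats** — Mann-Whitney U (midranks, tie-corrected normal approximation
  with continuity correction, exact p for small untied samples) and Spearman
  correlations, with batch table output.
* **pipeline / cli** — end-to-end runner with a hashed artifact manifest.

## CLI

```sh
# full pipeline: simulate -> recognize -> gait -> profile -> classify
#                -> evaluate -> stats
ecoassess run-all --seed 42 --out-dir runs/demo

# individual stages
ecoassess simulate  --seed 7 --out-dir cohort --dropout 0.05 --jitter 0.05
ecoassess recognize --tracks cohort/tracks/p001.csv --out p001_events.csv
ecoassess gait      --tracks cohort/tracks/p001.csv --events p001_events.csv --out p001_gait.csv
ecoassess classify  --profiles runs/demo/profiles.csv --task autonomy \
                    --folds 20 --seed 0 --features paper --out cls.json
ecoassess evaluate  --recognized runs/demo/recognized_events.csv \
                    --truth runs/demo/gt_events.csv --out eval.csv
ecoassess stats     --profiles runs/demo/profiles.csv --out-dir stats/
ecoassess roundtrip cohort/tracks/p001.csv --kind tracks
```

All commands accept `--seed`; two runs with the same configuration produce
byte-identical artifacts.  Exit codes: 0 success, 1 validation error, 2 stage
failure.

## File formats

* tracks: CSV `t,person_present,x,y,posture,lfx,lfy,rfx,rfy`, one row per
  frame, empty spatial cells when absent;
* zones: JSON `[{"name", "polygon": [[x, y], ...]}]` in meters;
* event models: JSON `{"name", "components": {alias: state}, "constraints":
  [{"kind", "args"}]}`;
* events: CSV `model_name,t_start,t_end` (plus `participant_id` for cohort
  files);
* profiles: one CSV row per participant, columns named after the published
  feature lists (e.g. `person_using_pharmacybasket_frequency_of_event`).
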