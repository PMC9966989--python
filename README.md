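# mhckit

Analysis pipeline for relating **minor health complaints (MHCs)** — mild,
subjectively perceived psychosomatic disturbances measured with the 29-item
stress-reaction block of the Brief Job Stress Questionnaire (BJSQ) — to daily
dietary nutrient intake.

Because the originating survey data are embargoed, the package ships a
first-class synthetic-cohort generator with the statistical structure the
analysis assumes (five correlated latent traits driving graded ordinal item
responses; log-normal nutrient intakes with configurable planted effects and a
shared diet-quality factor), so the whole pipeline is testable end to end.

## Pipeline stages

1. **Cohort filter** (`mhckit.bjsq`) — excludes non-workers and subjects with
   high stress reactions in both seasons (887 → 794 on the reference flow).
2. **Recode** — 4-point responses dichotomized 0-0-1-1 (1-1-0-0 for the
   reversed vigor items Q01–Q03), so 1 always encodes the unfavourable pole.
3. **Factor structure** (`mhckit.factor_analysis`) — KMO sampling adequacy,
   scree/parallel-analysis/MAP factor counts, maximum-likelihood EFA with
   direct-Oblimin (quartimin) rotation, threshold-based item assignment, and a
   confirmatory fit reporting CFI / TLI / SRMR.
4. **IRT** (`mhckit.irt`) — per-factor two-parameter logistic model fit by
   Bock–Aitkin marginal-ML EM; factor-level averaged response curves and their
   0.5-probability thresholds order complaints by the disorder level at which
   they appear (vigor loss earliest, anxiety + depression last).
5. **MHC scores & median split** (`mhckit.mhc`) — four fixed item-sum scores
   (lack of vigor Q01–Q03, irritability Q04–Q06, fatigue Q07–Q09, somatic
   Q19–Q26 + Q28), each split at its cohort median (≤ median = "low").
6. **Nutrient screen** (`mhckit.nutrient_screen`) — Mann-Whitney comparison of
   39 nutrients across the four splits, selection of nutrients significant in
   ≥ 3 of 4 items at raw α = 0.05, cut-off derivation from the feasible
   interval between worse- and better-status subgroup means (default rule:
   midpoint rounded to two significant figures, with override support and
   violation reporting), per-subject counting of nutrients consumed at or
   above cut-off, and comparison of MHC levels across the 0N / 1–4N / 5–8N /
   9–12N / 13–17N count groups.

Reference fixtures (the published pattern matrix, subgroup-mean table, and
age distribution) ship as CSVs under `src/mhckit/data/`.

## CLI

```bash
mhc demo --out demo_run --seed 0          # synthetic cohort + full pipeline
mhc simulate --n 887 --seed 0 --out data/ # cohort CSVs only
mhc bjsq score --in data/bjsq.csv --out scores.csv
mhc bjsq recode --in data/bjsq.csv --out binary.csv
mhc factors count --in binary.csv
mhc factors efa --in binary.csv --k 5 --out pattern.csv
mhc irt fit --in binary.csv --out params.csv
mhc mhc score --in data/bjsq.csv --out mhc_scores.csv
mhc mhc split --in mhc_scores.csv --out splits.csv
mhc screen run --intakes data/nutrients.csv --splits splits.csv \
    --scores mhc_scores.csv --out screen_out/
mhc run --config pipeline.yaml            # full pipeline from YAML
```

Pipeline configuration is a flat YAML file mirroring
`mhckit.interface.PipelineConfig`; unknown keys are rejected by name. Every
run writes a `manifest.json` with per-stage row counts, warnings, and SHA-256
checksums of all outputs (reruns with the same config are byte-identical).

## Notes

- The severity-grading boundary tables (A–E) of the official stress-check
  manual are not public; the package ships calibrated, editable defaults and
  no downstream stage depends on grades.
- No multiple-testing correction is applied in the screen by default
  (matching the source procedure); `screen(..., fdr=True)` enables
  Benjamini–Hochberg.
- Several published cut-offs are inconsistent with any single separation rule
  applied to the published subgroup means (e.g. iron 8.1 vs a somatic
  worse-group mean of 8.16); the tools report such violations instead of
  silently adjusting them, and the CLI accepts a cut-off override file.
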