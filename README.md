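# normdev

Age-normative modelling of regional brain morphometry. Given a cohort
table (demographics + QC covariates) and a subjects × regions matrix of a
morphometric such as cortical thickness, `normdev`:

- estimates **age norms** per region from the control group: a LOESS mean
  trajectory (span chosen per region by bounded scalar minimization of a
  cross-validated SSE) tabulated into one-year age bins as (mean, SD, n),
  dropping bins with fewer than five controls or near-zero SD;
- converts individual values into **w-scores** — age-normed deviation
  scores `(value − bin mean) / bin SD` — with an empirical **centile**
  cross-check and a with-replacement **bootstrap** reliability p-value per
  subject × region;
- characterizes **atypicality**: region-wise outlier flags (|w| > 2),
  per-region prevalence maps, a one-sample proportion chi-square (with and
  without Yates continuity correction), per-subject global deviation
  ratios gW / gW⁺ / gW⁻ and outlier age summaries;
- contrasts normative inference with conventional **case-control
  inference**: region-wise linear mixed models (random site intercept)
  with and without region-wise outlier removal, one-sample w-score tests,
  Spearman brain–behaviour maps with a joint BH-FDR family, and a-priori
  power calculations (minimum detectable d and r);
- ships a seeded **synthetic cohort generator** (nonlinear age
  trajectories, site offsets, heteroscedastic noise, planted region-wise
  outliers, globally-thin subjects, coupled phenotypes) with ground truth,
  so the whole pipeline is testable without external data.

## CLI

```sh
normdev simulate --out sim/ --n-control 500 --n-case 500 --seed 1
normdev fit-norms --cohort sim/cohort.csv --morph sim/morphometry.csv \
    --out model/ --sex all --sse-mode cv
normdev score --cohort sim/cohort.csv --morph sim/morphometry.csv \
    --model model/ --out wscores.csv
normdev atypicality --wscores wscores.csv --cohort sim/cohort.csv --out atyp/
normdev case-control --cohort sim/cohort.csv --morph sim/morphometry.csv \
    --wscores wscores.csv --out stats.csv
normdev wscore-tests --wscores wscores.csv --cohort sim/cohort.csv --out w_stats.csv
normdev behaviour --wscores wscores.csv --phenotypes pheno.csv --out rho.csv
normdev bootstrap --cohort sim/cohort.csv --morph sim/morphometry.csv \
    -B 1000 --seed 1 --out boot_p.csv
normdev power --n 870 --alpha 0.005 --power 0.80 --kind d
normdev run --out run/ --seed 1        # full simulate→norms→score→stats pipeline
```

`normdev run` accepts a YAML config (see `normdev.pipeline.RunConfig`) and
writes every stage output plus a manifest (seed, input hashes, timings)
under the output directory; reruns with the same config and seed are
byte-identical.

All tables are plain delimited text: the cohort CSV needs columns
`subject_id, group (case|control), sex (male|female), age, site` and
optionally `motion_fd, euler`; the morphometry CSV has `subject_id` plus
one numeric column per region.

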