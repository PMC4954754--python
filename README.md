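# uprtriage

Staged high-throughput-screening triage and quantification pipeline for
discovering small molecules that preferentially activate the ATF6 arm of the
unfolded protein response (UPR). The package implements, as reusable and
tested components:

- **plate_qc** — percent-of-control normalization against in-plate control
  medians, Z′-factor and signal/background plate quality control;
- **triage** — the three-tier hit-calling funnel: primary cutoff (default
  25.1%, strict), blacklist removal, confirmation at mean + 3 SD of DMSO,
  stringency re-application, and dual-reporter (ERSE vs XBP1) 2-fold
  selectivity;
- **expression** — reference(Tg)-normalized geneset activation scores
  (100·log fc / log fc_ref over genes the reference induces >1.5-fold),
  UPR-profile classification (global / preferential ATF6 / weak),
  differential expression with Benjamini–Hochberg correction, RPKM, and
  Ward/Euclidean hierarchical clustering;
- **imaging** — per-cell nuclear:ER ratio quantification with an adaptive
  per-plate activation threshold (lowest histogram bin above ratio 1 where
  stressed cells outnumber vehicle cells) and vehicle mean + 3 SD hit calls;
- **kinetics** — pulse-chase fraction secreted/remaining, CHX-chase
  fractions, vehicle normalization, four-parameter-logistic dose-response
  fitting (EC50) and two-compartment rate recovery;
- **synthetic** — seeded generators for every input table with planted
  ground truth (compound classes, geneset effects, activated-cell
  fractions, kinetic rates). All generator distributions are explicit
  stand-ins chosen for analytic checkability; no raw-data distributions are
  published for the assays being modelled;
- **pipeline** — one-config, one-seed orchestration of all stages with a
  consolidated JSON + Markdown report and a triage×expression crosswalk
  ranking.

## CLI

Every stage is a subcommand of `upr-triage`; stages exchange plain CSV/TSV/
JSON tables and can be chained:

```sh
upr-triage simulate screen --seed 1 --out sim/            # raw plate CSVs + truth
upr-triage qc --plates sim/plates_primary.csv --out qc/   # % activation + Z′ report
upr-triage triage --primary qc_primary/activations.csv \
    --confirm qc_confirm/activations.csv \
    --counter qc_counter/activations.csv \
    --blacklist ids.txt --out triage/
upr-triage genescore --expr expr.tsv --genesets sets.tsv --reference Tg --out scores/
upr-triage imaging --cells cells.csv --stressor-label Tg --vehicle-label vehicle --out img/
upr-triage kinetics fractions --chase chase.csv --vehicle vehicle --out kin/
upr-triage kinetics ec50 --dr dose_response.csv --out fit/
upr-triage run --config run.yaml --out run/               # full pipeline, one seed
```

`upr-triage run` accepts a YAML config (seed, stage list, screen geometry,
all thresholds); identical config + seed produces byte-identical reports.

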