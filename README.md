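# hfnet

Biomarker–physiology network analysis for heart-failure case–control
cohorts: a tested, reusable implementation of a systems-level pipeline
linking a 92-factor circulating-biomarker panel to myocardial function,
physical capacity, daily physical activity, and mortality — together with a
synthetic-cohort generator that reproduces the statistical structure the
analysis assumes, so every stage is testable without any data download.

## What's inside

| Module | Role |
| --- | --- |
| `hfnet.cohortsim` | Synthetic case–control cohorts: 3-block correlated log-normal biomarkers, a 14-variable physiological block driven by three latent factors, Weibull proportional-hazards survival, day-structured accelerometer traces, planted ground truth for recovery tests |
| `hfnet.accelerometry` | 60-s epoch integration, Troiano-style non-wear detection (60-min zero runs, ≤2 interruption minutes of 1–99 cpm), wear-time activity summaries with cpm skewness and the <3-wear-day exclusion |
| `hfnet.preprocess` | Unit-variance scaling, Cockcroft–Gault clearance, Bland–Altman agreement, Welch-t screening of log2 markers with Benjamini–Hochberg FDR, correlation structure with a k=3 average-linkage cut, cohort description tables |
| `hfnet.oplsda` | From-scratch two-class OPLS-DA: predictive + orthogonal components, stratified k-fold Q², VIP (`sum(VIP²) = p` exactly), subject-bootstrap loading CIs, classification |
| `hfnet.pca_summary` | Correlation-matrix PCA, per-category PC1/PC2 summary scores oriented so higher = better function, median-split quadrant risk groups |
| `hfnet.mi_network` | Rank-binned plug-in mutual information (exactly invariant to monotone transforms), seeded permutation tests, BH across pairs, ARACNE-style DPI triangle pruning, bootstrap `|r| > 0.2` & FDR < 5% retention, hub/connectivity reports, GraphML + TSV export |
| `hfnet.survival` | Newton–Raphson Cox fitting with Efron ties and step-halving, per-quartile hazard-ratio tables (crude + adjusted for age/eGFR/VO2peak/LVEF), Kaplan–Meier with Greenwood CIs, PC-score and quadrant risk contrasts |
| `hfnet.pipeline` / `hfnet.cli` | End-to-end orchestration with YAML config, SHA-256 manifests, and deterministic per-stage seed fan-out |

## CLI

```bash
hfnet simulate --out cohort_dir --seed 1 --traces     # cohort TSV + ground truth + epoch CSVs
hfnet validate cohort_dir/cohort.tsv                  # structural checks, exit 1 on findings
hfnet accel-qc cohort_dir/traces/*.csv --out activity.tsv
hfnet screen cohort_dir/cohort.tsv --out screen.tsv --fdr 0.05
hfnet run-all --out run_dir --seed 1                  # simulate -> screen -> OPLS -> PCA -> network -> survival
```

`run-all` accepts a YAML config (`--config`) exposing every threshold
(FDR, |r|, VIP, active-cpm, wear days, DPI tolerance, permutation and
bootstrap counts); a fixed master seed makes every stage byte-reproducible
(per-stage child seeds are derived by stable hashing).

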