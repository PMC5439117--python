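# gcnaclass

Molecular re-classification of diffuse gliomas from copy-number and
mutation data, as a tested, end-to-end pipeline:

- **Copy-number event calling** from GISTIC2.0-style gene-score matrices
  (±0.5 broad thresholds) or from per-sample segment tables
  (per-sample baseline correction, length-weighted region medians, ±0.1
  broad thresholds), with focal amplification / homozygous-deletion
  calls at ±0.6 — all boundary values call inclusively.
- **1p/19q codeletion detection** (whole-arm loss of both 1p and 19q)
  and whole-chromosome gain/loss flags over a GRCh37 region map.
- **Classical (Torgerson) MDS** of the binary-mutation / ternary-CNA
  alteration matrix, with per-sample alteration-burden weights.
- **Three-way cluster assignment** from IDH1/2 mutation status and
  1p/19q codeletion, plus canonical integrated diagnostic labels
  (oligodendroglial IDH-mutant codeleted / astrocytic IDH-mutant /
  astrocytic IDH-wildtype).
- **Prognostic CNA subtypes** W1–W4 (IDH-wildtype: chromosome 1 gain,
  chromosome 19 gain, CDK4/MDM2 co-amplification) and M1–M3
  (IDH-mutant: CDK4 amplification, CDKN2A homozygous deletion,
  chromosome 14 gain), driven by declarative, ordered rule tables that
  can be overridden from YAML; plus the A/B/C wildtype subgrouping
  (chr1 gain or TP53 → A; chr19 gain → B; else C).
- **Survival analysis**: Kaplan–Meier product-limit estimation and Cox
  proportional-hazards regression (Newton–Raphson, Efron/Breslow ties)
  implemented in-package, with group comparisons, the age-45
  dichotomized analysis, and the merged-subtype (M1/2 vs M3) model with
  WHO-grade adjustment.
- **Cross-cohort validation**: merging of statistically
  indistinguishable subtypes, baseline-normalized median OS, and
  cross-cohort OLS regression of normalized values.
- **Synthetic cohort generator** emitting all four input tables plus a
  ground-truth table, so the full pipeline is testable without external
  data.  With `noise_sd=0` the pipeline recovers every generated
  cluster and subtype label exactly.

## CLI

All subcommands share `--config FILE` (YAML/JSON; defaults hold all
thresholds, rule tables and generator parameters), `--seed INT`,
`--out DIR` and `--log-level`.

```sh
gcnaclass simulate --seed 7 --out sim/
gcnaclass call-cna --gistic sim/gistic.tsv --mutations sim/mutations.tsv --out calls/
gcnaclass classify --gistic sim/gistic.tsv --mutations sim/mutations.tsv \
    --clinical sim/clinical.tsv --out clusters/
gcnaclass subtype --clusters clusters/clusters.tsv --gistic sim/gistic.tsv \
    --mutations sim/mutations.tsv --out subtypes/
gcnaclass embed --gistic sim/gistic.tsv --mutations sim/mutations.tsv --k 2 --out emb/
gcnaclass survive --clinical sim/clinical.tsv --groups subtypes/subtypes.tsv \
    --group-col subtype --age-cutoff 45 --out surv/
gcnaclass validate --cohort-a survA.tsv --cohort-b survB.tsv --baseline W1 --out val/
```

Outputs are deterministic TSVs (per-sample tables sorted by sample ID)
plus a `manifest.json` recording config, seed and version; a rerun with
the same seed and config is byte-identical.

## Conventions

- Segment coordinates are 1-based inclusive, GRCh37; `chrN` and `N`
  chromosome spellings are both accepted and normalized.
- Mutation tables accept MAF-style headers (`Tumor_Sample_Barcode`,
  `Hugo_Symbol`) as synonyms.
- Missing clinical fields are empty strings in TSV and typed-missing
  internally; records without OS are excluded from survival operations
  but retained for classification.
- Region medians are segment-length weighted; the per-sample baseline
  correction subtracts the length-weighted autosomal median (idempotent).
- The exact branch structure of the W/M subtype trees is a documented
  default, not a published fact; override it via `gcnaclass subtype
  --rules rules.yaml` (ordered `when:` condition → `label:` pairs, final
  catch-all mandatory).

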