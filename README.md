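# oncointegrate

Integration of heterogeneous multi-study cancer cohorts — clinical
tables, expression matrices and copy-number profiles in per-study file
dialects — into a single analysable structure, and survival-time
prediction on top of it.

The package is aimed at computational biologists who hold several
loosely related per-study datasets (e.g. a neuroblastoma RNA-Seq cohort
and a breast-cancer microarray/CNV cohort) and want to (a) pool records
of the same type across studies without hand-writing per-file parsers,
(b) relate patients to each other through shared molecular aberrations
and external protein knowledge, and (c) use the pooled, enriched data to
train survival-time regression models.

## What it does

**Horizontal integration** (`semistructure`). Each delimited file's
separator is auto-detected, header metadata parsed, and every record
folded into a per-data-type *semi-structure*: the map
field name → number of records carrying it, built incrementally record
by record. A data schema derived from the semi-structure projects each
record into a canonical document; every document carries the record ID
and the Sample ID. Documents live in a line-delimited JSON store.

**Vertical integration** (`network`, `edks`). Molecular values become
aberration calls (expression: cohort z-score |z| ≥ 2; copy number:
log-ratio beyond ±0.5) and feed a two-layer patient–protein network.
Relations are scored:

    score(internal, f) = 1.0 + 0.05 (f − 1)
    score(linked, f)   = 0.5 s + 0.05 (f − 1)

where *f* is the number of distinct supporting patients and *s* ∈ [0,1]
the provider's association score, so raw-data relations always outrank
externally derived ones. A relation is **trusted** when *f* > 10
(strictly); untrusted linked relations are pruned, and only trusted
relations drive enrichment. External protein–protein knowledge comes
from a pluggable provider (offline TSV fixture by default; a REST
provider with retry/backoff exists for live endpoints).

**TICF** (`ticf`). The Tumor Integrated Clinical Feature concatenates
tumor stage, tumor size (mm) and age at diagnosis — in this exact order
of prognostic importance — into a fixed-width composite:

    TICF = stage·10⁶ + size·10³ + age,

whose numeric order equals the lexicographic order of
(stage, size, age). Composites are z-normalized (mean/SD stored for
later transforms) and patients stratified into k = 5 near-equal groups.

**Enrichment** (`enrichment`). For a studied patient: ring0 = their TICF
group; ring1 = patients carrying the group's trusted proteins; ring2 =
patients reached through one trusted linked protein hop. The union's
feature matrix (normalized TICF + binary trusted-protein indicators,
re-normalized) and survival-month targets form the per-patient dataset.

**Survival models** (`survival`). SVR with RBF / linear / polynomial
kernels and decision-tree regression, evaluated by seeded k-fold
cross-validation with four metrics (R², explained variance, negative
mean/median absolute error), reported mean ± SD for held-out and
training folds. `run_ablation` crosses ±composite × ±network on a shared
fold partition.

**Synthetic cohorts** (`synthetic`). Because the real cohorts the
design targets are access-restricted, a generator produces two-study
fixtures with planted ground truth: study-specific dialects, survival
`max(0, α − β₁·stage − β₂·size − β₃·age + Σδ_m + ε)` with per-module
carrier effects δ_m, co-aberrant protein modules whose carriers cluster
on the TICF axis, and an external-knowledge fixture with satellite
proteins reachable only through the linked layer.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_survival_prediction.py` (default synthetic scenario,
550 patients across two studies, seed 7) prints:

```
5-fold CV on 374 patients, 27 features (held-out R^2, mean +/- SD over folds):
  svr_rbf   : R^2 0.860 +/- 0.051   MAE 6.6 months
  svr_linear: R^2 0.954 +/- 0.008   MAE 4.6 months
  svr_poly  : R^2 0.952 +/- 0.009   MAE 4.6 months
  dtr       : R^2 0.903 +/- 0.014   MAE 6.6 months

ablation grid (mean held-out R^2 over the four models):
  ticf_network      : 0.917
  separate_network  : 0.910
  ticf_only         : 0.806
  separate_only     : 0.798
```

374 of 550 patients have complete (stage, size, age) and hence a defined
TICF; 27 features are the normalized composite plus 26 trusted-protein
indicators. The linear-kernel SVR predicts held-out survival within
about 4.6 months on average. The grid shows both design choices earn
their keep: dropping the relation network costs ≈ 0.11 R², and replacing
the composite with separate clinical columns costs a little more at
every configuration.

The same pipeline is scriptable from the shell:

```
oncointegrate run --out runs/demo            # simulate -> ... -> ablate
oncointegrate simulate --out fixtures --seed 7
oncointegrate ingest --study NB --data-type clinical --in fixtures/NB_clinical.tsv --store store
oncointegrate build-network --store store --out net.graphml
oncointegrate link --net net.graphml --edks fixtures/edks.tsv --out net_linked.graphml
oncointegrate ticf --store store --out ticf.tsv
oncointegrate predict --store store --net net_linked.graphml --report report.json
```

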