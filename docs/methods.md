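# Methods

## The model

The package treats multi-study cancer data integration as two orthogonal
operations. *Horizontal* integration pools records of one data type
(clinical, expression, copy number) across studies that use different
delimiters, header conventions and field vocabularies. Instead of a
fixed schema, each data type accumulates a **semi-structure**: a map
from field name to the number of records carrying it, folded in record
by record. The semi-structure is order-invariant (it is a multiset
count), and the derived data schema is a projection: a validated
document keeps only fields present in the semi-structure and must carry
a record ID and a Sample ID. Unknown fields are dropped and logged
rather than rejected, so adding a study can never invalidate previously
ingested data.

*Vertical* integration relates the pooled documents through a two-layer
undirected network. Nodes are patients (sample IDs) and proteins (Hugo
symbols, upper-cased). The **internal layer** is derived from raw data:
a patient–protein edge per aberration call, and patient–patient
similarity edges between patients sharing at least one trusted protein,
weighted by the number of shared trusted proteins. The **linked layer**
adds protein–protein edges from an external-knowledge provider.

### Aberration calling

The raw data do not come with mutation calls, so the package defines
them:

* expression — per protein, values are standardized across the whole
  cohort (population SD); a patient is aberrant at |z| ≥ `z_abs_cutoff`
  (default 2.0). Zero-variance proteins are never aberrant.
* copy number — aberrant at value ≥ `cn_gain` (default +0.5) or ≤
  `cn_loss` (default −0.5), i.e. log-ratio-style cutoffs.

All three cutoffs live in `AberrationConfig`. These defaults are the
conventional two-sigma / half-log choices; they are not estimated from
data.

### Relation scoring and trust

Each relation has a frequency *f* = number of **distinct patients**
supporting it. For a patient–protein edge this is the protein's carrier
count; for a linked protein–protein edge it is the number of patients
carrying either endpoint (the relation is exercised once per such
patient). Scores are affine in frequency:

* internal: `base_internal + frequency_bonus · (f − 1)` (defaults 1.0, 0.05)
* linked: `base_linked · provider_score + frequency_bonus · (f − 1)`
  (default base 0.5, provider score in [0, 1])

This form is the simplest one with the two properties the design
requires: strictly increasing in frequency, and internal ≥ linked at
equal frequency for any provider score ≤ 1. A relation is **trusted**
iff *f* > `trusted_threshold`, read strictly (the default threshold 10
means support 11 is trusted, support 10 is not). Pruning removes
untrusted linked edges only; internal edges derived from raw data are
never discarded, they are merely ignored by enrichment traversal when
untrusted.

### The composite clinical feature

TICF concatenates tumor stage (1–4), tumor size (mm) and age at
diagnosis (years) with fixed digit widths (1, 3, 3):

    TICF = stage·10⁶ + size·10³ + age.

Fixed-width zero-padded concatenation is the only reading under which
the composite's numeric order equals the lexicographic order of
(stage, size, age) for all inputs — stage dominates, then size, then
age — and decomposition is exact. Heterogeneous encodings are
normalized first: roman or prefixed stages ("III", "stage 3") map
through a table; sizes below 10 with a decimal point are taken as cm and
converted to mm; unmappable components leave the patient's TICF
undefined (the patient can still be reached through the network and
appears in feature matrices with the TICF column imputed to 0, the
post-normalization mean).

Composites are z-normalized with the population SD; the mean/SD pair is
stored so new patients transform consistently. Constant input is
degenerate: all zeros plus a flag, rather than a division by zero.
Stratification sorts patients by (normalized value, sample ID) and cuts
the order into k contiguous groups whose sizes differ by at most one
(k = 5 by default). Nearest-neighbour queries sort by absolute distance
on the same axis with sample-ID tie-breaks. The grouping is therefore
deterministic quantile stratification, and the "neighbour" notion is a
true nearest-neighbour query on the normalized axis; no labels from a
prior clustering are involved.

### Enrichment

For a studied patient the dataset grows in rings: ring0 is the TICF
group; ring1 adds carriers of the group's trusted proteins; ring2 adds
carriers of proteins one **trusted linked hop** away. Exactly one linked
hop is traversed; only trusted edges are followed (this is where the
scoring mechanism prunes external noise). Rings are made disjoint by set
subtraction, so enrichment is monotone by construction. The feature
matrix over the ring union holds the normalized TICF plus binary
indicators for the proteins used, each column re-normalized (constant
columns become zeros). Rows without a survival value stay in the matrix
for prediction but are excluded from training; fewer than two rows with
targets is an error.

## Survival models and evaluation

Four families: SVR with RBF, linear and polynomial kernels, and decision
tree regression. Defaults: C = 1.0, ε = 0.1, `gamma="scale"`, polynomial
degree 3 with `coef0 = 1.0` (the standard inhomogeneous polynomial
kernel; the homogeneous default cannot represent lower-degree terms),
trees unlimited depth with a fixed seed. Because C and ε are expressed
in target units and survival spans 0–240 months, the SVR families fit on
a standardized target and predictions are transformed back; trees are
scale-equivariant and fit months directly. No hyperparameter search is
performed.

Evaluation is k-fold cross-validation (k = 5 default): one seeded
shuffle, k near-equal folds, every row validated exactly once. Four
metrics per fold — R², explained variance, negative mean absolute error,
negative median absolute error — are aggregated as mean and population
SD, reported separately for held-out and training folds (labelled
explicitly, since "training" metrics overstate accuracy for
high-capacity models).

The ablation grid crosses the composite feature against its separate
components (stage, size, age as three z-scored columns) and the relation
network against clinical-only features. All four configurations share
one row set — every TICF-defined patient, which equals the union of all
ring0 groups — and the same seeded fold partition, so comparisons are
paired; with-network configurations add binary indicator columns for
every protein that is internally trusted or an endpoint of a trusted
linked relation. The comparison scalar is the mean held-out R² across
the four families.

## The synthetic generator

The generator emulates the *structure* of two-study cancer data, not any
particular platform's file format: one tab-delimited study with
snake_case fields, arabic stages, mm sizes and pediatric ages (150
patients), one comma-delimited study with mixed-case fields, roman
stages, cm sizes and adult ages (400 patients). Defaults, chosen once:

* stage distribution (0.30, 0.30, 0.25, 0.15); sizes uniform 5–90 mm;
* survival = max(0, 220 − 30·stage − 0.05·size − 0.01·age + Σδ_m + ε),
  ε ~ N(0, 6²) months, capped at 240. The effect hierarchy
  (stage ≫ size ≫ age) mirrors the prognostic ordering the composite
  feature assumes, and makes noiseless survival monotone in the
  composite (the 30-month stage gap exceeds the largest combined
  size+age contribution);
* four protein modules of 5 co-aberrant proteins each (two expression,
  two copy-number), carriers drawn at rate 0.35 from one quartile band
  of the composite axis and 0.02 elsewhere, with per-module survival
  effects δ = (−20, −10, +10, +20) months. Module carriers therefore
  exceed the trust threshold and carry survival signal that clinical
  features alone do not explain;
* one satellite protein per module, related to the core only through
  the external-knowledge fixture and carried by ≤ 10 patients — signal
  reachable only through the linked layer;
* 70% of patients have complete (stage, size, age); the rest lack one
  component and hence a TICF;
* expression baselines are uniform(−0.5, 0.5) jitter, so a non-carrier's
  |z| is bounded near √3 < 2 and aberration calls equal the planted
  sets exactly; copy-number baselines are ±0.1 jitter against ±1 shifts.

A separate parameter-recovery configuration (single study, n = 500,
complete clinical data, no modules, noise at 5% of the clinical signal
SD) generates survival exactly linear in (stage, size, age) for checking
that the models recover a planted relationship.

What the generator does **not** emulate: real platform formats (CEL,
raw aCGH), censoring, correlated expression structure beyond the planted
modules, batch effects, or missingness mechanisms other than
missing-completely-at-random clinical components. Passing tests
demonstrate that the machinery is correct and that the framework's
advantages hold under these planted conditions; they do not certify
effect sizes on real cohorts.

## Numerical and design choices

* Delimiter candidates are fixed to {tab, comma, semicolon}; the winner
  must split every sampled line into the same number (≥ 2) of columns,
  maximal count wins, ties break tab > comma > semicolon.
* Header convention: `#key=value` lines; the first unprefixed line is
  the attribute row; conflicting repeated keys keep the first value and
  log.
* Field values stay strings at ingestion; typed coercion happens in the
  consuming modules.
* The document store is line-delimited JSON with sorted keys, making
  stores byte-stable; it replaces a document database behind a thin
  interface. The network persists to GraphML (via networkx) or a
  canonical sorted TSV edge list; both round-trip the edge multiset.
* Normalization treats SD ≤ 1e-12·max(1, |mean|) as degenerate
  (constant up to float fuzz).
* Problem sizes used by the test suite and the acceptance script — 550
  synthetic patients in the default scenario, 500 in the recovery
  scenario, 100 random small networks for traversal checks — were chosen
  so the full pipeline completes in seconds while keeping every carrier
  count comfortably above the trust threshold.

## Known limitations

* Survival months are treated as a plain regression target; there is no
  censoring-aware analysis (no Kaplan–Meier or Cox models).
* Expression and copy-number calls assume one value per (protein,
  patient); probe-level or multi-sample data must be collapsed upstream.
* The online knowledge provider implements the retry contract but is
  not used by the test suite; offline TSV fixtures are the default.
* Linked traversal is exactly one hop; deeper chains are deliberately
  not followed to keep the enriched cohorts bounded.
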