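# Methods

## The experimental design the pipeline assumes

A biotin ligase (TurboID, detected through its V5 tag) is expressed in a
chosen brain cell type via Cre drivers (pan-neuronal hSyn, excitatory-neuron
Camk2a, astrocyte Aldh1l1). After biotin supplementation, biotinylated
proteins are enriched from regional brain lysates on streptavidin beads and
quantified by label-free MS, one column per enrichment run. Control animals
lack the ligase; their pulldowns contain only streptavidin background —
prominently the endogenously biotinylated carboxylases (Pc, Pcca/b,
Mccc1/2, Acaca/b) — so the labeled-vs-control contrast identifies
cell-type-derived proteins. The ligase's own MS intensity is the per-sample
normalization anchor, because the entire labeled proteome scales with
ligase expression and labeling efficiency, which differ across brain
regions and drivers.

The companion immunoassay arm measures cytokines and signaling
phospho-proteins (MAPK, Akt/mTOR panels) on multiplex beads in two modes:
the standard sandwich (total analyte) and an adapted mode that omits the
biotinylated detection antibody, so the streptavidin fluorophore reports
only analytes biotinylated in vivo (cell-type-derived signal).

## Processing model

- **Scales.** Intensities are analyzed in log2; missingness is explicit
  (zero intensity on input means "not quantified", never "zero amount").
- **Filtering.** Minimum-valid-value rule, either across all samples
  (default k = 3) or within every design group. Defaults follow common
  practice for this design (3 valid of 9 for a 3-vs-6 cohort; per-group
  thresholds for two-genotype regional cohorts).
- **Imputation.** Missing values are drawn per sample from
  `Normal(mu - shift*sigma, (width*sigma)^2)` with width 0.3 and shift 1.8
  (the Perseus defaults), where mu and sigma come from that sample's
  *observed* values only. Scope is per-sample (Perseus default);
  whole-matrix scope is available. Each sample has its own deterministic
  substream — sub-seed `(master_seed, crc32(sample_id))` — so subsetting
  columns never changes another column's draws.
- **Bait normalization** is an additive per-sample shift in log2 space
  (equivalently a ratio to bait on the linear scale): scale-free and
  exactly preserving within-sample structure. Control samples, where the
  bait is structurally absent, are exempted and flagged; the reference is
  the grand mean of bait values over in-scope samples (a fixed value is
  accepted).
- **Testing.** Student pooled-variance t by default (matching the
  Perseus-style workflow); Welch available. Technical replicates are
  treated as independent columns, as in the source design. Degenerate
  rows: zero pooled variance with equal means gives t = 0, p = 1; with
  unequal means, p is set to the machine minimum and flagged. No
  multiple-testing correction by default (the classification rule is
  stated on unadjusted p); Benjamini–Hochberg q-values are opt-in.
- **Thresholds** (all boundary-inclusive): 2-fold + p <= 0.05 for
  enrichment; 4-fold one-vs-rest + p <= 0.05 for core regional
  signatures; Z > 1.96 for over-representation; k = 5 K-means clusters.
- **Over-representation.** The exact upper hypergeometric tail is reported
  together with the finite-population-corrected normal Z; the enriched
  flag follows the Z rule (the operative criterion in this workflow),
  with a strict-Fisher mode available. The two disagree for small terms.
  Hits absent from the background are dropped (counted); symbols are
  upper-cased before all set operations because mouse (Gfap) and
  human-cased (GFAP) symbol lists are mixed in practice; protein groups
  with several symbols contribute their first symbol.
- **Immunoassay.** Fluorescence is processed per analyte, clipped at zero
  after every subtraction (clips logged). The cell-type-derived fraction
  is the adapted/standard ratio per well, averaged per analyte; wells with
  zero standard signal are excluded as undefined. Normalized cell-type
  analyte levels are (labeled − control) region means divided by the
  region's relative bait abundance from MS on the linear scale (fluorescence
  is linear, so the linear bait ratio is the consistent choice). An
  avidin-blocking control dataset passes when the median blocked/unblocked
  residual is <= 0.1.

## Synthetic-data generator

The generator emulates what the analysis assumes, with ground truth
recorded for scoring:

- log2-normal intensities: per-protein base levels `Normal(24, 2^2)`;
- a fraction (default 10%) of truly enriched proteins elevated by
  `delta_enrich` (default 3) log2 units in labeled samples, a sub-fraction
  carrying an extra `delta_region` (default 2.5) in one region;
- the bait present only in labeled samples at a region-dependent level;
  controls carry it as structurally missing (true zero), so downstream
  bait normalization must tolerate bait-absent columns;
- endogenous-biotin background proteins at equal expectation in both
  genotypes;
- a shared per-sample labeling-efficiency factor in labeled samples
  (regional bait offset plus mouse-level ligase variability) multiplying
  all ligase-labeled rows and the bait itself — the structure bait
  normalization is designed to remove. Without it, region-varying bait
  with non-scaling proteins would make normalization *create* regional
  artifacts, the opposite of its purpose;
- noise partitioned into technical (sd `noise_sd/2`; technical replicates
  resample the same mouse-level mean), mouse-level, and ligase components
  such that one replicate's marginal within-group residual sd is
  `noise_sd` (default 0.5, a typical LFQ residual);
- missing-not-at-random dropout as a separate operation on the log2
  matrix: each value goes missing with probability
  `logistic((midpoint - x)/slope)` — monotone in intensity, 0.5 at the
  midpoint, a hard threshold as slope tends to 0. The logistic form is a
  modeling stand-in; left-shifted imputation assumes left-censoring but no
  specific mechanism.
- matched immunoassay plates: standard expectation `abundance + blank`,
  adapted labeled `fraction * abundance * bait_rel + blank`, adapted
  control `blank`, all with multiplicative noise of configured CV.

The default cohort layout is 2 mice per genotype, five regions (CTX, HIP,
ST, PM, CB), technical replicates for labeled samples in all regions except
hippocampus — 18 labeled and 10 control columns.

All randomness flows from one seed through named `SeedSequence` spawns
(base means, effect assignment, noise), so identical configs are
bit-identical and stages can be tested independently.

**What the generator does not emulate:** peptide-level effects (shared
peptides, protein rollup), correlated protein modules, shared
cortex/hippocampus covariance (each regional effect lives in exactly one
region, so merged CTX+HIP one-vs-rest groups dilute single-region plants),
batch effects, or intensity-dependent variance. Passing recovery tests
therefore demonstrates correctness of the inference chain under the
model's assumptions, not performance on real acquisitions — in particular,
severe left-censoring plus imputation biases control-group means upward
and genuinely reduces sensitivity, which the tests quantify on the
fully observed matrix by design.

## Study-scale choices in tests and the acceptance script

Monte-Carlo recovery runs use 2,000 proteins / 3 mice per group for
enrichment and 1,000 proteins / 4 mice per region (single technical
replicate, 30 planted regional proteins) for signatures, averaged over 20
seeds; null calibration uses 10,000 protein tests. These sizes give
Monte-Carlo error comfortably below the margins being checked while the
whole acceptance run stays within seconds. "n per group/region" counts
biological samples; recovery is scored on the fully observed generated
matrix, with the bait and endogenous rows excluded from the positive set
by definition.

## Numerical conventions

- Exact hypergeometric tails come from `scipy.stats.hypergeom.sf`; test
  oracles recompute them by exact rational summation.
- UPGMA uses `scipy.cluster.hierarchy.linkage(method="average")` on
  one-minus-Pearson distances (range [0, 2]); constant items are an
  error, not a silent drop.
- PCA treats samples as observations and proteins as centered features
  (SVD); variance fractions sum to 1 over retained components; the sign
  convention makes each component's largest-magnitude loading positive.
- K-means is seeded with `n_init` restarts; empty/duplicated centroids on
  degenerate inputs are flagged.
- The 2-D embedding of the joint MS + immunoassay matrix is a pluggable,
  seeded adapter (t-SNE by default); only its output shape is part of the
  tested contract.
- −log10 p is capped at 320 for plotting when p underflows.

## Known limitations

- Imputation assumes each sample has at least two observed values and
  that missingness is left-censored; it will bias group differences when
  entire groups are censored (quantified in the recovery analyses above).
- The "fraction >= 0.5 implies cell-type origin" rule inherits the
  assumptions of the adapted assay (complete dependence of the adapted
  signal on in-vivo biotinylation; verified per dataset via the
  avidin-blocking check).
- Ordering of imputation and bait normalization is configurable; the
  default is filter → impute → normalize. On fully observed data the
  order is immaterial (tested).
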