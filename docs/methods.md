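# Methods

## Model and pipeline

The package identifies *subnetwork markers*: connected interaction-network
modules, anchored on genes altered at both the expression and the copy-number
level, whose aggregate activity serves as a single diagnostic/prognostic
feature. The pipeline is a funnel:

expression + CNA list → DEGs → seed genes → expanded PPI graph → MCL
clusters → filtered markers → per-sample activity scores → (a) SVM
classification, (b) Cox risk score → median split → KM/log-rank.

### Differential expression

Two-group one-way ANOVA per gene on the log2 matrix, identical to the
pooled-variance t-test (F = t²). Fold change is computed on the log2 scale
and reported as *signed linear* FC: `sign(d)·2^|d|` for log2 difference `d`,
so −4 means four-fold down and |FC| ≥ 1 always holds (a zero difference is
reported as the +1 boundary). DEG cutoffs |FC| > 2 and BH-adjusted p < 0.05
are strict inequalities. BH is the step-up procedure implemented directly
(stable ranks for ties); genes with zero within-group variance get p = 0 if
the means differ and p = 1 otherwise, with a warning, rather than being
dropped silently. No covariates, pairing, or empirical-Bayes moderation.

### Network expansion

Seeds are grown `hops` steps (default 1) through the interaction database;
the working graph is the *induced* subgraph on all reached nodes, so
neighbor–neighbor edges are kept. Direction and interaction type are
ignored; the graph is simple and unweighted. Seeds missing from the database
are retained as isolated flagged nodes (warning); if no seed maps, the run
stops. Both the depth and the induced-subgraph choice are configurable
because upstream tools differ on them.

### MCL

From-scratch dense implementation. Adjacency plus self-loops (weight 1,
damping parity oscillations) is column-normalized, then iterated:
expand (`M^e`, default e = 2), inflate (entry-wise power r = 2.0, then
column renormalization), prune (zero entries < 1e−5, renormalize), until the
max entry change < 1e−8 or 200 iterations (non-convergence returns the
current clustering with a flag, never an exception). A column that prunes to
zero mass gets unit mass on its diagonal. Clusters are connected components
of the symmetrized nonzero support of the converged matrix; this yields a
partition directly. An attractor-overlap resolver (largest cluster wins,
ties to the cluster holding the lexicographically smallest member) is kept
as a safety net but is unreachable through component extraction. Markers =
clusters with ≥ 3 nodes and ≥ 1 seed, ordered by size then smallest member,
ids 1..n.

Inflation 2.0 is the common plugin default and the granularity knob: the
tests assert that r = 4 yields at least as many clusters as r = 1.5. Dense
matrices with pruning are deliberate — the target graphs are at most a few
thousand nodes, where dense linear algebra beats sparse machinery on
simplicity and is fast enough (a 200-node graph clusters in ~40 ms).

On graphs with exact attractor symmetry the tied node's side is decided by
floating-point rounding; the oracle test therefore uses elementary numpy
operations in the same order, which makes "identical clustering" exact.

### Scoring

z-transform uses the n−1 standard deviation; zero-variance genes are dropped
with a warning. Direction membership (up/down) is decided for *every* member
gene by the sign of the training case−control mean difference — not only
DEGs — because expansion-added genes must be scorable too; exact ties join
neither set. `SS_i(s)` = mean z over up members − mean z over down members;
an empty side contributes 0. Validation cohorts are z-scored within
themselves (cross-platform scales differ) while directions stay frozen;
genes missing on the validation platform are dropped from their sets, a
per-subnetwork coverage fraction is reported, and coverage < 50% triggers a
warning.

### Classification

Linear-kernel SVM, C = 1, no tuning by default (grid search over C with
stratified k-fold is opt-in) — the simplest defensible choice when the
kernel is otherwise unconstrained. Positive class = case, so sensitivity is
detection of patients. AUC is the Mann–Whitney rank statistic of the
decision values (ties count ½); the 95% CI is DeLong by default
(hand-implemented placement-value form) with a seeded bootstrap alternative.
A class absent from an evaluation cohort leaves its metric as missing, never
zero. PCA is centered, components capped at min(samples−1, features).

### Survival

Cox fits use the partial likelihood with Efron tie handling (via lifelines)
and Wald 95% CIs. The prognostic model fits the subnetwork scores as
continuous covariates in one multivariate model — the risk score formula has
one β per subnetwork — while clinical covariates (age ≥ 50, female, stage
III–IV, lymphatic invasion; reference levels coded 0) are fit separately for
reporting. Risk = Σ SS_i·β_i; the split is `score > median → high`, ties to
low (a deterministic convention; the midpoint median is used). External
validation freezes the β's and recomputes only the median inside the new
cohort. β's are used at full precision; a published one-decimal
15-coefficient colorectal model is shipped as `CRC15_RISK_BETAS` purely as a
worked-example fixture (unit scores → −5.4).

### Enrichment

One-sided over-representation: expected = |query|·|term|/|background|,
FE = observed/expected, p = hypergeometric upper tail P(X ≥ observed)
(p = 1 when observed = 0). The background defaults to the union of the
annotation file's genes and is overridable; BH-adjusted p-values accompany
the raw ones as hygiene. No GO-DAG propagation or term trimming.

## Synthetic data: what it emulates, what it does not

`gen_expression` draws per-gene baselines from Normal(7, 1) with i.i.d.
Normal(0, 0.5) noise and shifts a random 10% of genes by ±2 log2 units in
cases — the magnitude regime of a strong tumor/normal microarray contrast.
`gen_ppi` plants a partition graph (5 blocks × 8 nodes, p_in = 0.6,
p_out = 0.05) whose leading blocks are filled with true-DE genes, and builds
the CNA list from half of the in-graph DE genes plus null decoys, so the
seed intersection lands inside planted blocks and "true" marker subnetworks
exist by construction. `gen_survival` uses exponential event times with
hazard `h0·exp(β·z(risk))` (h0 = 0.02, β = 1 per sd of risk — proportional
hazards by construction, the assumption the Cox stage needs), Uniform(0, u)
censoring with u solved by Brent's method to hit the expected censoring
fraction (default 20%), and independent clinical covariates
(P(age ≥ 50) = 0.8, P(female) = 0.5, P(stage III–IV) = 0.45,
P(invasion) = 0.35).

Defaults (500 genes, 30 + 30 samples, effect 2.0, sd 0.5, survival n = 300)
were chosen once as a realistic strong-signal regime at desk scale; the
validation cohort shares the training truth map but draws fresh baselines
and noise. Not emulated: batch effects, probe cross-hybridization,
correlated noise, copy-number segments, non-proportional hazards, platform
dropout. Passing tests therefore demonstrate correctness of the machinery
and recoverability under clean planted signal — not performance on real
cohorts, where effect sizes are smaller and noise is structured. Perfect
accuracy/AUC on the synthetic validation cohort reflects the planted effect
size, not a general claim.

## Numerical choices and degenerate inputs

- BH: stable argsort, running minimum from the largest rank, cap at 1.
- MCL: convergence on max absolute entry change; stochasticity is asserted
  to 1e−9 after every inflate step in tests; idempotence at convergence is
  checked within 10× tol.
- Duplicate probe rows collapse to the row with the highest mean intensity;
  symbols match case-sensitively after trimming, no alias resolution.
- Degenerate cases raise typed errors rather than guessing: single-class
  labels, < 2 samples per group, constant Cox covariates, zero events,
  all-identical risk scores, empty seed intersection (warning + halt
  downstream), subnetworks with no scorable gene.
- Pipeline determinism: one `rng_seed` fans out per stage via a CRC32 hash
  of the stage name; no timestamps enter any artifact, so identical configs
  give byte-identical outputs.

## Design choices where the design was open

- "ANOVA" with two groups is the pooled-variance F-test — the tumor/normal
  contrast needs nothing more.
- 1-hop induced expansion as the default reading of seed-based network
  growth; both depth and edge induction are exposed.
- Hard MCL partition (component extraction + deterministic tie-break)
  because downstream scoring assumes disjoint markers.
- Universal sign rule for up/down membership (all members, training data) —
  the only rule that covers expansion-added genes consistently.
- Risk model with per-subnetwork β's (matching the one-β-per-marker score
  formula) rather than a single dichotomized risk covariate; both Cox modes
  are available.
- CLI stage commands re-run the pipeline up to the requested stage instead
  of consuming intermediate files — purity over incremental caching at this
  scale.

## Known limitations

Dense MCL memory grows as O(n²) (fine to a few thousand nodes). No
confidence-weighted edges, no probe-level preprocessing, no alias mapping,
no time-dependent covariates or competing risks. The log-rank test is the
two-group 1-df form. DeLong CIs are clipped to [0, 1] rather than
logit-transformed. Acceptance of sample counts below ~15 per class in the
SVM stage is mechanical, not a statistical endorsement.

## Problem sizes used in tests

Test and acceptance runs use the default synthetic conditions above
(500 genes, 40-node marker graph, 200-node planted-partition for MCL
recovery, survival cohorts of 100–300) — sizes chosen so the whole suite
exercises every stage in seconds while keeping every estimator in a regime
where its statistical guarantees are meaningful.
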