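# Methods

## The analysis model

The quantity of interest is the partial correlation between leukocyte
telomere length (LTL, Z-scored within cohort) and the natural-log
concentration of each serum metabolite, given adjustment covariates.  For a
cohort with n available-case rows and k covariates (model 1: age, sex;
model 2: age, sex, BMI), both variables are residualized on the covariates
(with intercept) by least squares and r is the Pearson correlation of the
residual vectors.  This equals the inverse-correlation-matrix definition
r_xy·Z = −Ω_xy/√(Ω_xx Ω_yy), which the test suite uses as an independent
oracle.  Significance uses t = r√(df/(1−r²)) with df = n − 2 − k, two-sided;
the df convention (covariates consume degrees of freedom) is stated because
it is easy to get silently wrong.

Sex is encoded 0 = male, 1 = female.  Constant covariate columns (an
all-female cohort) are pruned from the design before fitting, and k counts
the covariates actually retained.  Missing values are excluded pairwise per
metabolite (available-case analysis), never imputed, so n varies by
metabolite within a cohort.

### Family relatedness

Twin and family cohorts violate the independence behind the t reference.
Three modes are provided; the default, `mixed_residual`, fits a one-way
random-intercept model y = Xβ + u_family + e to each variable by REML and
correlates the conditional residuals (fixed-effect fit and BLUP family
intercepts both removed).  The REML profile over the variance ratio
λ = σ²_u/σ²_e is optimized as a scalar (bounded search on log λ, with the
λ = 0 boundary checked explicitly) using per-family sufficient statistics,
which makes a fit cost milliseconds; statsmodels' MixedLM fits the same
model and serves as the oracle in a unit test, but is too slow to be the
per-metabolite workhorse in replicate simulations.  `one_per_family` keeps
one seeded-random member per family; `none` ignores relatedness.  A
simulation experiment (500 replicates, 200 families of 4, intra-class
correlation 0.5 on both variables) shows the naive test rejects a true null
at ~0.14 when α = 0.05 while the mixed residualization stays at ~0.05.

### Meta-analysis

Per-cohort correlations are pooled on the Fisher z = atanh(r) scale with
inverse-variance weights w = n − k − 3 (the reciprocal asymptotic variance
of z for a partial correlation), z̄ = Σwz/Σw, SE = 1/√Σw, p from the normal
reference, r_meta = tanh(z̄).  The weighting convention is a design choice —
the source analysis names no method — so a sample-size-weighted variant
(w = n) is available behind a flag, and Cochran's Q and I² are reported as
diagnostics without influencing anything.  Each pooled row carries a
direction string over the configured cohort order (KORA, NTR, EGCUT,
TwinsUK, ERF, LLS, QIMR): `+`/`-` by sign, `0` when |r| < 0.005 (i.e. r
rounds to 0.00 at the reporting precision), `?` when the cohort contributed
no estimate.  Leave-cohort-out sensitivity re-runs the identical pipeline on
the subset and flags verdict changes.

### Multiple testing

The effective number of independent metabolites is computed from the
eigenvalues λ₁ ≥ … ≥ λ_m of the metabolite correlation matrix
(pairwise-complete, on ln concentrations) as
Veff = Σᵢ [1{λᵢ ≥ 1} + (λᵢ − ⌊λᵢ⌋)].  The family-wise threshold is
α/⌈Veff⌉; the ceiling convention matches the matSpD tool, and both raw and
integer forms are reported because the rounding rule behind the published
integer is not recoverable.  Numerical care: eigenvalues that are integers
up to rounding error are snapped before the fractional part is taken (an
exact eigenvalue 3 computed as 3 − 4·10⁻¹⁵ would otherwise contribute ~2
instead of 1), and tiny negative eigenvalues (> −10⁻⁶) from non-PSD
pairwise-complete estimates are absolute-valued while larger negatives are
an error.  Benjamini–Hochberg FDR values (statsmodels step-up) annotate
every row; an `m_override` lets a p-value subset be adjusted against the
full panel size by padding with p = 1, which cannot lower any head value.

### Clustering, correlogram, pathway search

Metabolites are clustered by their (model 1 r, model 2 r) profile with
complete-linkage agglomerative clustering on euclidean distance; rows are
sorted lexicographically by name before linkage so tie-breaking is
deterministic, and a two-cluster cut is reported alongside the full merge
tree.  The correlogram is the pairwise-complete Pearson matrix of the
significant metabolites' ln concentrations within one reference cohort.
Figures always have TSV companions with the exact plotted numbers; tests
target the TSVs and image bytes are explicitly untested.

The pathway question — do two metabolites participate in reactions within
two steps of each other? — is answered by breadth-first expansion
alternating metabolite → reaction → metabolite.  Traversal respects
reaction direction unless the reaction is reversible, never passes through
hub metabolites (currency compounds: ATP, ADP, AMP, NAD(H), NADP(H), H₂O,
CO₂, Pi, PPi, CoA by default; configurable), and matches the target against
the full substrate-and-product set of every traversed reaction.  Hubs may
appear as co-substrates of used reactions; the filter only blocks them as
intermediates, since its purpose is to prevent non-specific connections.
Ties are broken lexicographically so returned paths are deterministic, and
unordered pairs are searched in both directions keeping the shorter found
path.  A curated ~37-node methionine/homocysteine network ships with the
package: transmethylation (MAT, GNMT, SAHH), transsulfuration (CBS, CTH),
the betaine/choline remethylation arm (PLD, choline oxidation, BHMT, MS),
the gamma-glutamyl cycle, and phosphatidylcholine turnover including the
PEMT reaction (PE + SAM → PC + SAH).  PEMT is what links the
phosphatidylcholines to methionine within two steps — it is the dominant
SAM consumer in vivo, i.e. precisely the homocysteine-metabolism connection
the analysis highlights.  A synonym table maps panel short names to network
nodes; lipid species map to class-level nodes (e.g. "PC aa C32:1" →
phosphatidylcholine), a documented approximation, and acylcarnitines have
no node in this network so they are reported as unmapped rather than
failing.

## The synthetic consortium

The generator emulates the study conditions, not the assay physics.  Each
cohort is drawn from a joint Gaussian latent model:

* age ~ N(μ, σ) and sex ~ Bernoulli(%female) per the published cohort
  table; BMI likewise, absent entirely for QIMR and missing for a handful
  of samples where the published BMI n is smaller than the cohort n;
* families are non-overlapping clusters (size distribution per cohort:
  mostly 1–2 for twin registers, 1–4 sibships for the family studies) whose
  members share Gaussian random intercepts — one for LTL, one for
  metabolites — with weight √ICC.  ICC is the single relatedness knob
  (0 for the population samples, 0.3–0.4 for family/twin designs); zygosity
  is not modelled;
* standardized log-metabolite residuals have within-class block correlation
  ρ plus the shared family component; the planted metabolites additionally
  load on the LTL residual so that their partial correlation with LTL given
  age, sex and BMI equals the planted r exactly.  Concentrations are
  exponentiated to µM around class-typical medians (e.g. hexose ~4.5 mM,
  amino acids ~120 µM, acylcarnitines ~0.15 µM);
* missingness is MCAR (no mechanism is documented for the real data) and
  values below the limit of detection are censored to missing — never
  imputed.  QC judges the *reported* values, so the median-above-LOD rule
  is meaningful; censoring is applied when the analysis matrix is built,
  keeping unreliable values out of the analysis;
* replicate QC-sample tables are drawn log-normal with a per-metabolite
  true CV (default 8%) from which the CV criterion is computed, since the
  source protocol does not say which samples defined the CV.

Default planted effects mirror the published associations: +0.05 on
lysoPC a C17:0, +0.04 on PC ae C38:4, −0.04 on Met, Tyr and PC aa C32:1,
−0.10 on C3-OH.  Within-class correlations (AA 0.30, AC 0.45, SM 0.55,
lysoPC 0.55, PC aa/ae 0.60) were calibrated once so that the effective
number of independent metabolites computed on a reference-size simulated
cohort lands near the published 46 of 131 (measured 44–49 across
ERF/NTR-size cohorts and seeds).

Seeding: a master seed derives one seed per cohort through
`SeedSequence((master, cohort_index))` — a counter scheme, so appending a
cohort never changes earlier cohorts — with separate streams for replicate
tables and missingness injection.  Identical inputs and seed give
byte-identical tables.

What passing tests on this generator do **not** show about real data: no
batch or plate effects, no qPCR measurement-error structure, no
non-Gaussian tails or skewed LOD mechanisms, lognormal-Gaussian copula
only, family structure reduced to exchangeable clusters, and blocks are
independent across classes whereas real lipid classes correlate with each
other.  Parameter-recovery results transfer to real cohorts only insofar as
those features are second-order for a covariate-adjusted correlation of
magnitude ~0.05.

## Calibration experiments and problem sizes

Three replicated experiments (all seeded, `telometa.experiments`) document
operating characteristics at sizes chosen to finish in minutes on one CPU:

* **Family-wise error**: 500 replicates of 20 block-correlated null
  metabolites (4 blocks, ρ = 0.5) at n = 500; the Veff-based threshold
  yields FWER ≈ 0.05–0.065 (the Li–Ji style estimator is known to be
  slightly liberal under moderate correlation; the band 0.05 + 2 binomial
  SE ≈ 0.07 holds).
* **Planted-effect recovery**: 100 replicates of the full pipeline at the
  published cohort sizes with an eight-metabolite panel and r = 0.05
  planted on one metabolite.  The planted correlation is defined
  conditional on age, sex and BMI, so the fully adjusted model is the
  estimand-matched estimator (the BMI-less cohort drops out; pooled
  n = 7,660).  Mean estimate ≈ 0.048–0.051, SD ≈ 0.012 (the asymptotic
  1/√n), ≥ 93–99% of replicates within ±0.025 depending on seed.
* **Cluster inflation**: see family relatedness above.

The reduced panel in the recovery experiment is a design choice: the
pooled-estimate sampling distribution for one metabolite does not depend on
how many null metabolites ride along, and eight keeps 100 full-pipeline
replicates cheap.

## Numerical choices and degenerate inputs

* p-values are floored at the smallest positive normal double; a perfect
  correlation reports that floor, never 0.
* Exactly collinear design columns are pruned (QR-rank test at 10⁻⁸
  relative tolerance); an empty design is an error.
* Fisher transform requires |r| < 1; pooled correlations are clipped away
  from ±1 by one ulp before atanh.
* REML: singleton-only grouping degenerates to a flat profile; residuals
  then reduce to OLS residuals, so all family modes agree on unrelated
  cohorts (tested at 10⁻⁸).
* Zero-variance residuals, constant LTL vectors, fewer than k + 4 rows, and
  metabolites missing from the LOD table are errors, not warnings.
* QC boundary semantics: CV = 25% passes ("not exceeding"), missing
  fraction = 5% fails ("less than"), median = LOD fails ("above").
* Sorting everywhere uses stable mergesort with lexicographic name
  tie-breaks, so outputs are bitwise reproducible run to run.

## Known limitations

* The per-cohort correlation estimates of the restricted real data are not
  reproducible by construction; parameter-recovery experiments stand in for
  them.
* The mixed-residual family adjustment uses an exchangeable within-family
  covariance; pedigree/GRM kinship models are out of scope.
* The meta-analysis is fixed-effect only; heterogeneity is reported, not
  modelled.
* The shipped reaction network is a curated teaching-size fixture for the
  methionine/homocysteine neighbourhood, not a genome-scale reconstruction;
  the loader accepts user reaction TSVs for anything larger.
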