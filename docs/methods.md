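# Methods

`oxysites` implements a comparative pipeline linking the physicochemical
variation of positively selected amino-acid sites in oxygen-sensing genes
(the HIFA transcription-factor and EGLN/PHD prolyl-hydroxylase families of
ray-finned fishes) to whole-animal hypoxia tolerance, measured as the
standardized critical oxygen tension P_crit (kPa; lower = more tolerant).
This note documents the model at each stage, the tunable parameters, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Pipeline overview

For one gene family (homology group):

1. **Sanitize** the aligned amino-acid sequences: frameshift markers,
   stop symbols and any non-canonical character become `X`; `X` and the gap
   `-` are treated as missing downstream.
2. **Truncation filter** (optional, off by default): drop sequences whose
   ungapped length falls below a fraction (default 0.5) of the median
   ungapped length of the retained full-length sequences, iterated to a
   fixed point. Truncated paralogs otherwise form an artefactual
   physicochemical cluster driven by imputation.
3. **Encode** the selected codon columns with the five extended z-scale
   descriptors (z1 hydrophobicity, z2 steric bulk, z3 polarity, z4–z5
   electronic effects; constants shipped in
   `data/sandberg_zscales.tsv` with citation). Each sequence becomes a
   row of 5·m features. Missing cells are imputed with the per-column mean
   of observed cells, which leaves every column's observed mean unchanged.
   Imputation happens after the truncation filter, so removed sequences
   never influence the means.
4. **PCA** on the centered (not rescaled — the z-scales are already on
   comparable published scales) feature matrix, retaining the minimal
   number of components whose cumulative variance reaches the target
   (default 0.90), capped at the matrix rank and at n−1. The achieved
   fraction is recorded.
5. **Group inference**: k-means (25 seeded restarts) on the retained PC
   scores for k = 1…k_max (default min(n−1, 10)), scored by the BIC of a
   spherical Gaussian mixture with per-cluster variances evaluated at the
   k-means partition (see "BIC choice" below). The minimizing k is chosen;
   ties go to the smaller k.
6. **Discriminant analysis**: the generalized symmetric eigenproblem
   B a = λ W a of the between- vs within-group covariance of the PC
   scores, with a ridge of 1e-8 on W to guard singleton groups. k−1
   discriminant axes (LDs) are kept; each LD's share of the discriminant
   variance is its eigenvalue over the eigenvalue sum (for k = 2 this is
   identically 1.00). Discriminant coefficients are composed back through
   the PCA rotation to per-variable loadings; each LD's loading vector is
   sign-flipped so its largest-magnitude element is positive, making output
   reproducible across eigensolvers.
7. **Top-loading codons**: per LD, the five |loading| values of each site
   are summed (a site is one biological unit — the map is to codons, not
   descriptors) and sites at or above the 90th percentile of that aggregate
   are reported, ties at the threshold included.
8. **PGLS**: standardized P_crit is regressed on the LD scores under a
   multivariate-normal error with covariance σ²·V(λ), where C holds the
   shared root-to-tip branch lengths of the gene tree and V(λ) multiplies
   the off-diagonal of C by Pagel's λ. Every paralog row of a species
   receives that species' P_crit, so species with several gene copies
   contribute several points. Two λ modes are fitted per temperature:
   fixed λ = 0.001 ("no phylogenetic influence") and λ estimated by
   bounded profile maximum likelihood on [1e-6, 1] (Brent, xatol 1e-6;
   boundary hits flagged, a lower-bound estimate prints as 0.000).
   Backward model reduction drops, one at a time, the term whose
   term-deletion F-test (nested GLS at the current model's λ, which is
   re-optimized between steps in ML mode) has the largest p ≥ 0.1, until
   all remaining LDs are significant; if everything is dropped the
   intercept-only model is reported with the dropped list.
9. **Random-site control**: the identical pipeline on a seeded uniform
   draw (default 52) of non-selected columns with at least one observed
   residue; its PGLS models are reported full, without reduction, since
   reducing a null model would simply empty it.
10. **Support filter and proportions**: sites with a BUSTED evidence ratio
    strictly greater than 2 are flagged as supported; the proportion of
    selected codons per family is compared across families with a Pearson
    χ² test (no continuity correction) on the 2×g table, plus a focal
    2×2 variant (one family against the pooled rest). Alignment codon
    totals are required inputs; where only the site census is available,
    the per-family maximum codon index is used as an explicit lower bound.

## Statistical details

* **GLS computation.** Cholesky whitening; β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, standard
  errors from σ̂²(XᵀV⁻¹X)⁻¹ with σ̂² = RSS_V/(n−p); two-sided t tests on
  n−p degrees of freedom; the reported log-likelihood is the ML profile
  (σ²_ML = RSS_V/n). A design with condition number above 1e12 is rejected
  with the offending columns named.
* **R².** 1 − RSS_V/TSS_V with TSS_V from the intercept-only GLS fit under
  the same V. This matches printing a single model R² per fitted model;
  the log-likelihood is stored alongside so alternative definitions can be
  compared.
* **λ bounds.** λ > 1 is disallowed (V can lose positive definiteness);
  ML, not REML, to match the field's standard tooling convention.
* **Scale invariance.** Multiplying all branch lengths by c > 0 leaves
  β̂, t, p and λ̂ unchanged (σ̂² scales by 1/c); this is asserted in tests.

### BIC choice for the number of groups

A criterion of the form n·ln(WSS/n) + k·ln(n) on the pooled k-means WSS
cannot stop at the true k on tightly clustered data: k-means removes a
roughly constant *fraction* of a homogeneous cluster's WSS per additional
split (≈ 25% per split on small clusters in few dimensions), which always
beats the ln(n) penalty, so the argmin slides to k_max. The criterion used
here is the BIC of a spherical Gaussian mixture with per-cluster variances
evaluated at the k-means partition (parameters: k·d means, k variances,
k−1 weights). Splitting a genuinely homogeneous cluster then buys little
likelihood while still paying the full penalty, and the criterion is exact
in the separable limit. Per-cluster variances are floored at 1% of the
overall per-dimension variance to block the classic mixture degeneracy in
which shaving off a near-coincident pair of rows sends a cluster variance,
and hence the criterion, to −∞.

## Synthetic data generator

The generator produces the full five-file input bundle with known ground
truth, so every stage is testable without any external data.

* **Tree**: pure-birth (Yule) with n tips (default 48) and birth rate 1.
  Starting from two root lineages, the interval with i lineages lasts
  Exp(i·b), and a final Exp(n·b) interval separates the last split from
  the present, so the expected root-to-tip depth is Σ_{i=2..n} 1/(i·b).
  Trees are ultrametric.
* **Groups**: tips are partitioned into k (default 4) clade-based blocks
  by splitting the largest clade at its root until enough blocks exist,
  then merging the smallest. Blocks are ordered so the first two lie
  within the same basal half of the tree where possible; the first
  (standardized Helmert) group contrast therefore compares the two most
  closely related groups — the component of group structure least
  confounded with the deepest divergence, which is what makes the
  random-site control a true null for the planted effect.
* **Selected sites** (default m = 30): per site, k anchor residues are
  picked by greedy max–min distance in z-space, and each group's residue
  profile is a softmax over −concentration · (z-distance to its anchor)
  (default concentration 10: sharply group-diagnostic but still
  polymorphic columns). Residues are i.i.d. per tip given the group — no
  within-group phylogenetic correlation, keeping the DAPC ground truth
  exact.
* **Background columns** (default 60): same construction but structured
  only around the basal two-clade split, with a weaker concentration
  (default 3), emulating shallowly conserved background variation. The
  random-site control draws from these columns.
* **Gaps**: i.i.d. at rate 0.02.
* **Phenotype**: P_crit = intercept (6 kPa) + Σ β_j·contrast_j + ε with
  ε ~ MVN(0, σ²·V(λ_true)); default β = (2, 0, 0) kPa per SD of contrast,
  λ_true = 0.5, σ² = 1 kPa². The covariance is normalized to unit mean
  tip depth so σ² is the marginal tip variance regardless of tree height.
  Because standardized P_crit is strictly positive, the rare draw dipping
  below 0.5 kPa is shifted up to that floor — a constant offset invisible
  to β and λ recovery.

What the generator does **not** emulate: within-group sequence evolution
along the tree (residues are exchangeable within groups), indel structure
(gaps are i.i.d., not block-wise), codon-level selection processes (the
site list is an input by design), multiple gene families with shared
species, and temperature dependence of P_crit (one pseudo-temperature is
generated). Tests passing on these data therefore validate the
*statistical machinery* — encoding, imputation, dimension reduction, group
and loading recovery, λ/effect estimation, calibration of the control —
not the upstream biology of alignment quality or selection inference.

## Problem sizes and calibration results

The shipped calibration study (`analysis/06_calibration_study.py`, also
recomputed by `scripts/acceptance.py`) uses 200 simulations at 64 tips for
parameter recovery and 1,000 replicates at 48 tips for error calibration;
the random-site control runs the full pipeline on 100 seeds. At these
sizes the Monte-Carlo mean of the planted effect is recovered essentially
unbiased (≈ 2.0 for truth 2.0), while the ML estimate of λ shows the
well-known downward finite-sample bias (mean ≈ 0.42 for truth 0.5).

Under a pure phylogenetic-noise null with an equally phylogenetically
structured predictor, the λ = 0.001 model rejects at roughly four times
the nominal 5% level — the quantitative core of the argument for
phylogenetic correction — while the ML-λ model is close to nominal but
retains a slight inflation (≈ 0.06–0.08 at 48 tips across seed families).
The residual inflation is the cost of plugging the estimated λ into the
t-tests as if it were known: with λ fixed at its true value the same
machinery rejects at the nominal rate. At these sample sizes roughly one
replicate in six underestimates λ badly enough to under-correct. REML
estimation of λ would reduce (not remove) this, but ML is retained as the
field-standard convention for this analysis.

## Known limitations

* Site lists, evidence ratios and trees are consumed, never inferred;
  garbage in, garbage out.
* The discriminant axes are identified only up to rotation when
  eigenvalues tie, and their indices are not comparable across data sets;
  "LD1 matters" is a statement about one fitted analysis.
* Column-mean imputation shrinks gapped sequences toward the centroid,
  which can only dilute, never invent, group structure — but families
  with extreme gap fractions should use the truncation filter first.
* The per-test α = 0.1 retention rule performs no multiplicity correction
  across genes or temperatures, matching the source analysis design.
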