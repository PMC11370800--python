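# oxysites

Comparative analysis of oxygen-sensing gene evolution and hypoxia
tolerance in ray-finned fishes: does the physicochemical variation at
positively selected amino-acid sites of the HIFA (hypoxia-inducible factor
alpha) and EGLN (prolyl hydroxylase) gene families predict a species'
critical oxygen tension?

The package is for comparative physiologists and molecular evolution
researchers who already have, per gene family: an aligned set of coding
sequences, a maximum-likelihood gene tree, a list of positively selected
codon positions (e.g. from MEME/FEL, with optional BUSTED evidence
ratios), and standardized P_crit values (kPa) per species. It turns those
into group structure, discriminant axes and phylogenetically corrected
regressions, and ships a fully synthetic data generator so the entire
pipeline is testable end to end with known ground truth.

## The method

1. **Site encoding.** Each selected codon column is scored with the five
   extended z-scale descriptors of amino-acid physicochemistry
   (z1 hydrophobicity, z2 steric bulk, z3 polarity, z4–z5 electronic
   effects); gaps and unknowns are imputed with per-column means of the
   observed residues.
2. **DAPC** (discriminant analysis of principal components). PCA retains
   the minimal components reaching ~90% of the variance; k-means plus a
   BIC infers the number of gene groups k; the generalized eigenproblem
   `B a = λ W a` of between- vs within-group covariance yields k−1
   linear discriminants (LDs), each with its share of the discriminant
   variance, and per-codon loadings (sites at the 90th percentile of
   aggregated |loading| are reported per LD).
3. **PGLS** (phylogenetic generalized least squares). For each
   temperature, standardized P_crit is regressed on the LD scores under
   error covariance `σ² V(λ)`, where `V(λ)` keeps the diagonal of the
   Brownian shared-branch-length matrix `C` and multiplies its
   off-diagonals by Pagel's λ. Two modes: λ = 0.001 (no phylogenetic
   influence) and λ estimated by profile maximum likelihood on [1e-6, 1].
   Backward ANOVA reduction (term-deletion F-tests) keeps LDs with
   P < 0.1.
4. **Controls.** A seeded draw of non-selected sites (default 52) is run
   through the identical pipeline with unreduced models; BUSTED evidence
   ratios > 2 flag supported sites; a Pearson χ² test compares
   selected-codon proportions across families.

## Worked example

The numbered scripts under `analysis/` run a complete study on synthetic
data (results land under `results/`):

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_dapc_selected_sites.py --seed 1
python analysis/03_pgls_hypoxia_tolerance.py --seed 1
python analysis/04_random_site_control.py --seed 1
python analysis/05_site_census_chi2.py
python analysis/06_calibration_study.py --seed 1
```

Script 01 writes a 48-tip Yule tree, four clade-based sequence groups
differentiated at 30 selected sites (plus 60 background columns), and a
P_crit table with a planted 2 kPa/SD effect of the first group contrast
under λ = 0.5 phylogenetic noise. Scripts 02–04 then print:

```
inferred k = 4 groups; LD variance proportions = [0.5, 0.34, 0.16]
top-loading codons per LD: {1: [14, 16, 30], 2: [16, 18, 29], 3: [2, 5, 14]}

fixed lambda=0.001 R2=0.832 retained: ['LD1', 'LD2', 'LD3'] dropped: ['(none)']
   ml lambda=0.000 R2=0.832 retained: ['LD1', 'LD2', 'LD3'] dropped: ['(none)']

fixed lambda=0.001 R2=0.000 k=2 LDs significant at 0.05: ['(none)']
   ml lambda=0.898 R2=0.000 k=2 LDs significant at 0.05: ['(none)']
```

Reading this: DAPC recovers the four planted groups exactly, and the
reduced PGLS models keep the discriminant axes that carry the planted
group effect (R² = 0.83 on this draw; the ML λ hit the lower boundary
here, i.e. after the group means are in the model little phylogenetic
residual signal remains). The random-site control — same tree, same
phenotype, 52 columns that carry only background phylogenetic structure —
finds k = 2 background groups whose single LD is unrelated to P_crit once
λ is free (λ̂ = 0.90 absorbs the basal divergence): the association is
specific to the selected sites.

Script 05 summarizes the shipped census of published selected codons
(e.g. 53 episodic sites for HIF2A vs 8 for EGLN1) and prints the
proportion comparison:

```
HIF2A vs pooled other HIFA: chi2 = 9.419, p = 0.00215
```

Script 06 reports the Monte-Carlo calibration (effect recovery is
unbiased; ML λ̂ is biased low at n = 64; the λ = 0.001 model over-rejects
roughly fourfold under a phylogenetic null while the ML-λ model is close
to nominal).

A `oxysites` command-line interface wraps the same stages
(`simulate`, `encode`, `dapc`, `pgls`, `run`, `control`); see
`oxysites --help`.

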