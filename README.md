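# gutmet

Integrative gut-microbiome / urine-metabolome cohort analysis in Python.

`gutmet` implements the statistical core of a metabolome-wide association
study (MWAS) linking a urinary metabolite — hippurate, the glycine
conjugate of microbially produced benzoate — to gut metagenome gene
richness, curated phenylpropanoid metabolic modules, enterotypes, diet
strata and insulin-resistance phenotypes. It is written for microbiome /
metabolomics researchers who want each stage of such an analysis as a
tested, reusable component rather than a one-off script:

- **`gutmet.nmr`** — ¹H-NMR preprocessing: probabilistic quotient
  normalisation (PQN), statistical recoupling of variables (SRV) peak
  clustering, targeted multiplet integration (hippurate at 7.84(d),
  7.64(t), 7.55(t) ppm), creatinine adjustment.
- **`gutmet.opls`** — O-PLS(-DA) with a single predictive component,
  sevenfold cross-validated Q²_Ŷ, response-permutation significance, and
  per-cluster MWAS tables for Manhattan-style pseudo-spectra.
- **`gutmet.modules`** — KEGG-syntax metabolic module parsing,
  Omixer-RPM-style per-sample abundance/coverage (OR = max, AND = min,
  module = median over steps), gene richness, Shannon diversity, and
  prevalence-filtered (>20 %) module–metabolite associations.
- **`gutmet.enterotypes`** — Dirichlet-multinomial mixture (DMM)
  community typing with Laplace model selection, dominant-taxon
  labelling, Hellinger transform, Bray-Curtis PCoA, Kruskal-Wallis +
  joint-rank Dunn comparisons.
- **`gutmet.stats`** — consensus choice of k (elbow/silhouette/gap),
  k-means stratification, probabilistic PCA tolerant of missing values,
  forward stepwise rank regression (AIC), partial Spearman correlations,
  Storey-q / Benjamini-Hochberg FDR, normality-gated group tests, ROUT
  outlier screening, IPGTT summaries, and adjusted-attribution reports.
- **`gutmet.synth`** — a synthetic cohort generator that plants known
  effects (hippurate–richness coupling, module coupling, community
  types, a diet-conditional hippurate→HOMA-IR interaction) so the whole
  pipeline is testable end to end without any external data.

## The model in brief

Let `x_i ∈ R^p` be subject *i*'s spectrum (or cluster-integral vector)
and `y_i` the response (gene richness or its high/low class). O-PLS
removes `n_orth` components of X-variation orthogonal to y, then fits
one predictive component by NIPALS; prediction quality is

```
Q²_Ŷ = 1 − PRESS / TSS,   PRESS = Σ (y_i − ŷ_i,held-out)²
```

under sevenfold cross-validation, with empirical significance
`p = (#{Q²_null ≥ Q²_obs} + 1) / (n_perm + 1)` from response
permutations. Module abundance follows KEGG module syntax: for each
reaction step the abundance is the max over alternative orthologs of the
min over complex subunits, and the module value is the median over steps
when step coverage reaches 2/3. Enterotypes maximise the
Dirichlet-multinomial mixture likelihood by EM, with the number of
components chosen by the Laplace approximation to the negative log model
evidence. Attribution statistics are partial Spearman correlations
(rank, residualise, correlate), including the 2×2 "collapse" pattern:
an association that vanishes after adjusting for a partner variable was
mediated by it.

## Worked example

```python
import numpy as np
import gutmet as g

coh = g.generate_cohort(g.SynthConfig(seed=0))          # 200 subjects
spectra = g.pqn_normalize(coh.spectra)                  # undo dilution
clusters = g.srv_cluster(spectra)                       # SRV peak clusters
feats = clusters.integrate(spectra)                     # cluster integrals
rich = g.gene_richness(coh.ko_table,
                       cutoff=float(np.median(coh.truth.gene_richness_true)))

mwas = g.mwas_coefficients(feats, rich.gene_count.to_numpy())
print(mwas.sort_values("covariance_with_y", key=abs, ascending=False).head(1))

perm = g.permutation_test(feats, rich.gene_count.to_numpy(),
                          n_orth=1, n_perm=999, seed=0)
print(f"Q2 = {perm.observed_q2:.3f}, permutation p = {perm.p_empirical:.3g}")
```

Output (152 SRV clusters found):

```
cluster_id  apex_ppm  covariance_with_y  correlation_with_y      p_value
     C0028  7.549650         485.051483            0.528110 9.256095e-16
Q2 = 0.220, permutation p = 0.001
```

The top cluster by |covariance| sits at 7.55 ppm — one of the three
planted hippurate multiplets — with a positive association with gene
richness (r = 0.53), and the cross-validated O-PLS-DA model beats all
999 response permutations. Continuing to the functional layer:

```python
assoc = g.associate_modules(
    g.module_profiles(g.load_synthetic_modules(), coh.ko_table),
    g.integrate_regions(spectra))          # summed hippurate multiplets
print(assoc.head(2)[["module_id", "name", "prevalence", "rho", "q"]])
```

```
module_id                               name  prevalence       rho            q
   MC0004   cinnamate conversion (synthetic)         1.0  0.893385 1.909663e-69
   MC0005  coumarate degradation (synthetic)         1.0  0.876251 1.011111e-63
```

Exactly the two hippurate-coupled phenylpropanoid modules planted by the
generator reach significance; the 17 prevalent decoy modules do not.
(The bundled module definitions are synthetic stand-ins; curated
definitions in the same plain-text format are drop-in replacements.)

A CLI mirrors the library (`gutmet synth cohort`, `gutmet nmr pqn|srv|integrate`,
`gutmet opls cv|permtest|mwas`, `gutmet modules abundance|associate`,
`gutmet enterotype fit|pcoa|compare`, `gutmet stats ...`); run
`gutmet --help` for details.

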