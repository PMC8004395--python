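# dietmg — diet–microbiome coupling analysis

`dietmg` is a Python toolkit for studying how habitual diet covaries with the
gut metagenome and with gastrointestinal symptoms, written for microbiome
researchers analysing paired food-diary and shotgun-metagenomic cohorts (the
motivating setting is irritable bowel syndrome, IBS). It implements, as a
tested reusable library:

- **Nutrient-informed food trees.** Food items from a composition database
  are arranged in a 5-level rooted tree (root → five broad classes → database
  hierarchy → nutrient subcategories → items), where the level-5
  subcategories come from a Dirichlet multinomial mixture (DMM) over each
  category's per-100 g nutrient vectors, with the number of components chosen
  by the minimum Laplace approximation to the negative log model evidence.
  Four-day diet diaries become binary leaf-presence profiles compared with
  unweighted UniFrac, d(p,q) = (branch length unique to p or q) / (total
  observed branch length), and summarised by the log2 meat/plant ratio.
- **FSA-NPS diet quality.** Each item scores
  `sum(points for energy kJ, sugars, saturated fat, sodium; 0–10 each) −
  sum(points for fiber, protein, fruit/veg %; 0–5 each)` ∈ [−15, 40],
  mapped to classes A–E (separate drink thresholds); the diet index is the
  energy-weighted mean score of everything consumed. Meal-level quality
  profiles, excess fructose, ±4 SD FODMAP outlier flags and the 800–4500
  kcal/day plausibility screen are included.
- **MSP subspecies calling.** A metagenomic species pangenome (MSP) is
  detected in a sample when its median core-gene coverage exceeds 2;
  accessory genes are called present inside the 2.5–97.5% quantile band of
  that sample's core coverages; samples are clustered on Jaccard distances
  between accessory profiles with partition around medoids, k selected by
  mean silhouette width and validated by subset-bootstrap stability.
- **Ordination and two-table coupling.** √JSD distances between
  subspecies-level metagenomes, classical PCoA with Gower out-of-sample
  projection, PERMANOVA (trace form, continuous or categorical covariates,
  including a per-taxon-node scan with a 2% effect-size filter), co-inertia
  analysis of paired PCoA blocks with the RV coefficient
  RV = tr(XᵀY YᵀX) / √(tr((XᵀX)²)·tr((YᵀY)²)), projection of
  individuals having only one data block, and principal-component regression
  of clinical responses (exhaled H₂/CH₄, symptom severity, meat/plant ratio)
  on the leading co-inertia axes.
- **Functional analysis.** Gene abundances aggregated to CAZy families and
  hydrogenase metal-site groups, CAZotype DMM partitioning with χ² tests
  against enterotypes, |rho| > 0.4 Spearman correlation networks between
  CAZy and hydrogenase families, and two-class Fisher LDA ranking of
  features for severe-vs-control.
- **Synthetic cohorts with planted truth.** Every input — food database,
  diaries, gene counts with an MSP catalog, annotation maps, clinical table —
  can be generated with known latent structure (meat↔plant gradient, food
  quality gradient coupled to severity, disjoint accessory-gene subspecies
  blocks, a gas-metabolism latent coupling one [FeFe] hydrogenase group to
  animal-carbohydrate CAZy families), so every stage is testable end to end.

## Worked example

The library is used from Python; `examples/` holds one short script per
capability. Coupling diet and metagenome on a 150-subject synthetic cohort
(`python examples/04_coinertia_prediction.py`) prints:

```
co-inertia RV coefficient (training): 0.45
axis A1 vs planted meat/plant latent: rho = -0.93
held-out H2/CH4 ratio prediction from the microbiome block: r = 0.66 (p = 2e-07)
```

The RV coefficient measures overall diet–metagenome covariation on the
100-subject training set; the first co-inertia axis aligns with the planted
meat/plant gradient (|rho| = 0.93), and a 5-component regression fitted on
training co-inertia scores predicts the exhaled H₂/CH₄ log-ratio of the 50
held-out subjects projected from their microbiome block alone (Pearson
r = 0.66).

A single thin CLI orchestrates the full pipeline:

```bash
dietmg demo --seed 42 --outdir results_demo
```

runs every stage on a 60-subject synthetic cohort in well under a minute,
deterministically, and reports the co-inertia RV (0.506 at seed 42) plus
held-out prediction correlations for the gas ratio (0.81), severity (0.77)
and meat/plant ratio (0.95), writing all tables, the food tree (newick) and
a parameter manifest to the output directory. `dietmg run --config cfg.yaml`
exposes every threshold (detection median, quantile band, silhouette floor,
correlation threshold, axis counts, energy cutoffs), and
`dietmg validate` schema-checks input files.

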