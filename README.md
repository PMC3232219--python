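# devodiverge

Comparative analysis of developmental gene-expression divergence across
three species (two ingroup hominids plus an outgroup; human, chimpanzee,
macaque by default) and brain regions.

Cross-species expression studies sampled across the lifespan raise a
question a single adult time point cannot answer: is a species difference
*constitutive* — the same offset at every age — or does it reflect
*developmental remodeling*, a change in the shape of the expression-age
trajectory itself?  The two modes have different biology (remodeling
concentrates in tissue-specific, conserved genes and points at
trans-regulation; constitutive divergence tracks cis-regulatory drift), so
this package keeps them strictly separate throughout.

For researchers in comparative transcriptomics, the package provides:

* **Divergence typing** — per gene, polynomial trajectory models on a log2
  age scale and three exactly calibrated nested F-tests (age test, ANCOVA
  differential-expression test, mean-centered pattern test) classify genes
  as type I (constitutive divergence, flat trajectory), type II
  (constitutive divergence, developmental trajectory), or type III
  (developmental remodeling), with permutation-based FDR.
* **Lineage branch statistics** — Euclidean distances between fitted
  trajectories feed the closed-form three-taxon neighbor-joining
  decomposition; R = log2(b_H / b_C) measures human-vs-chimpanzee
  acceleration, summarized by set medians, Wilcoxon signed-rank tests and
  bootstrap CIs (mean-removed distances for type III, so only shape
  divergence counts).
* **Trans-regulator screen** — two-stage candidate calling for miRNAs (or
  TFs, sign-flipped): hypergeometric target enrichment in the focal gene
  set, then a binomial test for an excess of strong negative
  regulator-target trajectory correlations (r < −0.75) over the
  non-enriched background rate, with a label-permutation null for the
  expected number of enriched regulators.
* **Annotation enrichment and sequence associations** — Bonferroni-corrected
  hypergeometric category tests, specificity contrasts with bootstrap CIs,
  Spearman correlations between per-lineage expression divergence and
  sequence scores (conservation, mutation counts, binding-site densities),
  conservation-adjusted binding-site density, expression-distribution
  equalization and mutation-estimate trimming.
* **A synthetic-data generator** — three-species expression-age datasets
  with known ground truth (divergence types, implanted human acceleration
  k, regulators negatively coupled to target sets, sequence-score
  couplings), so every pipeline stage is testable without any downloads.

See `docs/methods.md` for the statistical model and design decisions.

## Worked example

```python
from devodiverge import (
    branch_ratio_stats, build_branch_trees, classify_dataset,
    common_age_grid, fit_species_trajectories, screen_candidates,
)
from devodiverge.synthetic_data import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_type1=100, n_type2=100, n_type3=100, n_null=100,
                      n_coupled=2, n_decoy=20, targets_per_regulator=10,
                      human_acceleration=5.0, seed=7)
bundle = generate_dataset(cfg)

# 1. type every gene from its p-values
calls, table = classify_dataset(bundle.expression, bundle.transform)
print(table["dtype"].value_counts().to_dict())

# 2. human/chimpanzee branch ratio among remodeled genes (shape only)
grid = common_age_grid(bundle.expression.samples, bundle.transform)
models = fit_species_trajectories(bundle.expression, bundle.transform)
t3 = list(table.index[table["dtype"] == "III"])
trees = build_branch_trees(models, grid, remove_mean=True, features=t3)
s = branch_ratio_stats(trees, n_boot=1000, seed=1)
print(f"type III: n={s.n}, median 2^R = {2**s.median_R:.2f}, "
      f"Wilcoxon p = {s.wilcoxon_p:.2e}")

# 3. screen regulators against the remodeled set
background = list(table.index[table["dtype"].isin(["I", "II"])])
models.update(fit_species_trajectories(bundle.regulator_expression, bundle.transform))
results, perm = screen_candidates(
    bundle.regulator_expression.feature_ids, t3, background,
    models, grid, bundle.targets, n_perm=500, seed=2)
print([r.regulator_id for r in results if r.candidate])
```

Output:

```
{'none': 108, 'III': 100, 'II': 97, 'I': 95}
type III: n=100, median 2^R = 5.04, Wilcoxon p = 3.96e-18
['mir-001', 'mir-002']
```

Reading it: all 100 implanted remodeling (type III) genes are recovered
(the 108 "none" calls are dominated by the 100 null genes); the median
human/chimpanzee branch-length ratio among them is 2^R ≈ 5.04, recovering
the implanted five-fold human acceleration with an overwhelmingly
significant Wilcoxon test; and both implanted regulators — and no decoys —
survive the two-stage screen.

The same steps run from the shell:

```bash
devodiverge simulate --seed 7 --out sim/
devodiverge classify --matrix sim/matrix.tsv --meta sim/meta.tsv --out calls.tsv
devodiverge screen --matrix sim/matrix.tsv --mirna-matrix sim/mirna_matrix.tsv \
    --meta sim/meta.tsv --calls calls.tsv --targets sim/targets.tsv --out screen.tsv
```

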