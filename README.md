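# herdclust

Herd clustering from mixed-type social-ecological survey data, and genetic
evaluation of dairy cows with **herd clusters** instead of single herds in
the contemporary-group definition.

## The problem

Local endangered cattle breeds are typically kept in many small family
farms. Genetic evaluation anchors each record in a contemporary group (CG)
- classically the herd-test-day, the set of cows milked in the same herd on
the same recording day - but with three cows per herd a herd-test-day
holds one or two records, the CG effect swallows most of the information,
and breeding-value reliabilities suffer. If herds with similar management,
feeding, housing and social characteristics can be grouped into a few herd
clusters (HCs), the cluster-test-day becomes a better-filled CG that still
represents a homogeneous environment.

`herdclust` implements both halves of that idea:

1. **Herd clustering.** A survey with quantitative, nominal, ordinal and
   (a)symmetric binary variables is turned into a Gower dissimilarity
   matrix, d(i,j) = Σₖ wₖ δᵢⱼₖ dᵢⱼₖ / Σₖ wₖ δᵢⱼₖ, and clustered with four
   competing strategies - Ward agglomerative clustering (AHC),
   partitioning around medoids (PAM), fuzzy clustering (FZC), and
   clustering-of-variables followed by AHC on the synthetic variables
   (CoVAHC). The winning configuration (method, number of clusters k) is
   the one maximizing the average silhouette width,
   ASW = mean of s(i) = (b(i) − a(i)) / max(a(i), b(i)), over k = 2..10.
2. **Genetic evaluation.** A pedigree repeatability test-day model,
   y = μ + B + YS + L + CG + f(DIM) + b·CA + a + pe + e with
   a ~ N(0, σ²ₐA) and a third-order Legendre regression f on days in milk,
   is solved by Henderson's mixed-model equations; variance components come
   from EM-REML, and reliabilities r² = 1 − PEV/σ²ₐ are compared across the
   four CG schemes HTD / HCTD / HTM / HCTM (herd or herd-cluster, crossed
   with test day or test month).

A seed-deterministic synthetic-data module generates all four inputs
(survey, pedigree, test-day records, fertility records) with planted
cluster structure and known variance components, so every claim the
package makes is testable. `docs/methods.md` has the full model
description and numerical choices.

## Worked example

```python
import numpy as np
from herdclust import (SurveySimConfig, simulate_survey, edit_variables,
                       asw_sweep)

survey, truth = simulate_survey(SurveySimConfig(seed=1))
edited, removed = edit_variables(survey)
print(f"{survey.values.shape[1]} variables surveyed, "
      f"{len(edited.specs)} kept after editing ({len(removed)} removed)")

sweep = asw_sweep(edited, seed=1)
method, k = sweep.selected
print(f"selected: {method} with k={k} herd clusters "
      f"(ASW={sweep.table.loc[method, k]:.3f})")
part = sweep.selected_partition().relabel_by_size()
print("cluster sizes:", np.bincount(part.labels).tolist())
```

prints

```
117 variables surveyed, 106 kept after editing (11 removed)
selected: ahc with k=4 herd clusters (ASW=0.534)
cluster sizes: [13, 11, 5, 1]
```

The generator planted 4 clusters of sizes 13/5/1/11 among 30 herds plus 11
removable (constant/duplicated) columns; the editing step removed exactly
those 11, the sweep picked k = 4, and the selected partition reproduces
the planted sizes. (At this separation the four methods produce the same
partition, so their ASW ties and the tie-break chooses by method order.)

Feeding the selected clusters into the genetic evaluation on sparse
simulated herds (300 cows in 25 herds, a median of ~3 records per
herd-test-day, cluster-shared environments):

```python
from herdclust import (GeneticSimConfig, simulate_pedigree,
                       simulate_test_days, compare_cg_models,
                       VarianceComponents)

cfg = GeneticSimConfig(seed=1, n_sires=15, daughters_per_sire=20,
                       n_herds=25, cluster_env_sd=2.0, herd_env_sd=0.5)
ped, bv = simulate_pedigree(cfg)
records, herd_clusters, _ = simulate_test_days(ped, bv, cfg)
table, _ = compare_cg_models(records, ped, herd_clusters,
                             schemes=("HTD", "HCTD"),
                             vc=VarianceComponents(3.0, 2.0, 5.0))
print(table[["n_cg_raw", "n_cg", "mean_cg_occupancy",
             "rel_mean_all", "rel_mean_sires"]].round(3))
```

```
        n_cg_raw  n_cg  mean_cg_occupancy  rel_mean_all  rel_mean_sires
scheme
HTD          447   274              4.544         0.449           0.646
HCTD         400   252              5.083         0.458           0.652
```

Replacing herds by herd clusters generates fewer, better-filled
contemporary groups (447 → 400 generated; mean occupancy 4.5 → 5.1
records) and raises mean breeding-value reliability both for the whole
population (0.449 → 0.458) and for sires with daughter records
(0.646 → 0.652).

## Command line

```bash
herdclust simulate --seed 1 --out inputs/          # write synthetic inputs
herdclust evaluate --survey inputs/survey.csv --specs inputs/specs.yaml --out run/
herdclust genetics --records inputs/testday.csv --pedigree inputs/pedigree.csv \
                   --partition run/selected_partition.csv --out run/
herdclust full --out run/                          # the whole pipeline
```

All tabular I/O is CSV; variable types live in a YAML sidecar. Reruns with
the same seed write byte-identical outputs.

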