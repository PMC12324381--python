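# bristlekit

Quantify and classify the spatial organisation of spot patterns in
developing tissues — built for the sensory-bristle (microchaete)
precursor patterns on the *Drosophila* dorsal thorax, and applicable
to any 2-D point cloud with local density structure.

Developmental patterning is stochastic at the cell level yet produces
reproducible tissue-scale arrangements, and beyond overall density it
is not obvious how to compare such patterns quantitatively. Starting
from per-tissue centroid tables (x, y in microns) and tissue areas,
`bristlekit` computes five global features per tissue:

| Feature | Meaning |
|---|---|
| RSA | relative sensory area, `N · a_cell / A` (density; default cell area 24.5 μm²) |
| CN  | number of DBSCAN clusters at the tissue's optimal (ε, MinPts) |
| OP  | outlier prevalence — fraction of cells in no cluster |
| CQ  | cluster quality — the pattern silhouette score `(1/N) Σ S(i)` |
| CSV | cluster size variance — `(1/(K−1)) Σ ((η_i − η̄)/N)²` |

Clustering uses an in-package DBSCAN with fully deterministic
tie-breaking; (ε, MinPts) are tuned per tissue by maximising the
pattern silhouette score over a scale-free grid. Downstream, the
package provides the comparison stack a perturbation screen needs —
Kruskal–Wallis and paired Mann–Whitney tests, nested logistic
regressions compared by likelihood-ratio tests, and a grid-searched
SVM that bounds a *wild-type patterning region* in control-scaled
feature space, from which each perturbation's penetrance (fraction of
tissues outside the region) is read off. A synthetic-pattern generator
(hard-core sequential inhibition with row structure and block density
heterogeneity) makes the whole pipeline testable without microscopy
data.

## Worked example

```python
from bristlekit import (
    PatternFeaturizer, Cohort, SVMGridSpec,
    simulate_cohort, feature_selection_report, train_boundary, penetrance,
)

patterns, pairing = simulate_cohort(
    {"wildtype": ("wildtype", 40), "dense_heterogeneous": ("dense_heterogeneous", 40)},
    master_seed=1,
)
table = PatternFeaturizer().fit_transform(patterns)
cohort = Cohort(features=table, pairing=pairing)

wt = table[table.group == "wildtype"]
print(wt[["RSA", "CN", "OP", "CQ", "CSV"]].mean().round(4))

report = feature_selection_report(cohort, "dense_heterogeneous")
print(report.univariate[["feature", "p_value"]])

model = train_boundary(
    cohort, {"wildtype": 0, "dense_heterogeneous": 1}, spec=SVMGridSpec(split_seed=1)
)
print("held-out accuracy:", model.test_accuracy)
print("penetrance:", penetrance(model, cohort, "dense_heterogeneous"))
```

Output:

```
RSA     0.0279
CN     11.8000
OP      0.2231
CQ      0.4248
CSV     0.0013
dtype: float64
  feature       p_value
0     RSA  1.413485e-14
1      CN  6.851414e-05
2      OP  3.388297e-03
3      CQ  9.348127e-01
4     CSV  1.335954e-10
held-out accuracy: 1.0
penetrance: 1.0
```

Reading: synthetic wild-type tissues cluster into row segments with
about 22% of cells unclustered and a pattern silhouette of ~0.42. The
perturbed group (1.8× density, 3× block heterogeneity) differs most
strongly in RSA and CSV (cluster quality barely moves); on those two
features the SVM separates the groups perfectly on held-out tissues,
and every perturbed tissue falls outside the wild-type region
(penetrance 1.0).

The same pipeline is scriptable from the shell for cohorts on disk:

```bash
bristlekit simulate --out cohort/ --seed 1 --preset wildtype=40 --preset dense_heterogeneous=40
bristlekit features --manifest cohort/manifest.csv --out features.csv
bristlekit compare  --features features.csv --pairing cohort/pairing.csv --out-dir reports/
bristlekit region   --features features.csv --pairing cohort/pairing.csv --out-dir region/
```

Real data enter through the same door: a manifest
(`pattern_id,group,tissue_area_um2,centroid_file`) pointing at plain
`x_um,y_um` tables or ImageJ "Results" exports (`X,Y` columns), plus a
`pairing.csv` mapping each mutant group to its control.

See `docs/methods.md` for the model details, parameter defaults, what
the synthetic generator does and does not emulate, and known
limitations.

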