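# alloatlas

Spatially resolved single-cell analysis of allograft imaging mass cytometry
(IMC). Liver transplant biopsies carry three clinically distinct states —
no rejection (NR), acute T-cell mediated rejection (TCMR) and chronic
rejection (CR) — and multiplexed imaging of a 22-marker panel turns each
~1 mm² region of interest (ROI) into a table of segmented cells with
per-marker intensities and µm coordinates. `alloatlas` implements the
analysis layer between that table and the biology, for computational
pathologists and transplant immunologists:

* **Phenotyping** — intensities are stabilized as `asinh(x / 5)` and
  z-scored per channel; an ordered, declarative gating hierarchy (first
  match wins, hepatocytes by exclusion) assigns 10 metaclusters and
  refines the key immune compartments into 30 subclusters, 41 final
  labels; per-patient composition features follow.
* **Spatial statistics** — on a directed 10-nearest-neighbor graph per
  ROI: a stratified permutation test for pairwise attraction/avoidance
  (`p = (1 + #{null ≥ obs}) / (1 + n_perm)`, two one-sided calls at
  α = 0.01), k-means cellular neighborhoods over neighbor-composition
  profiles, and distance-to-endothelium profiles.
* **Trajectory orientation** — per compartment: 2-D embedding, coarse
  k-means, root = cluster with the highest NR fraction, lineages as
  root-to-leaf paths of the centroid minimum spanning tree, pseudotime by
  arc-length projection.
* **Group testing** — Shapiro-Wilk-gated choice between ANOVA/t-tests and
  Kruskal-Wallis/Wilcoxon, with Holm correction over each feature's
  pairwise family.
* **Predictive modeling** — L1-penalized logistic regression
  (cross-validated penalty on a 100-point path from the analytic
  λ_max), bootstrap stability selection (5,000 resamples, keep features
  with ≥ 50% non-zero frequency), and 1,000 stratified 75/25 splits
  reporting sensitivity/specificity/accuracy/AUC, averaged coefficients,
  per-patient median predictions and their Spearman association with
  outcome.
* **Synthetic cohorts** — a first-class generator (log-normal expression
  templates derived from the gating rules; Neyman-Scott co-aggregation;
  planted neighborhood motif blocks; group-dependent composition shifts)
  so every stage is testable end to end with known ground truth.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
import alloatlas as aa

cfg = aa.default_cohort_config({"NR": 6, "TCMR": 6, "CR": 6}, cells_per_roi=800, seed=0)
table, truth = aa.generate_cohort(cfg)
std = aa.preprocess(table)                        # asinh(x/5), then per-channel z-score
assignment = aa.assign_phenotypes(std, aa.default_ruleset())

acc = (assignment["final"].to_numpy() == truth.cells["true_label"].to_numpy()).mean()
print(f"cells: {len(table)}, gating accuracy vs ground truth: {acc:.3f}")

graphs = aa.build_graphs(table, k=10)
res = aa.test_interactions_by_group(graphs, assignment["final"], table,
                                    n_perm=200, alpha=0.01, seed=0)
sig = res[res["call"] != "none"]
print(f"significant ordered pairs: {len(sig)} of {res['observed'].notna().sum()} tested")

props = aa.compute_proportions(assignment, table, "all_cells", level="final")
tests = aa.test_features(props)
hit = tests[(tests["feature"] == "PD1+ CD4 T-cells") & (tests["comparison"] == "NR vs TCMR")].iloc[0]
print(f"PD1+ CD4 T-cells, NR vs TCMR: {hit['test']}, Holm-adjusted p = {hit['p_holm']:.4f}")
```

prints

```text
cells: 14409, gating accuracy vs ground truth: 0.998
significant ordered pairs: 780 of 5043 tested
PD1+ CD4 T-cells, NR vs TCMR: two-sample t, Holm-adjusted p = 0.0409
```

14,409 synthetic cells gate back to their generating labels at 99.8%
accuracy; 780 of 5,043 testable ordered label pairs are called attraction
or avoidance (the generator plants both co-aggregation and motif
structure, so far more than the 2α null rate is expected); and the planted
TCMR enrichment of PD1+ CD4 T-cells is recovered as a Holm-significant
group difference.

The same pipeline runs from the shell (`alloatlas run-all --config
pipeline.yaml --seed 17 --out run_dir`, with per-stage subcommands `synth`,
`phenotype`, `stats`, `spatial`, `trajectory`, `predict`); a run directory
contains per-stage CSV tables with schema headers, `model_report.json` and
a `manifest.json` of content hashes — reruns with the same seed are
byte-identical.

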