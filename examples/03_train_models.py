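"""Train and evaluate the candidate models for one drug.

70/30 split, correlation-based feature selection on the training cells,
lasso/ridge tuned by 5-fold CV and a random forest tuned by OOB error; the
best trainer predicts the held-out cells.
"""

from diffsen import SimConfig, simulate_cohort, within_dataset_run

cohort = simulate_cohort(SimConfig(
    n_cells_per_dataset=150, n_datasets=1, n_transporters=150,
    n_targets=1, drugs_per_target=3, planted_per_drug=3,
    effect_size_beta=2.0, seed=3,
))
dataset = cohort.datasets[0]
drug = cohort.drugs[0]

result = within_dataset_run(
    drug, dataset.name, dataset.sensitivity, dataset.silencing,
    dataset.features, k=50, seed=13,
)

print(f"drug {result.drug_id}  (train {result.n_train_cells} cells, "
      f"test {result.n_test_cells} cells)")
print(f"winning family: {result.model_family}  {result.hyperparameters}")
print(f"training CV score (Pearson r): {result.cv_score:.3f}")
print(f"held-out performance: r = {result.test_r:.3f}, p = {result.test_p:.2e}")
print(f"successful model (p < 0.05): {result.success}")

planted = set(cohort.truth.planted_transporters[drug.drug_id])
selected_planted = planted & set(result.selection.selected)
print(f"\nplanted transporters among the {len(result.selection.selected)} "
      f"selected features: {len(selected_planted)}/{len(planted)} "
      f"({sorted(selected_planted)})")
print("A successful model means held-out DiffSen is predictable from")
print("transporter features - the signature of transporter-driven resistance.")
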