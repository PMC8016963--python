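"""Simulate a two-dataset cohort with planted transporter-mediated resistance.

Builds 2 partially overlapping cell-line panels in which, for each drug,
known ("planted") transporters drive resistance to it, then prints the
design so you can see exactly what downstream stages should recover.
"""

from diffsen import SimConfig, simulate_cohort

config = SimConfig(
    n_cells_per_dataset=100,   # cell lines per dataset
    n_datasets=2,
    overlap_fraction=0.5,      # half the panel is shared between datasets
    n_transporters=100,        # transporter expression features
    n_genetic_features=10,     # binary mutation/CNV-style flags (all null)
    n_targets=2,
    drugs_per_target=3,
    planted_per_drug=2,        # transporters truly driving resistance
    effect_size_beta=2.0,      # strength of the planted effect
    dependency_weight_alpha=1.0,
    noise_sd=1.0,
    seed=1,
)
cohort = simulate_cohort(config)

print(f"drugs: {len(cohort.drugs)}, datasets: {len(cohort.datasets)}")
print(f"cells shared by both datasets: {len(cohort.truth.shared_cells)}")
for ds in cohort.datasets:
    print(f"  {ds.name}: sensitivity {ds.sensitivity.shape}, "
          f"silencing {ds.silencing.shape}, features {ds.features.shape}")
print("\nplanted truth (drug -> transporter: weight):")
for drug in cohort.drugs[:3]:
    planted = cohort.truth.planted_transporters[drug.drug_id]
    pretty = ", ".join(f"{t}: {w:.2f}" for t, w in sorted(planted.items()))
    print(f"  {drug.drug_id} (target {drug.targets[0]}): {pretty}")
print("...")
print("\nDrugs sharing a target share their planted set (analog series); the")
print("pipeline's job is to re-identify these transporters from the data alone.")
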