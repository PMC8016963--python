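import numpy as np
import pandas as pd
import pytest

from diffsen import (
    ConfigError,
    SimConfig,
    compute_diffsen,
    read_matrix,
    read_truth,
    simulate_cohort,
    simulate_fingerprints,
    tanimoto,
    write_cohort,
)


def _small(**kw):
    base = dict(
        n_cells_per_dataset=50, n_datasets=2, overlap_fraction=0.5,
        n_transporters=30, n_genetic_features=3, n_targets=2,
        drugs_per_target=3, planted_per_drug=2, effect_size_beta=2.0,
        noise_sd=1.0, seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerator:
    def test_seeded_runs_are_bit_identical(self):
        a = simulate_cohort(_small())
        b = simulate_cohort(_small())
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.sensitivity, db.sensitivity)
            pd.testing.assert_frame_equal(da.silencing, db.silencing)
            pd.testing.assert_frame_equal(da.features, db.features)
        assert a.truth.planted_transporters == b.truth.planted_transporters

    def test_drug_and_target_counts(self):
        cohort = simulate_cohort(_small(n_targets=2, drugs_per_target=3))
        assert len(cohort.drugs) == 6
        assert all(len(d.targets) == 1 for d in cohort.drugs)

    def test_two_target_drugs_average_dependencies(self):
        cohort = simulate_cohort(_small(n_two_target_drugs=2))
        two = [d for d in cohort.drugs if len(d.targets) == 2]
        assert len(two) == 2
        groups = cohort.truth.structure_groups
        for d in two:  # singleton structure groups
            gid = [g for g, mem in groups.items() if d.drug_id in mem]
            assert len(gid) == 1 and groups[gid[0]] == [d.drug_id]

    def test_structure_groups_partition_drugs(self, tiny_cohort):
        members = [d for grp in tiny_cohort.truth.structure_groups.values() for d in grp]
        assert sorted(members) == sorted(d.drug_id for d in tiny_cohort.drugs)

    def test_planted_transporters_exist_in_features(self, tiny_cohort):
        feature_ids = set(tiny_cohort.datasets[0].features.index)
        for planted in tiny_cohort.truth.planted_transporters.values():
            assert set(planted) <= feature_ids

    def test_designed_overlap(self):
        cohort = simulate_cohort(_small(overlap_fraction=0.5))
        cells1 = set(cohort.datasets[0].features.columns)
        cells2 = set(cohort.datasets[1].features.columns)
        assert cells1 & cells2 == set(cohort.truth.shared_cells)
        assert len(cohort.truth.shared_cells) == 25

    def test_beta_zero_breaks_transporter_association(self):
        """Without a planted effect the differential carries no transporter
        signal: the mean planted-transporter correlation is ~0."""
        cohort = simulate_cohort(_small(effect_size_beta=0.0,
                                        n_cells_per_dataset=150, seed=21))
        ds = cohort.datasets[0]
        rs = []
        for drug in cohort.drugs:
            vec = compute_diffsen(drug, ds.sensitivity, ds.silencing).to_series()
            for t in cohort.truth.planted_transporters[drug.drug_id]:
                expr = ds.features.loc[t, vec.index]
                rs.append(np.corrcoef(expr, vec)[0, 1])
        assert abs(float(np.mean(rs))) < 0.1

    def test_stronger_beta_strengthens_association(self):
        """Monotonicity: expected |corr(planted expression, DiffSen)|
        increases with the planted effect size (50-seed Monte-Carlo)."""
        means = {}
        for beta in (0.0, 1.0, 2.0):
            vals = []
            for seed in range(50):
                cohort = simulate_cohort(_small(
                    effect_size_beta=beta, n_datasets=1, n_cells_per_dataset=60,
                    n_transporters=20, seed=1000 + seed,
                ))
                ds = cohort.datasets[0]
                drug = cohort.drugs[0]
                vec = compute_diffsen(drug, ds.sensitivity, ds.silencing).to_series()
                for t in cohort.truth.planted_transporters[drug.drug_id]:
                    expr = ds.features.loc[t, vec.index]
                    vals.append(abs(np.corrcoef(expr, vec)[0, 1]))
            means[beta] = float(np.mean(vals))
        assert means[0.0] < means[1.0] < means[2.0]

    @pytest.mark.parametrize(
        "field,value",
        [
            ("overlap_fraction", 1.5),
            ("drugs_per_target", 2),
            ("n_transporters", 0),
            ("effect_size_beta", -1.0),
            ("noise_sd", 0.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            simulate_cohort(_small(**{field: value}))


class TestFingerprintSimulation:
    def test_within_sim_one_gives_identical_bits(self, tiny_cohort):
        fps = simulate_fingerprints(
            tiny_cohort.drugs, tiny_cohort.truth.structure_groups,
            within_sim=1.0, between_sim=0.0, seed=3,
        )
        g0 = tiny_cohort.truth.structure_groups["G00"]
        assert fps[g0[0]].bits == fps[g0[1]].bits
        assert tanimoto(fps[g0[0]], fps[g0[1]]) == 1.0

    def test_between_sim_zero_gives_disjoint_bits(self, tiny_cohort):
        fps = simulate_fingerprints(
            tiny_cohort.drugs, tiny_cohort.truth.structure_groups,
            within_sim=0.6, between_sim=0.0, seed=3,
        )
        a = tiny_cohort.truth.structure_groups["G00"][0]
        b = tiny_cohort.truth.structure_groups["G01"][0]
        assert not fps[a].bits & fps[b].bits
        assert tanimoto(fps[a], fps[b]) == 0.0

    def test_mean_within_similarity_near_target(self):
        """100 replicate pairs: the generator hits its own similarity target."""
        from diffsen.io import DrugRecord

        drugs = [DrugRecord(f"d{i}", f"d{i}", ["T"]) for i in range(200)]
        groups = {f"g{i}": [f"d{2*i}", f"d{2*i+1}"] for i in range(100)}
        fps = simulate_fingerprints(drugs, groups, within_sim=0.6,
                                    between_sim=0.05, seed=8)
        sims = [tanimoto(fps[g[0]], fps[g[1]]) for g in groups.values()]
        assert abs(float(np.mean(sims)) - 0.6) < 0.1

    def test_empty_group_rejected(self, tiny_cohort):
        with pytest.raises(ConfigError):
            simulate_fingerprints(tiny_cohort.drugs, {"g": []}, seed=0)


class TestWriteCohort:
    def test_round_trip_and_manifest(self, tiny_cohort, tmp_path):
        fps = simulate_fingerprints(
            tiny_cohort.drugs, tiny_cohort.truth.structure_groups, seed=2
        )
        manifest = write_cohort(tiny_cohort, tmp_path, fingerprints=fps)
        assert len(manifest["datasets"]) == 2
        for entry, ds in zip(manifest["datasets"], tiny_cohort.datasets):
            for kind in ("sensitivity", "silencing", "features"):
                back = read_matrix(tmp_path / entry[kind])
                pd.testing.assert_frame_equal(back, getattr(ds, kind))
        truth = read_truth(tmp_path / manifest["truth"])
        assert truth.planted_transporters == tiny_cohort.truth.planted_transporters
        assert truth.structure_groups == tiny_cohort.truth.structure_groups
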