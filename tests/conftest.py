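from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from diffsen import (
    SimConfig,
    load_config,
    run_pipeline,
    simulate_cohort,
    simulate_fingerprints,
    write_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two small overlapping datasets with planted transporter effects."""
    cfg = SimConfig(
        n_cells_per_dataset=80,
        n_datasets=2,
        overlap_fraction=0.4,
        n_transporters=80,
        n_genetic_features=5,
        n_targets=2,
        drugs_per_target=3,
        planted_per_drug=2,
        effect_size_beta=2.0,
        dependency_weight_alpha=1.0,
        noise_sd=1.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """A written cohort plus two identical full pipeline runs on it.

    Shared by the report-content tests and the determinism check so the
    expensive run-all happens exactly twice in the whole suite.
    """
    root = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(
        n_cells_per_dataset=60,
        n_datasets=2,
        overlap_fraction=0.4,
        n_transporters=60,
        n_genetic_features=4,
        n_targets=2,
        drugs_per_target=3,
        planted_per_drug=2,
        effect_size_beta=2.0,
        seed=29,
    )
    cohort = simulate_cohort(cfg)
    fps = simulate_fingerprints(cohort.drugs, cohort.truth.structure_groups, seed=29)
    write_cohort(cohort, root, fingerprints=fps)
    config = load_config(root / "run_config.yaml")
    out1, out2 = root / "out1", root / "out2"
    rep1 = run_pipeline(config, out_dir=out1)
    rep2 = run_pipeline(config, out_dir=out2)
    return SimpleNamespace(
        cohort=cohort, dir=root, config=config,
        out1=out1, out2=out2, rep1=rep1, rep2=rep2,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def labeled_matrix():
    """A 3x4 matrix with one missing value, in the io contract."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.5, np.nan, 1.5, 2.5], [-1.0, 0.0, 1.0, 2.0]],
        index=["r1", "r2", "r3"],
        columns=["ca", "cb", "cc", "cd"],
    )
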