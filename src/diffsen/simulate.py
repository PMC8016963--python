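"""Synthetic multi-dataset cohorts with planted transporter-mediated resistance.

The generator emulates the study design the pipeline is built for: two or
three drug-sensitivity "datasets" (think CTD2 / PRISM / GDSC) profiling
partially overlapping cell-line panels, each with a matched gene-silencing
viability screen and a feature matrix of transporter expression plus binary
genetic flags.

Generative law (all matrices viability-oriented, higher = more resistant):

* expression  E(t,c) = exp(mu_t + lineage_shift(l(c),t) + N(0, 0.8)),
  lognormal-like with per-lineage shifts; datasets remeasure it with small
  lognormal noise;
* silencing   v(g,c) = gain_k * (D(g,c) + N(0, noise_sd)) + offset_k, where
  D(g,c) ~ N(0,1) is the cell-intrinsic latent dependency on target g;
* sensitivity s(d,c) = gain_k * (alpha * Dep_d(c) + beta * P_d(c)
                        + N(0, noise_sd)) + offset_k,
  with Dep_d the drug's target dependency (two-target drugs: the average of
  the two latent dependencies) and P_d = sum_t w_t * zscore(E(t,.)) the
  planted transporter effect (unit-variance weight vector).

Planted transporters are drawn per *structure group* (drugs sharing a
target), mirroring analog series that share efflux liabilities; the truth
object records every planted effect so downstream stages can be tested for
parameter recovery.  Runs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import Fingerprint
from .exceptions import ConfigError
from .io import DrugRecord, write_lineages, write_matrix

DEFAULT_LINEAGES = ("lung", "breast", "skin", "colon")
#: per-dataset (gain, offset) defaults, emulating AUC-vs-viability scale gaps
DEFAULT_DATASET_SCALE = ((1.0, 0.0), (1.6, 0.25), (0.7, -0.1))


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic cohort."""

    n_cells_per_dataset: int = 200
    n_datasets: int = 2
    overlap_fraction: float = 0.5
    n_transporters: int = 300
    n_genetic_features: int = 20
    n_targets: int = 5
    drugs_per_target: int = 4
    n_two_target_drugs: int = 0
    planted_per_drug: int = 3
    effect_size_beta: float = 2.0
    dependency_weight_alpha: float = 1.0
    noise_sd: float = 1.0
    feature_noise_sd: float = 0.1
    lineage_shift_sd: float = 0.5
    dataset_scale: tuple[tuple[float, float], ...] | None = None
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    seed: int = 0

    def validate(self) -> None:
        def positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

        for name in ("n_cells_per_dataset", "n_datasets", "n_transporters",
                     "n_targets", "noise_sd"):
            positive(name)
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigError(
                f"overlap_fraction must be in [0,1], got {self.overlap_fraction}"
            )
        if self.drugs_per_target < 3:
            raise ConfigError(
                f"drugs_per_target must be >= 3 (the fewer-than-three target "
                f"filter must be satisfiable), got {self.drugs_per_target}"
            )
        for name in ("n_genetic_features", "n_two_target_drugs", "planted_per_drug"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.effect_size_beta < 0:
            raise ConfigError(f"effect_size_beta must be non-negative, got {self.effect_size_beta}")
        if self.planted_per_drug > self.n_transporters:
            raise ConfigError("planted_per_drug exceeds n_transporters")
        if self.n_two_target_drugs and self.n_targets < 2:
            raise ConfigError("n_two_target_drugs requires n_targets >= 2")
        if len(self.lineages) < 1:
            raise ConfigError("lineages must be non-empty")
        if self.dataset_scale is not None and len(self.dataset_scale) < self.n_datasets:
            raise ConfigError("dataset_scale must provide (gain, offset) per dataset")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort: what was planted where."""

    planted_transporters: dict[str, dict[str, float]]  # drug -> {transporter: w}
    true_alpha: dict[str, float]
    true_beta: dict[str, float]
    structure_groups: dict[str, list[str]]  # group id -> member drugs
    shared_cells: list[str]  # the core cell lines present in every dataset

    def validate(self, feature_ids: set[str], drug_ids: set[str]) -> None:
        for drug, planted in self.planted_transporters.items():
            missing = set(planted) - feature_ids
            if missing:
                raise ConfigError(
                    f"planted transporters {sorted(missing)} of drug {drug!r} "
                    "absent from the feature matrix"
                )
        members = [d for grp in self.structure_groups.values() for d in grp]
        if len(members) != len(set(members)) or set(members) != drug_ids:
            raise ConfigError("structure_groups is not a partition of the drugs")


@dataclass
class SimDataset:
    name: str
    sensitivity: pd.DataFrame
    silencing: pd.DataFrame
    features: pd.DataFrame
    lineages: pd.Series


@dataclass
class SyntheticCohort:
    datasets: list[SimDataset]
    drugs: list[DrugRecord]
    truth: SyntheticTruth
    config: SimConfig = field(repr=False, default=None)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a multi-dataset cohort under the planted-resistance model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells_per_dataset
    n_shared = int(round(config.overlap_fraction * n))

    # cell universe: a core shared by every dataset plus per-dataset unique cells
    counter = 0

    def new_cells(k):
        nonlocal counter
        ids = [f"CL{counter + i:04d}" for i in range(k)]
        counter += k
        return ids

    core = new_cells(n_shared)
    per_dataset_cells = []
    for _ in range(config.n_datasets):
        per_dataset_cells.append(core + new_cells(n - n_shared))
    all_cells = [f"CL{i:04d}" for i in range(counter)]
    cell_pos = {c: i for i, c in enumerate(all_cells)}
    n_all = len(all_cells)

    lineage_of = rng.choice(len(config.lineages), size=n_all)
    lineages = pd.Series(
        [config.lineages[i] for i in lineage_of], index=all_cells, name="lineage"
    )

    transporters = [f"TSPT{i:03d}" for i in range(config.n_transporters)]
    genetic = [f"MUT{i:03d}" for i in range(config.n_genetic_features)]
    targets = [f"TGT{i:02d}" for i in range(config.n_targets)]

    # latent log-expression with lineage shifts; lognormal on the natural scale
    mu = rng.normal(2.0, 0.5, size=config.n_transporters)
    shift = rng.normal(
        0.0, config.lineage_shift_sd, size=(len(config.lineages), config.n_transporters)
    )
    log_expr = (
        mu[None, :] + shift[lineage_of, :] + rng.normal(0.0, 0.8, size=(n_all, config.n_transporters))
    ).T  # transporters x cells
    expr_z = np.vstack([_zscore(np.exp(row)) for row in log_expr])

    # binary genetic flags, cell-intrinsic
    q = rng.uniform(0.05, 0.5, size=config.n_genetic_features)
    genetic_vals = (rng.uniform(size=(config.n_genetic_features, n_all)) < q[:, None]).astype(float)

    # latent dependency per target gene, cell-intrinsic
    dependency = rng.normal(0.0, 1.0, size=(config.n_targets, n_all))

    # drugs and structure groups (analog series per target; two-target drugs
    # are their own singleton groups)
    drugs: list[DrugRecord] = []
    groups: dict[str, list[str]] = {}
    drug_targets: dict[str, list[int]] = {}
    idx = 0
    for ti in range(config.n_targets):
        gid = f"G{ti:02d}"
        groups[gid] = []
        for _ in range(config.drugs_per_target):
            did = f"D{idx:03d}"
            drugs.append(DrugRecord(drug_id=did, name=f"drug-{idx}", targets=[targets[ti]]))
            drug_targets[did] = [ti]
            groups[gid].append(did)
            idx += 1
    for j in range(config.n_two_target_drugs):
        did = f"D{idx:03d}"
        t1, t2 = rng.choice(config.n_targets, size=2, replace=False)
        drugs.append(
            DrugRecord(drug_id=did, name=f"drug-{idx}", targets=[targets[t1], targets[t2]])
        )
        drug_targets[did] = [int(t1), int(t2)]
        groups[f"G2T{j:02d}"] = [did]
        idx += 1

    # planted transporters per structure group, shared by the group's drugs
    planted: dict[str, dict[str, float]] = {}
    group_planted: dict[str, dict[str, float]] = {}
    for gid in sorted(groups):
        if config.planted_per_drug == 0:
            group_planted[gid] = {}
        else:
            chosen = rng.choice(
                config.n_transporters, size=config.planted_per_drug, replace=False
            )
            w = np.abs(rng.normal(1.0, 0.25, size=config.planted_per_drug))
            w = w / np.linalg.norm(w)  # unit variance of the planted combination
            group_planted[gid] = {
                transporters[int(t)]: float(wi) for t, wi in zip(chosen, w)
            }
        for did in groups[gid]:
            planted[did] = dict(group_planted[gid])

    # planted effect P_d(c) over the full cell universe
    tr_pos = {t: i for i, t in enumerate(transporters)}
    planted_effect = {}
    for did, pw in planted.items():
        if pw:
            planted_effect[did] = sum(
                w * expr_z[tr_pos[t]] for t, w in pw.items()
            )
        else:
            planted_effect[did] = np.zeros(n_all)

    scale = config.dataset_scale
    if scale is None:
        scale = tuple(
            DEFAULT_DATASET_SCALE[k % len(DEFAULT_DATASET_SCALE)]
            for k in range(config.n_datasets)
        )

    alpha, beta = config.dependency_weight_alpha, config.effect_size_beta
    datasets: list[SimDataset] = []
    for k in range(config.n_datasets):
        name = f"ds{k + 1}"
        cells = per_dataset_cells[k]
        pos = np.array([cell_pos[c] for c in cells])
        gain, offset = scale[k]

        sil = dependency[:, pos] + rng.normal(0.0, config.noise_sd, size=(config.n_targets, len(cells)))
        silencing = pd.DataFrame(gain * sil + offset, index=targets, columns=cells)

        rows = []
        for d in drugs:
            tlist = drug_targets[d.drug_id]
            dep = dependency[tlist, :][:, pos].mean(axis=0)
            s = alpha * dep + beta * planted_effect[d.drug_id][pos]
            s = s + rng.normal(0.0, config.noise_sd, size=len(cells))
            rows.append(gain * s + offset)
        sensitivity = pd.DataFrame(
            np.vstack(rows), index=[d.drug_id for d in drugs], columns=cells
        )

        meas = np.exp(
            log_expr[:, pos] + rng.normal(0.0, config.feature_noise_sd,
                                          size=(config.n_transporters, len(cells)))
        )
        features = pd.DataFrame(
            np.vstack([meas, genetic_vals[:, pos]]) if config.n_genetic_features
            else meas,
            index=transporters + genetic,
            columns=cells,
        )
        datasets.append(
            SimDataset(
                name=name,
                sensitivity=sensitivity,
                silencing=silencing,
                features=features,
                lineages=lineages[cells],
            )
        )
        for d in drugs:
            d.datasets.add(name)

    truth = SyntheticTruth(
        planted_transporters=planted,
        true_alpha={d.drug_id: alpha for d in drugs},
        true_beta={d.drug_id: beta for d in drugs},
        structure_groups=groups,
        shared_cells=list(core),
    )
    truth.validate(
        feature_ids=set(transporters) | set(genetic),
        drug_ids={d.drug_id for d in drugs},
    )
    return SyntheticCohort(datasets=datasets, drugs=drugs, truth=truth, config=config)


def simulate_fingerprints(
    drug_table: list[DrugRecord],
    structure_groups: dict[str, list[str]],
    within_sim: float = 0.6,
    between_sim: float = 0.05,
    seed: int = 0,
    bits_per_drug: int = 128,
) -> dict[str, Fingerprint]:
    """Synthetic fingerprints realizing designed Tanimoto similarities.

    Every drug receives ``bits_per_drug`` bits composed of a global
    background set (shared by all drugs), a group core set (shared within a
    structure group) and a private set, sized so that the within-group
    Tanimoto equals ``within_sim`` and the between-group Tanimoto equals
    ``between_sim`` up to integer rounding.  ``within_sim = 1`` yields
    identical sets within a group; ``between_sim = 0`` yields disjoint sets
    across groups.
    """
    if not structure_groups or any(not members for members in structure_groups.values()):
        raise ConfigError("structure_groups must be non-empty groups of drugs")
    if not 0.0 <= between_sim <= within_sim <= 1.0:
        raise ConfigError(
            f"need 0 <= between_sim <= within_sim <= 1, got "
            f"({between_sim}, {within_sim})"
        )
    known = {d.drug_id for d in drug_table}
    members_all = [d for grp in structure_groups.values() for d in grp]
    unknown = set(members_all) - known
    if unknown:
        raise ConfigError(f"structure_groups reference unknown drugs {sorted(unknown)}")

    n = bits_per_drug
    private = int(round(n * (1.0 - within_sim) / (1.0 + within_sim)))
    background = int(round(2.0 * n * between_sim / (1.0 + between_sim)))
    core = n - background - private
    if core < 0:
        raise ConfigError(
            f"incompatible similarity targets: within_sim={within_sim}, "
            f"between_sim={between_sim} leave no room for group-core bits"
        )

    rng = np.random.default_rng(seed)
    pool = iter(rng.permutation(10 * n * (len(members_all) + len(structure_groups) + 1)).tolist())

    def draw(k):
        return frozenset(f"b{next(pool)}" for _ in range(k))

    global_bits = draw(background)
    fingerprints: dict[str, Fingerprint] = {}
    for gid in sorted(structure_groups):
        core_bits = draw(core)
        for did in sorted(structure_groups[gid]):
            fingerprints[did] = Fingerprint(
                drug_id=did, bits=global_bits | core_bits | draw(private)
            )
    return fingerprints


def write_cohort(
    cohort: SyntheticCohort,
    out_dir,
    fingerprints: dict[str, Fingerprint] | None = None,
) -> dict:
    """Write a cohort in the harmonized TSV contract plus truth/manifest JSON.

    Also writes a ready-to-run pipeline config (``run_config.yaml``) wired
    to the emitted files.  Returns the manifest.  Matrices round-trip
    losslessly through :func:`diffsen.io.read_matrix`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"datasets": [], "files": []}

    def record(path: Path) -> str:
        manifest["files"].append(path.name)
        return path.name

    for ds in cohort.datasets:
        entry = {"name": ds.name}
        for kind in ("sensitivity", "silencing", "features"):
            path = out / f"{ds.name}_{kind}.tsv"
            write_matrix(getattr(ds, kind), path)
            entry[kind] = record(path)
        path = out / f"{ds.name}_lineages.tsv"
        write_lineages(ds.lineages, path)
        entry["lineages"] = record(path)
        entry["orientation"] = "viability_high_resistant"
        manifest["datasets"].append(entry)

    drugs_path = out / "drugs.tsv"
    pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in cohort.drugs],
            "name": [d.name for d in cohort.drugs],
            "targets": [";".join(d.targets) for d in cohort.drugs],
            "smiles": [d.smiles or "" for d in cohort.drugs],
        }
    ).to_csv(drugs_path, sep="\t", index=False)
    manifest["drugs"] = record(drugs_path)

    rows = [{"gene_id": t, "drug_id": ""} for ds in cohort.datasets[:1]
            for t in sorted({f for f in ds.features.index if not f.startswith("MUT")})]
    for did in sorted(cohort.truth.planted_transporters):
        for t in sorted(cohort.truth.planted_transporters[did]):
            rows.append({"gene_id": t, "drug_id": did})
    catalog_path = out / "catalog.tsv"
    pd.DataFrame(rows, columns=["gene_id", "drug_id"]).to_csv(
        catalog_path, sep="\t", index=False
    )
    manifest["catalog"] = record(catalog_path)

    truth_path = out / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "planted_transporters": cohort.truth.planted_transporters,
                "true_alpha": cohort.truth.true_alpha,
                "true_beta": cohort.truth.true_beta,
                "structure_groups": cohort.truth.structure_groups,
                "shared_cells": cohort.truth.shared_cells,
            },
            indent=1,
            sort_keys=True,
        )
    )
    manifest["truth"] = record(truth_path)

    if fingerprints is not None:
        fp_path = out / "fingerprints.json"
        fp_path.write_text(
            json.dumps(
                {d: sorted(fp.bits) for d, fp in sorted(fingerprints.items())},
                indent=1,
            )
        )
        manifest["fingerprints"] = record(fp_path)

    import yaml

    run_config = {
        "datasets": [
            {
                "name": e["name"],
                "sensitivity": e["sensitivity"],
                "silencing": e["silencing"],
                "features": e["features"],
                "lineages": e["lineages"],
                "orientation": e["orientation"],
            }
            for e in manifest["datasets"]
        ],
        "drugs": manifest["drugs"],
        "catalog": manifest["catalog"],
        "seed": int(cohort.config.seed if cohort.config else 0),
    }
    if fingerprints is not None:
        run_config["fingerprints"] = manifest["fingerprints"]
    cfg_path = out / "run_config.yaml"
    cfg_path.write_text(yaml.safe_dump(run_config, sort_keys=True))
    manifest["run_config"] = record(cfg_path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_truth(path) -> SyntheticTruth:
    """Re-load a truth file written by :func:`write_cohort`."""
    data = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_transporters={
            d: dict(v) for d, v in data["planted_transporters"].items()
        },
        true_alpha=dict(data["true_alpha"]),
        true_beta=dict(data["true_beta"]),
        structure_groups={g: list(v) for g, v in data["structure_groups"].items()},
        shared_cells=list(data["shared_cells"]),
    )
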