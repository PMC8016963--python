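"""End-to-end orchestration: load → harmonize → filter → DiffSen → models →
rank integration → enrichment, with a reproducible run report.

Every source of randomness derives from the master seed via
:func:`diffsen._util.fanout_seed` keyed by stage and drug id, so adding a
drug to a run never perturbs another drug's results, and two runs of the
same config produce byte-identical summary tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chem, enrichment, filtering, io, modeling
from ._util import fanout_seed
from .core import compute_diffsen
from .exceptions import (
    ConfigError,
    DiffsenError,
    InsufficientCellsError,
    ModelingError,
    TransferRefused,
)

logger = logging.getLogger(__name__)

STAGES = ("filter", "diffsen", "train", "transfer", "integrate", "enrich")


@dataclass
class DatasetSpec:
    name: str
    sensitivity: str
    silencing: str
    features: str
    lineages: str | None = None
    orientation: str = "viability_high_resistant"


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    datasets: list[DatasetSpec]
    drugs: str
    catalog: str
    fingerprints: str | None = None
    alpha_same_target: float = 0.05
    alpha_drug_target: float = 0.05
    alpha_success: float = 0.05
    correlation: str = "pearson"
    diffsen_mode: str = "zscore"
    k: int = 50
    chem_threshold: float = 0.35
    min_cells_per_lineage: int = 10
    split_fraction: float = 0.7
    top_n_cells: int = 10
    run_transfer: bool = True
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    def canonical(self) -> dict:
        d = {
            "datasets": [
                {k: v for k, v in vars(ds).items()} for ds in self.datasets
            ],
            **{
                k: v
                for k, v in vars(self).items()
                if k not in ("datasets", "base_dir")
            },
        }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode("utf8")
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML run config; all problems are reported at
    once rather than first-failure."""
    path = Path(path)
    errors: list[str] = []
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:  # unreadable / bad YAML
        return None, [f"config: cannot parse {path}: {exc}"]
    if not isinstance(raw, dict):
        return None, [f"config: top level of {path} must be a mapping"]

    base = path.parent
    specs: list[DatasetSpec] = []
    for i, entry in enumerate(raw.get("datasets") or []):
        name = entry.get("name", f"dataset[{i}]")
        spec = DatasetSpec(
            name=name,
            sensitivity=entry.get("sensitivity", ""),
            silencing=entry.get("silencing", ""),
            features=entry.get("features", ""),
            lineages=entry.get("lineages"),
            orientation=entry.get("orientation", "viability_high_resistant"),
        )
        for key in ("sensitivity", "silencing", "features"):
            rel = getattr(spec, key)
            if not rel:
                errors.append(f"datasets[{name}].{key}: missing path")
            elif not (base / rel).exists() and not Path(rel).is_absolute():
                if not (base / rel).exists():
                    errors.append(f"datasets[{name}].{key}: file not found: {rel}")
        if spec.lineages and not (base / spec.lineages).exists():
            errors.append(f"datasets[{name}].lineages: file not found: {spec.lineages}")
        if spec.orientation not in io.ORIENTATIONS:
            errors.append(
                f"datasets[{name}].orientation: unknown convention {spec.orientation!r}"
            )
        specs.append(spec)
    if not specs:
        errors.append("datasets: at least one dataset is required")

    kwargs: dict = {}
    for key in ("drugs", "catalog"):
        rel = raw.get(key, "")
        if not rel:
            errors.append(f"{key}: missing path")
        elif not (base / rel).exists():
            errors.append(f"{key}: file not found: {rel}")
        kwargs[key] = rel
    fp = raw.get("fingerprints")
    if fp and not (base / fp).exists():
        errors.append(f"fingerprints: file not found: {fp}")

    for key in ("alpha_same_target", "alpha_drug_target", "alpha_success"):
        val = raw.get(key, 0.05)
        if not (isinstance(val, (int, float)) and 0.0 < val < 1.0):
            errors.append(f"{key}: must be in (0,1), got {val!r}")
        kwargs[key] = float(val) if isinstance(val, (int, float)) else 0.05
    k = raw.get("k", 50)
    if not (isinstance(k, int) and k > 0):
        errors.append(f"k: must be a positive integer, got {k!r}")
        k = 50
    frac = raw.get("split_fraction", 0.7)
    if not (isinstance(frac, (int, float)) and 0.0 < frac < 1.0):
        errors.append(f"split_fraction: must be in (0,1), got {frac!r}")
        frac = 0.7
    mode = raw.get("diffsen_mode", "zscore")
    if mode not in ("raw", "zscore", "rank"):
        errors.append(f"diffsen_mode: must be raw|zscore|rank, got {mode!r}")
        mode = "zscore"
    corr = raw.get("correlation", "pearson")
    if corr not in ("pearson", "spearman"):
        errors.append(f"correlation: must be pearson|spearman, got {corr!r}")
        corr = "pearson"

    cfg = RunConfig(
        datasets=specs,
        fingerprints=fp,
        correlation=corr,
        diffsen_mode=mode,
        k=k,
        chem_threshold=float(raw.get("chem_threshold", 0.35)),
        min_cells_per_lineage=int(raw.get("min_cells_per_lineage", 10)),
        split_fraction=float(frac),
        top_n_cells=int(raw.get("top_n_cells", 10)),
        run_transfer=bool(raw.get("run_transfer", True)),
        seed=int(raw.get("seed", 0)),
        base_dir=base,
        **kwargs,
    )
    return (cfg if not errors else None), errors


def load_config(path) -> RunConfig:
    cfg, errors = validate_config(path)
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config_hash: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    filter_reports: dict = field(default_factory=dict)
    lineage_summary: dict = field(default_factory=dict)
    models: list[dict] = field(default_factory=list)
    success_fractions: dict = field(default_factory=dict)
    enrichment: list[dict] = field(default_factory=list)
    top_candidates: list[dict] = field(default_factory=list)
    cell_enrichment: list[dict] = field(default_factory=list)
    skips: list[dict] = field(default_factory=list)
    structure_groups: dict = field(default_factory=dict)

    def models_frame(self) -> pd.DataFrame:
        cols = ["drug_id", "train_dataset", "test_dataset", "model_family",
                "cv_score", "test_r", "test_p", "n_train_cells", "n_test_cells",
                "success"]
        df = pd.DataFrame(self.models, columns=cols)
        return df.sort_values(["drug_id", "train_dataset", "test_dataset"]).reset_index(drop=True)

    def enrichment_frame(self) -> pd.DataFrame:
        cols = ["scope_type", "scope", "n_annotated_used", "statistic", "p", "method"]
        df = pd.DataFrame(self.enrichment, columns=cols)
        return df.sort_values(["scope_type", "scope"]).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "filter_reports": self.filter_reports,
            "lineage_summary": self.lineage_summary,
            "models": self.models,
            "success_fractions": self.success_fractions,
            "enrichment": self.enrichment,
            "top_candidates": self.top_candidates,
            "cell_enrichment": self.cell_enrichment,
            "skips": self.skips,
            "structure_groups": self.structure_groups,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={self.config_hash} seed={self.seed}\n"
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True, default=float)
        )
        for name, frame in (
            ("models.tsv", self.models_frame()),
            ("enrichment.tsv", self.enrichment_frame()),
        ):
            with open(out / name, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        if self.top_candidates:
            with open(out / "importance.tsv", "w") as fh:
                fh.write(header)
                pd.DataFrame(self.top_candidates).to_csv(
                    fh, sep="\t", index=False, float_format="%.10g"
                )


def _load_fingerprints(config: RunConfig, drugs) -> dict[str, chem.Fingerprint]:
    """Fingerprints from the config's bit-set JSON, else from SMILES; drugs
    with neither become singletons downstream."""
    fps: dict[str, chem.Fingerprint] = {}
    if config.fingerprints:
        data = json.loads(config.path(config.fingerprints).read_text())
        for did, bits in data.items():
            fps[did] = chem.Fingerprint(drug_id=did, bits=frozenset(bits))
        return fps
    for d in drugs:
        if d.smiles:
            fps[d.drug_id] = chem.fingerprint_from_smiles(d.smiles, drug_id=d.drug_id)
    return fps


def run_pipeline(config: RunConfig, stop_after: str | None = None,
                 out_dir=None) -> RunReport:
    """Execute the pipeline through ``stop_after`` (default: everything).

    Stages: filter → diffsen → train → transfer → integrate → enrich.
    Returns the :class:`RunReport`; writes artifacts to ``out_dir`` when
    given.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"stop_after must be one of {STAGES}, got {stop_after!r}")
    stage_idx = STAGES.index(stop_after) if stop_after else len(STAGES) - 1
    report = RunReport(config_hash=config.config_hash, seed=config.seed)

    # ---- load + harmonize -------------------------------------------------
    raw = {}
    for spec in config.datasets:
        mats = {
            "sensitivity": io.orient_sensitivity(
                io.read_matrix(config.path(spec.sensitivity)), spec.orientation
            ),
            "silencing": io.orient_sensitivity(
                io.read_matrix(config.path(spec.silencing)), spec.orientation
            ),
            "features": io.read_matrix(config.path(spec.features)),
        }
        if spec.lineages:
            mats["lineages"] = io.read_lineages(config.path(spec.lineages))
        raw[spec.name] = mats
    data = io.harmonize(raw)
    drugs = io.read_drug_annotations(config.path(config.drugs))
    catalog = io.read_transporter_catalog(config.path(config.catalog))
    report.stage_counts["input_drugs"] = len(drugs)

    # ---- filter cascade ---------------------------------------------------
    by_id = {d.drug_id: d for d in drugs}
    after_targets = filtering.filter_by_target_count(drugs)
    report.stage_counts["after_target_count"] = len(after_targets)
    surviving: dict[str, list[str]] = {}
    for name in sorted(data.datasets):
        mats = data.datasets[name]
        rep1 = filtering.same_target_concordance(
            mats["sensitivity"], after_targets,
            alpha=config.alpha_same_target, method=config.correlation,
        )
        rep2 = filtering.drug_target_concordance(
            mats["sensitivity"], mats["silencing"],
            [by_id[d] for d in rep1.surviving],
            alpha=config.alpha_drug_target, method=config.correlation,
        )
        surviving[name] = sorted(rep2.surviving)
        report.filter_reports[name] = {
            "same_target": rep1.to_dict(),
            "drug_target": rep2.to_dict(),
            "surviving": surviving[name],
        }
        report.stage_counts[f"surviving[{name}]"] = len(surviving[name])

    # ---- lineage screen (descriptive) ------------------------------------
    for name in sorted(data.datasets):
        mats = data.datasets[name]
        if "lineages" not in mats:
            continue
        try:
            anova = filtering.lineage_anova(
                mats["features"], mats["lineages"].dropna(),
                min_cells_per_lineage=config.min_cells_per_lineage,
            )
        except InsufficientCellsError as exc:
            report.lineage_summary[name] = {"skipped": str(exc)}
            continue
        report.lineage_summary[name] = {
            "n_genes": int(len(anova)),
            "n_lineage_specific": int((anova["p"] < 0.05).sum()),
        }
    if stage_idx < STAGES.index("diffsen"):
        if out_dir:
            report.write(out_dir)
        return report

    # ---- DiffSen ----------------------------------------------------------
    diffsen_vectors: dict[tuple[str, str], object] = {}
    for name in sorted(data.datasets):
        mats = data.datasets[name]
        for did in surviving[name]:
            try:
                diffsen_vectors[(name, did)] = compute_diffsen(
                    by_id[did], mats["sensitivity"], mats["silencing"],
                    dataset=name, mode=config.diffsen_mode,
                )
            except (InsufficientCellsError, KeyError) as exc:
                report.skips.append(
                    {"stage": "diffsen", "dataset": name, "drug_id": did,
                     "reason": str(exc)}
                )
    report.stage_counts["diffsen_vectors"] = len(diffsen_vectors)
    if out_dir:
        dd = Path(out_dir) / "diffsen"
        dd.mkdir(parents=True, exist_ok=True)
        for (name, did), vec in sorted(diffsen_vectors.items()):
            with open(dd / f"{name}_{did}.tsv", "w") as fh:
                fh.write(f"# config_hash={config.config_hash} seed={config.seed}\n")
                vec.to_series().rename("diffsen").to_csv(
                    fh, sep="\t", index_label="cell_id", float_format="%.10g",
                )
    if stage_idx < STAGES.index("train"):
        if out_dir:
            report.write(out_dir)
        return report

    # ---- within-dataset models -------------------------------------------
    results: list[modeling.ModelResult] = []
    for name in sorted(data.datasets):
        mats = data.datasets[name]
        for did in surviving[name]:
            if (name, did) not in diffsen_vectors:
                continue
            seed = fanout_seed(config.seed, "within", name, did)
            try:
                res = modeling.within_dataset_run(
                    by_id[did], name, mats["sensitivity"], mats["silencing"],
                    mats["features"], k=config.k, seed=seed,
                    alpha=config.alpha_success,
                    split_fraction=config.split_fraction,
                    diffsen_mode=config.diffsen_mode,
                )
            except (ModelingError, InsufficientCellsError) as exc:
                report.skips.append(
                    {"stage": "train", "dataset": name, "drug_id": did,
                     "reason": str(exc)}
                )
                continue
            results.append(res)
    if stage_idx >= STAGES.index("transfer") and config.run_transfer:
        names = sorted(data.datasets)
        for a in names:
            for b in names:
                if a == b:
                    continue
                for did in sorted(set(surviving[a]) & set(surviving[b])):
                    seed = fanout_seed(config.seed, "transfer", a, b, did)
                    try:
                        res = modeling.cross_dataset_run(
                            by_id[did], a, data.datasets[a], b, data.datasets[b],
                            k=config.k, seed=seed, alpha=config.alpha_success,
                            diffsen_mode=config.diffsen_mode,
                        )
                    except TransferRefused as exc:
                        report.skips.append(
                            {"stage": "transfer", "dataset": f"{a}->{b}",
                             "drug_id": did, "reason": exc.reason}
                        )
                        continue
                    except (ModelingError, InsufficientCellsError) as exc:
                        report.skips.append(
                            {"stage": "transfer", "dataset": f"{a}->{b}",
                             "drug_id": did, "reason": str(exc)}
                        )
                        continue
                    results.append(res)

    report.models = [r.to_row() for r in results]
    pairs: dict[str, list[bool]] = {}
    for r in results:
        key = (r.train_dataset if r.train_dataset == r.test_dataset
               else f"{r.train_dataset}->{r.test_dataset}")
        pairs.setdefault(key, []).append(r.success)
    report.success_fractions = {
        key: round(sum(v) / len(v), 6) for key, v in sorted(pairs.items())
    }
    if stage_idx < STAGES.index("integrate"):
        if out_dir:
            report.write(out_dir)
        return report

    # ---- rank integration -------------------------------------------------
    successful = [r for r in results if r.success and r.selection is not None]
    rank_vectors: dict[str, list] = {}
    for r in successful:
        rank_vectors.setdefault(r.drug_id, []).append(
            enrichment.rank_features_per_model(r.selection)
        )
    drug_lists: dict[str, enrichment.RankedFeatureList] = {}
    for did in sorted(rank_vectors):
        try:
            drug_lists[did] = enrichment.aggregate_ranks(rank_vectors[did], scope=did)
        except DiffsenError as exc:
            report.skips.append(
                {"stage": "integrate", "dataset": "", "drug_id": did, "reason": str(exc)}
            )

    fps = _load_fingerprints(config, drugs)
    modeled = sorted(rank_vectors)
    grouped = chem.structure_groups(
        {d: fps[d] for d in modeled if d in fps}, threshold=config.chem_threshold
    ) if fps else []
    grouped_ids = {d for grp in grouped for d in grp}
    groups = {f"SG{i:03d}": grp for i, grp in enumerate(grouped)}
    for did in modeled:
        if did not in grouped_ids:
            groups[f"singleton:{did}"] = [did]
    report.structure_groups = groups
    group_lists: dict[str, enrichment.RankedFeatureList] = {}
    for gid in sorted(groups):
        vectors = [rv for did in groups[gid] for rv in rank_vectors.get(did, [])]
        if not vectors:
            continue
        try:
            group_lists[gid] = enrichment.aggregate_ranks(vectors, scope=gid)
        except DiffsenError as exc:
            report.skips.append(
                {"stage": "integrate", "dataset": "", "drug_id": gid, "reason": str(exc)}
            )
    report.stage_counts["drugs_integrated"] = len(drug_lists)
    report.stage_counts["structure_groups_integrated"] = len(group_lists)
    if stage_idx < STAGES.index("enrich"):
        if out_dir:
            report.write(out_dir)
        return report

    # ---- enrichment + importance ------------------------------------------
    for did in sorted(drug_lists):
        res = enrichment.transporter_enrichment(
            drug_lists[did], catalog.annotated.get(did, set())
        )
        report.enrichment.append(
            {"scope_type": "drug", "scope": did,
             "n_annotated_used": len(res.annotated_used),
             "statistic": res.statistic, "p": res.p, "method": res.method}
        )
    for gid in sorted(group_lists):
        annotated = set()
        for did in groups[gid]:
            annotated |= catalog.annotated.get(did, set())
        res = enrichment.transporter_enrichment(group_lists[gid], annotated)
        report.enrichment.append(
            {"scope_type": "group", "scope": gid,
             "n_annotated_used": len(res.annotated_used),
             "statistic": res.statistic, "p": res.p, "method": res.method}
        )

    member_map = {gid: groups[gid] for gid in group_lists}
    scores = enrichment.importance_scores(group_lists, member_map)
    for did in sorted(scores):
        top = scores[did].head(5)
        for rank_i, (fid, sc) in enumerate(top.items(), start=1):
            report.top_candidates.append(
                {"drug_id": did, "rank": rank_i, "feature": fid,
                 "importance": round(float(sc), 6)}
            )

    # tail enrichment of the top candidate feature per drug
    for did in sorted(scores):
        top_feature = scores[did].index[0]
        for name in sorted(data.datasets):
            key = (name, did)
            feats = data.datasets[name]["features"]
            if key not in diffsen_vectors or top_feature not in feats.index:
                continue
            try:
                tails = enrichment.cellline_enrichment(
                    feats.loc[top_feature], diffsen_vectors[key],
                    top_n=config.top_n_cells,
                )
            except (ConfigError, InsufficientCellsError) as exc:
                report.skips.append(
                    {"stage": "enrich", "dataset": name, "drug_id": did,
                     "reason": str(exc)}
                )
                continue
            report.cell_enrichment.append(
                {"drug_id": did, "dataset": name, "feature": top_feature,
                 "p_high": tails["p_high"], "p_low": tails["p_low"]}
            )
            break

    if out_dir:
        report.write(out_dir)
    return report
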