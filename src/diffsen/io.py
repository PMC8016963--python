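"""Harmonized data contract: readers, writers and dataset alignment.

The pipeline exchanges three kinds of labeled matrices, all as TSV with the
first column holding row ids and the header row holding cell-line ids:

* drug sensitivity   — drugs x cell lines (viability-oriented after
  :func:`orient_sensitivity`: higher value = more viable = more resistant)
* silencing viability — target genes x cell lines
* features           — transporter expression and binary genetic flags x
  cell lines

Matrices are held as :class:`pandas.DataFrame` with unique string indexes;
the readers enforce the contract (no duplicate ids, rectangular, numeric,
empty cells = missing) so downstream code can assume it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import norm_id
from .exceptions import HarmonizationError, ParseError

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}

#: input conventions accepted by :func:`orient_sensitivity`
ORIENTATIONS = ("viability_high_resistant", "sensitivity_high_sensitive")


@dataclass
class DrugRecord:
    """A screened compound with its primary target annotation.

    ``targets`` may hold more than two genes straight after parsing; such
    records are flagged (``too_many_targets``) and removed later by
    :func:`diffsen.filtering.filter_by_target_count`.
    """

    drug_id: str
    name: str
    targets: list[str]
    smiles: str | None = None
    datasets: set[str] = field(default_factory=set)

    @property
    def too_many_targets(self) -> bool:
        return len(self.targets) > 2


@dataclass
class TransporterCatalog:
    """The transporter/carrier feature universe plus per-drug annotations.

    ``all_transporters`` is every gene annotated as a transporter or carrier
    for any drug; ``annotated`` maps a drug id to the subset reported for
    that specific drug.
    """

    all_transporters: set[str]
    annotated: dict[str, set[str]]

    def __post_init__(self):
        for drug, genes in self.annotated.items():
            extra = genes - self.all_transporters
            if extra:
                raise ParseError(
                    f"catalog: genes annotated for drug {drug!r} missing from "
                    f"the transporter universe: {sorted(extra)}"
                )


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled TSV matrix, validating the contract.

    Empty / NA cells become NaN (missing, never zero).  Duplicate ids,
    ragged rows and non-numeric cells raise :class:`ParseError` with the
    offending line number.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        col_ids = [c.strip() for c in header[1:]]
        if len(set(col_ids)) != len(col_ids):
            dup = sorted({c for c in col_ids if col_ids.count(c) > 1})
            raise ParseError(f"{path}: line 1: duplicate column id(s) {dup}")
        row_ids: list[str] = []
        seen: set[str] = set()
        values: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(col_ids) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(col_ids) + 1} "
                    f"fields, got {len(row)}"
                )
            rid = row[0].strip()
            if rid in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate row id {rid!r}")
            seen.add(rid)
            row_ids.append(rid)
            parsed = []
            for j, cell in enumerate(row[1:]):
                tok = cell.strip()
                if tok.casefold() in _MISSING_TOKENS:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric value {cell!r} "
                        f"in column {col_ids[j]!r}"
                    ) from None
            values.append(parsed)
    return pd.DataFrame(values, index=row_ids, columns=col_ids, dtype=float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix in the TSV contract (missing values as empty cells)."""
    matrix.to_csv(path, sep="\t", index_label="id", na_rep="")


def read_drug_annotations(path) -> list[DrugRecord]:
    """Read the drug annotation TSV (drug_id, name, targets ';'-joined,
    optional smiles).  A drug with zero targets is a contract violation."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("drug_id", "name", "targets"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        targets = [t.strip() for t in str(row.targets).split(";") if t.strip()]
        if not targets:
            raise ParseError(
                f"{path}: line {lineno}: drug {row.drug_id!r} has no targets"
            )
        smiles = getattr(row, "smiles", "") or None
        records.append(
            DrugRecord(
                drug_id=row.drug_id.strip(),
                name=row.name.strip(),
                targets=targets,
                smiles=smiles.strip() if smiles else None,
            )
        )
        if records[-1].too_many_targets:
            logger.info(
                "drug %s has %d targets; will be removed by the target-count "
                "filter", records[-1].drug_id, len(targets)
            )
    return records


def read_transporter_catalog(path) -> TransporterCatalog:
    """Read the transporter catalog TSV (gene_id, drug_id; empty drug_id
    marks a generic transporter not tied to a specific drug)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'gene_id'")
    all_transporters: set[str] = set()
    annotated: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        gene = row.gene_id.strip()
        if not gene:
            continue
        all_transporters.add(gene)
        drug = getattr(row, "drug_id", "").strip()
        if drug:
            annotated.setdefault(drug, set()).add(gene)
    return TransporterCatalog(all_transporters=all_transporters, annotated=annotated)


def orient_sensitivity(matrix: pd.DataFrame, convention: str) -> pd.DataFrame:
    """Canonicalize a sensitivity (or silencing) matrix to viability
    orientation: higher value = more viable = more resistant.

    ``viability_high_resistant`` inputs pass through; the
    ``sensitivity_high_sensitive`` convention is negated (no rescaling).
    """
    if convention == "viability_high_resistant":
        return matrix.copy()
    if convention == "sensitivity_high_sensitive":
        return -matrix
    raise ParseError(
        f"unknown orientation {convention!r}; expected one of {ORIENTATIONS}"
    )


@dataclass
class HarmonizedData:
    """Datasets aligned to their usable cell lines, plus cross-dataset
    intersections used by transfer runs and rank integration."""

    datasets: dict[str, dict[str, pd.DataFrame]]
    shared_cells: dict[tuple[str, str], list[str]]
    shared_features: list[str]
    dropped_features: dict[str, list[str]]


def harmonize(
    datasets: dict[str, dict[str, pd.DataFrame]],
    max_missing_fraction: float = 0.2,
) -> HarmonizedData:
    """Align each dataset's matrices to the intersection of their cell lines.

    Within a dataset, sensitivity / silencing / features are restricted to
    cell lines present in all three (a cell line is only usable for modeling
    when drug response, dependency and features are all measured), in
    canonical lexicographic order.  Feature rows with more than
    ``max_missing_fraction`` missing cells are dropped; remaining missing
    feature values are imputed with the row median.  Missing sensitivity /
    silencing cells are left as NaN — excluded per analysis downstream.

    Also reports pairwise shared cell lines between datasets and the feature
    ids shared by every dataset (the universe available to cross-dataset
    models).
    """
    if not datasets:
        raise HarmonizationError("no datasets supplied")
    aligned: dict[str, dict[str, pd.DataFrame]] = {}
    dropped: dict[str, list[str]] = {}
    for name, mats in datasets.items():
        cells = None
        for key in ("sensitivity", "silencing", "features"):
            if key not in mats:
                raise HarmonizationError(f"dataset {name!r}: missing {key!r} matrix")
            cset = set(mats[key].columns)
            cells = cset if cells is None else cells & cset
        if not cells:
            raise HarmonizationError(
                f"dataset {name!r}: no cell lines shared by sensitivity, "
                "silencing and features"
            )
        order = sorted(cells)
        feats = mats["features"][order]
        frac_missing = feats.isna().mean(axis=1)
        keep = frac_missing <= max_missing_fraction
        dropped[name] = sorted(feats.index[~keep])
        if dropped[name]:
            logger.info(
                "dataset %s: dropped %d features with >%d%% missing values",
                name, len(dropped[name]), int(100 * max_missing_fraction),
            )
        feats = feats.loc[keep]
        if feats.isna().any().any():
            med = feats.median(axis=1)
            feats = feats.apply(lambda row: row.fillna(med[row.name]), axis=1)
        out = {
            "sensitivity": mats["sensitivity"][order],
            "silencing": mats["silencing"][order],
            "features": feats,
        }
        if "lineages" in mats:
            lin = mats["lineages"]
            out["lineages"] = lin.loc[lin.index.intersection(order)].reindex(order)
        aligned[name] = out

    names = sorted(aligned)
    shared_cells = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared_cells[(a, b)] = sorted(
                set(aligned[a]["features"].columns)
                & set(aligned[b]["features"].columns)
            )
    shared_features: set[str] | None = None
    for name in names:
        fset = set(aligned[name]["features"].index)
        shared_features = fset if shared_features is None else shared_features & fset
    return HarmonizedData(
        datasets=aligned,
        shared_cells=shared_cells,
        shared_features=sorted(shared_features or set()),
        dropped_features=dropped,
    )


def read_lineages(path) -> pd.Series:
    """Read the cell_id → lineage label table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "lineage"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["cell_id"].duplicated().any():
        dup = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"])
        raise ParseError(f"{path}: duplicate cell id(s) {dup}")
    return pd.Series(
        df["lineage"].str.strip().values,
        index=df["cell_id"].str.strip().values,
        name="lineage",
    )


def write_lineages(lineages: pd.Series, path) -> None:
    pd.DataFrame({"cell_id": lineages.index, "lineage": lineages.values}).to_csv(
        path, sep="\t", index=False
    )


def target_lookup(silencing: pd.DataFrame) -> dict[str, str]:
    """Map normalized gene ids to the silencing matrix's actual row ids,
    so drug-target matching tolerates case/whitespace differences."""
    return {norm_id(g): g for g in silencing.index}
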