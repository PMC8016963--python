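"""The resistance differential ("DiffSen") and train/test partitioning.

The central statistic contrasts, per cell line, how viable cells remain
under a drug versus under genetic silencing of the drug's primary target.
If knocking the target down kills a cell line but the drug does not, some
mechanism — canonically an efflux transporter exporting the compound — is
protecting the cells from the drug.  Both inputs are z-scored per row so
that AUC-scale drug screens and viability-scale dependency screens become
commensurable; the differential is then

    DiffSen(c) = z_drug(c) - z_silencing(c)

with positive values flagging candidate transporter-mediated resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import norm_id
from .exceptions import ConfigError, InsufficientCellsError
from .io import DrugRecord

logger = logging.getLogger(__name__)


@dataclass
class DiffSenVector:
    """Per-drug, per-cell-line resistance differential."""

    drug_id: str
    dataset: str
    cell_ids: list[str]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_ids, name=self.drug_id)


@dataclass
class TrainTestSplit:
    train_cells: list[str]
    test_cells: list[str]
    seed: int


def _zscore(v: np.ndarray) -> np.ndarray:
    # population SD: a 3-point row (1,2,3) maps to (-1.2247, 0, 1.2247)
    return (v - v.mean()) / v.std(ddof=0)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, SD 1 over its non-missing cells.

    Rows without at least two distinct finite values carry no ranking
    information and are dropped (logged).  Idempotent on already-scored
    rows.
    """
    keep = []
    out = matrix.copy()
    for rid in matrix.index:
        row = matrix.loc[rid]
        finite = row.dropna()
        if finite.nunique() < 2:
            logger.warning("zscore_rows: dropping constant/degenerate row %r", rid)
            continue
        mu = finite.mean()
        sd = finite.std(ddof=0)
        out.loc[rid] = (row - mu) / sd
        keep.append(rid)
    return out.loc[keep]


def silencing_profile(
    drug: DrugRecord, silencing: pd.DataFrame, cells: list[str] | None = None
) -> pd.Series:
    """The target-dependency profile a drug is compared against.

    Single-target drugs use the target's silencing row.  Two-target drugs
    use the mean of the two per-target z-scored rows (a scale-free
    combination), re-z-scored by the caller as needed.  Matching of target
    gene ids is whitespace/case tolerant.
    """
    lut = {norm_id(g): g for g in silencing.index}
    rows = []
    for t in drug.targets:
        key = norm_id(t)
        if key not in lut:
            raise KeyError(f"target {t!r} of drug {drug.drug_id!r} not in silencing matrix")
        row = silencing.loc[lut[key]]
        if cells is not None:
            row = row[cells]
        rows.append(row)
    if len(rows) == 1:
        return rows[0]
    zrows = [(r - r.mean()) / r.std(ddof=0) for r in rows]
    return sum(zrows) / len(zrows)


def compute_diffsen(
    drug: DrugRecord,
    sensitivity: pd.DataFrame,
    silencing: pd.DataFrame,
    dataset: str = "",
    min_cells: int = 10,
    mode: str = "zscore",
) -> DiffSenVector:
    """Compute the resistance differential for one drug.

    Cells are the lexicographically ordered intersection of cells with
    finite sensitivity and finite silencing for every target.  ``mode``
    selects the scale harmonization: ``zscore`` (default) subtracts per-row
    z-scores, ``rank`` subtracts normalized ranks, ``raw`` subtracts raw
    values (only meaningful when both inputs share a scale).
    """
    if drug.drug_id not in sensitivity.index:
        raise KeyError(f"drug {drug.drug_id!r} not in sensitivity matrix")
    sens_row = sensitivity.loc[drug.drug_id]
    sil_raw = silencing_profile(drug, silencing)
    usable = sorted(
        set(sens_row.dropna().index) & set(sil_raw.dropna().index)
    )
    if len(usable) < min_cells:
        raise InsufficientCellsError(
            f"insufficient_cells: drug {drug.drug_id!r} has {len(usable)} usable "
            f"cells (< {min_cells})"
        )
    s = sens_row[usable].to_numpy(dtype=float)
    v = sil_raw[usable].to_numpy(dtype=float)
    if mode == "zscore":
        diff = _zscore(s) - _zscore(v)
    elif mode == "rank":
        from scipy.stats import rankdata

        n = len(usable)
        diff = (rankdata(s) - rankdata(v)) / n
    elif mode == "raw":
        diff = s - v
    else:
        raise ConfigError(f"diffsen mode {mode!r} not one of raw|zscore|rank")
    return DiffSenVector(drug_id=drug.drug_id, dataset=dataset, cell_ids=usable, values=diff)


def split_train_test(
    cell_ids: list[str], fraction: float = 0.7, seed: int = 0
) -> TrainTestSplit:
    """Uniform random 70/30-style split of cell lines, reproducible by seed."""
    if not (0.0 < fraction < 1.0):
        raise ConfigError(f"fraction must be in (0,1), got {fraction}")
    cells = sorted(cell_ids)
    if len(cells) < 10:
        raise InsufficientCellsError(
            f"insufficient_cells: need >= 10 cells to split, got {len(cells)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cells))
    n_train = int(round(fraction * len(cells)))
    train = sorted(cells[i] for i in perm[:n_train])
    test = sorted(cells[i] for i in perm[n_train:])
    return TrainTestSplit(train_cells=train, test_cells=test, seed=seed)
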