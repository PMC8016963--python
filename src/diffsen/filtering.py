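"""The drug/target filter cascade and the lineage-specificity screen.

Drugs enter the pipeline only when their cell-line behavior is internally
consistent enough for the resistance differential to be meaningful:

1. ``filter_by_target_count`` — keep drugs with 1–2 primary targets
   (polypharmacology cannot be mimicked by silencing one gene);
2. ``same_target_concordance`` — drugs sharing a target must correlate in
   sensitivity across cell lines; targets left with fewer than three
   concordant drugs are dropped entirely;
3. ``drug_target_concordance`` — a drug's sensitivity profile must correlate
   significantly with silencing of its own target.

``lineage_anova`` is the accompanying descriptive screen: a per-gene one-way
ANOVA of feature values across tissue lineages with enough cell lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import norm_id, pearson_with_p
from .exceptions import InsufficientCellsError
from .io import DrugRecord

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceReport:
    """Outcome of one filter stage: every input drug is either surviving or
    removed with a reason (an exact partition of the input)."""

    surviving: list[str]
    removed: dict[str, str]
    pair_stats: list[dict] = field(default_factory=list)
    drug_stats: dict[str, dict] = field(default_factory=dict)
    skipped_pairs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "surviving": list(self.surviving),
            "removed": dict(self.removed),
            "pair_stats": list(self.pair_stats),
            "drug_stats": {k: dict(v) for k, v in self.drug_stats.items()},
            "skipped_pairs": list(self.skipped_pairs),
        }


def filter_by_target_count(drugs: list[DrugRecord]) -> list[DrugRecord]:
    """Keep exactly the drugs with one or two primary targets."""
    return [d for d in drugs if 1 <= len(d.targets) <= 2]


def _correlate(x: pd.Series, y: pd.Series, method: str) -> tuple[float, float, int]:
    """Correlation over the shared non-missing cells of two profiles."""
    shared = sorted(set(x.dropna().index) & set(y.dropna().index))
    n = len(shared)
    if n < 3:
        return np.nan, np.nan, n
    xv = x[shared].to_numpy(float)
    yv = y[shared].to_numpy(float)
    if method == "spearman":
        if np.std(xv) == 0 or np.std(yv) == 0:
            return 0.0, 1.0, n
        r, p = stats.spearmanr(xv, yv)
        return float(r), float(p), n
    r, p = pearson_with_p(xv, yv)
    return r, p, n


def same_target_concordance(
    sensitivity: pd.DataFrame,
    drugs: list[DrugRecord],
    alpha: float = 0.05,
    method: str = "pearson",
) -> ConcordanceReport:
    """Remove drugs discordant with their same-target peers, then targets
    with fewer than three surviving drugs.

    For every pair of drugs sharing a target, Pearson (or Spearman) r and a
    two-sided p are computed over shared non-missing cell lines; pairs with
    fewer than three shared cells are skipped and logged.  A drug passes a
    target group iff the median of its pairwise p-values in that group is
    below ``alpha`` (the evident intent of keeping mutually concordant
    drugs); a two-target drug must pass in every group it belongs to.
    Afterwards any target retaining fewer than three drugs is removed with
    all its drugs.
    """
    present = [d for d in drugs if d.drug_id in sensitivity.index]
    removed: dict[str, str] = {}
    for d in drugs:
        if d.drug_id not in sensitivity.index:
            removed[d.drug_id] = "not_in_sensitivity_matrix"

    groups: dict[str, list[DrugRecord]] = {}
    for d in present:
        for t in d.targets:
            groups.setdefault(norm_id(t), []).append(d)

    pair_stats: list[dict] = []
    skipped: list[dict] = []
    pvals: dict[str, dict[str, list[float]]] = {}  # drug -> target -> peer p's
    for target, members in sorted(groups.items()):
        for a, b in combinations(sorted(members, key=lambda d: d.drug_id), 2):
            r, p, n = _correlate(
                sensitivity.loc[a.drug_id], sensitivity.loc[b.drug_id], method
            )
            if np.isnan(p):
                skipped.append(
                    {"target": target, "drug_a": a.drug_id, "drug_b": b.drug_id,
                     "n_shared": n, "reason": "fewer_than_3_shared_cells"}
                )
                logger.warning(
                    "skipping pair (%s, %s) for target %s: %d shared cells",
                    a.drug_id, b.drug_id, target, n,
                )
                continue
            pair_stats.append(
                {"target": target, "drug_a": a.drug_id, "drug_b": b.drug_id,
                 "r": r, "p": p, "n_shared": n}
            )
            pvals.setdefault(a.drug_id, {}).setdefault(target, []).append(p)
            pvals.setdefault(b.drug_id, {}).setdefault(target, []).append(p)

    drug_stats: dict[str, dict] = {}
    concordant: list[DrugRecord] = []
    for d in present:
        # lower median: a drug is concordant when at least half of its peer
        # correlations are significant (even pair counts would otherwise
        # penalize a drug with one perfect and one null peer)
        med_by_target = {
            t: float(sorted(ps)[(len(ps) - 1) // 2])
            for t, ps in pvals.get(d.drug_id, {}).items()
        }
        drug_stats[d.drug_id] = {"median_p_by_target": med_by_target}
        if not med_by_target:
            # no evaluable peer pairs: the drug cannot demonstrate concordance,
            # and its target group is below size 3 anyway
            removed[d.drug_id] = "target_too_few_drugs"
            continue
        if all(p < alpha for p in med_by_target.values()):
            concordant.append(d)
        else:
            removed[d.drug_id] = "discordant_with_peers"

    # targets must retain >= 3 concordant drugs
    counts: dict[str, int] = {}
    for d in concordant:
        for t in d.targets:
            counts[norm_id(t)] = counts.get(norm_id(t), 0) + 1
    surviving = []
    for d in concordant:
        if all(counts[norm_id(t)] >= 3 for t in d.targets):
            surviving.append(d.drug_id)
        else:
            removed[d.drug_id] = "target_too_few_drugs"
    return ConcordanceReport(
        surviving=sorted(surviving),
        removed=removed,
        pair_stats=pair_stats,
        drug_stats=drug_stats,
        skipped_pairs=skipped,
    )


def drug_target_concordance(
    sensitivity: pd.DataFrame,
    silencing: pd.DataFrame,
    drugs: list[DrugRecord],
    alpha: float = 0.05,
    method: str = "pearson",
) -> ConcordanceReport:
    """Keep drugs whose sensitivity correlates significantly with silencing
    of their primary target.

    Two-target drugs are compared against the mean of the two per-target
    z-scored silencing profiles.  Drugs whose target is absent from the
    silencing matrix are removed with reason ``target_not_silenced``.
    """
    from .core import silencing_profile

    removed: dict[str, str] = {}
    drug_stats: dict[str, dict] = {}
    surviving: list[str] = []
    for d in sorted(drugs, key=lambda d: d.drug_id):
        if d.drug_id not in sensitivity.index:
            removed[d.drug_id] = "not_in_sensitivity_matrix"
            continue
        try:
            profile = silencing_profile(d, silencing)
        except KeyError:
            removed[d.drug_id] = "target_not_silenced"
            continue
        r, p, n = _correlate(sensitivity.loc[d.drug_id], profile, method)
        if np.isnan(p):
            removed[d.drug_id] = "fewer_than_3_shared_cells"
            continue
        drug_stats[d.drug_id] = {"r": r, "p": p, "n_shared": n}
        if p < alpha:
            surviving.append(d.drug_id)
        else:
            removed[d.drug_id] = "not_correlated_with_target_silencing"
    return ConcordanceReport(
        surviving=surviving, removed=removed, drug_stats=drug_stats
    )


def lineage_anova(
    features: pd.DataFrame,
    lineage_labels: pd.Series,
    min_cells_per_lineage: int = 10,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA of feature values across tissue lineages.

    Lineages with ``min_cells_per_lineage`` or fewer labeled cell lines are
    excluded (i.e. a lineage must have *more than* the threshold).  A gene
    constant across all cells has no lineage signal and reports F=0, p=1.
    Returns a DataFrame indexed by gene with columns ``F`` and ``p``.
    """
    labels = lineage_labels.loc[lineage_labels.index.intersection(features.columns)]
    counts = labels.value_counts()
    kept = sorted(counts.index[counts > min_cells_per_lineage])
    if len(kept) < 2:
        raise InsufficientCellsError(
            f"lineage_anova: only {len(kept)} lineage(s) with more than "
            f"{min_cells_per_lineage} cells; need at least 2"
        )
    cell_groups = [sorted(labels.index[labels == lin]) for lin in kept]
    out = []
    for gene in features.index:
        row = features.loc[gene]
        samples = [row[g].dropna().to_numpy(float) for g in cell_groups]
        samples = [s for s in samples if s.size >= 2]
        flat = np.concatenate(samples) if samples else np.array([])
        if len(samples) < 2 or flat.size == 0 or np.all(flat == flat[0]):
            out.append((gene, 0.0, 1.0))
            continue
        F, p = stats.f_oneway(*samples)
        if not np.isfinite(p):
            F, p = 0.0, 1.0
        out.append((gene, float(F), float(p)))
    return pd.DataFrame(out, columns=["gene", "F", "p"]).set_index("gene")
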