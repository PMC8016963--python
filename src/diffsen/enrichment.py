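"""Rank aggregation across models and transporter-set enrichment.

Each successful model ranks the whole feature universe by correlation with
the resistance differential (rank 1 = most resistance-associated).  Rank
vectors are averaged across models of the same drug — and across drugs of
the same structure group — and the question "are the annotated transporters
of this drug near the top of the aggregated list?" is answered with a
one-sided rank-sum test (exact by exhaustive permutation for small
universes, normal-approximation Mann-Whitney otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core import DiffSenVector
from .exceptions import ConfigError, DiffsenError, InsufficientCellsError
from .modeling import FeatureSelection

logger = logging.getLogger(__name__)

#: largest (universe, annotated) sizes handled by exhaustive permutation
EXACT_MAX_UNIVERSE = 12
EXACT_MAX_ANNOTATED = 8


@dataclass
class RankedFeatureList:
    """Aggregated feature ranks for one drug or structure group."""

    scope: str
    entries: list[tuple[str, float]]  # (feature, mean_rank), ascending
    n_models_integrated: int

    @property
    def universe(self) -> list[str]:
        return [f for f, _ in self.entries]

    def to_series(self) -> pd.Series:
        return pd.Series(
            [mr for _, mr in self.entries],
            index=[f for f, _ in self.entries],
            name=self.scope,
        )


@dataclass
class EnrichmentResult:
    scope: str
    annotated_used: list[str]
    statistic: float
    p: float
    method: str  # "exact_permutation" | "ranksum_normal" | "untestable"

    @property
    def untestable(self) -> bool:
        return self.method == "untestable"


def rank_features_per_model(selection: FeatureSelection) -> pd.Series:
    """Full rank vector over a model's feature universe.

    Rank 1 = highest positive correlation with the resistance differential;
    tied correlations receive average ranks.  The vector always sums to
    n(n+1)/2.
    """
    fids = [f for f, _, _ in selection.ranked_features]
    rs = np.array([r for _, r, _ in selection.ranked_features])
    ranks = stats.rankdata(-rs, method="average")
    return pd.Series(ranks, index=fids, name=selection.drug_id)


def aggregate_ranks(rank_vectors: list[pd.Series], scope: str) -> RankedFeatureList:
    """Average rank vectors over their common feature universe.

    The mean is taken feature-wise across models; output sorted by mean
    rank ascending (ties broken by feature id for a stable listing).
    Order of the input models is irrelevant.
    """
    if not rank_vectors:
        raise DiffsenError("aggregate_ranks: no rank vectors supplied")
    universe = set(rank_vectors[0].index)
    for rv in rank_vectors[1:]:
        universe &= set(rv.index)
    if not universe:
        raise DiffsenError(
            f"aggregate_ranks: models for scope {scope!r} share no features"
        )
    universe = sorted(universe)
    mat = np.vstack([rv[universe].to_numpy(float) for rv in rank_vectors])
    means = mat.mean(axis=0)
    order = sorted(range(len(universe)), key=lambda i: (means[i], universe[i]))
    entries = [(universe[i], float(means[i])) for i in order]
    return RankedFeatureList(scope=scope, entries=entries, n_models_integrated=len(rank_vectors))


def _exact_ranksum_p(positions: np.ndarray, m: int, observed: float) -> float:
    """Exhaustive-permutation p: the probability that m features placed
    uniformly at random on these list positions achieve a rank sum at least
    as extreme (small) as observed."""
    count = sum(
        1 for subset in combinations(positions, m) if sum(subset) <= observed + 1e-9
    )
    return count / comb(len(positions), m)


def transporter_enrichment(
    ranked: RankedFeatureList, annotated: set[str]
) -> EnrichmentResult:
    """Test whether annotated transporters sit near the top of the list.

    One-sided: annotated features should have smaller aggregated ranks than
    the rest.  For small problems (universe <= 12, annotated <= 8) the p is
    an exact enumeration over all placements of the annotated set;
    otherwise a normal-approximation rank-sum (Mann-Whitney) p with tie
    correction.
    """
    universe = ranked.universe
    ann = sorted(set(annotated) & set(universe))
    if not ann:
        return EnrichmentResult(
            scope=ranked.scope, annotated_used=[], statistic=float("nan"),
            p=float("nan"), method="untestable",
        )
    mean_ranks = ranked.to_series()
    positions = pd.Series(
        stats.rankdata(mean_ranks.to_numpy(), method="average"), index=mean_ranks.index
    )
    obs = float(positions[ann].sum())
    rest = [f for f in universe if f not in set(ann)]
    if not rest:
        return EnrichmentResult(
            scope=ranked.scope, annotated_used=ann, statistic=obs, p=1.0,
            method="exact_permutation",
        )
    if len(universe) <= EXACT_MAX_UNIVERSE and len(ann) <= EXACT_MAX_ANNOTATED:
        p = _exact_ranksum_p(positions.to_numpy(), len(ann), obs)
        method = "exact_permutation"
    else:
        _, p = stats.mannwhitneyu(
            mean_ranks[ann].to_numpy(),
            mean_ranks[rest].to_numpy(),
            alternative="less",
            method="asymptotic",
        )
        method = "ranksum_normal"
    return EnrichmentResult(
        scope=ranked.scope, annotated_used=ann, statistic=obs, p=float(p), method=method,
    )


def cellline_enrichment(
    expression: pd.Series, diffsen: DiffSenVector, top_n: int = 10
) -> dict[str, float]:
    """Tail enrichment of extreme-expression cell lines on the resistance
    differential.

    Two one-sided rank-sum p-values: ``p_high`` asks whether the ``top_n``
    highest-expressing cell lines have *higher* DiffSen than the rest
    (efflux-style resistance), ``p_low`` whether the lowest-expressing ones
    do (uptake-style resistance).  Ties at the selection boundary are broken
    deterministically by cell id and logged.
    """
    y = diffsen.to_series()
    cells = sorted(set(expression.dropna().index) & set(y.index))
    n = len(cells)
    if top_n >= n / 2:
        raise ConfigError(f"top_n={top_n} must be < half of {n} usable cells")
    if n < 3 * top_n:
        raise InsufficientCellsError(
            f"cellline_enrichment: need >= {3 * top_n} cells, got {n}"
        )
    expr = expression[cells]
    by_high = sorted(cells, key=lambda c: (-expr[c], c))
    by_low = sorted(cells, key=lambda c: (expr[c], c))
    for ordering, label in ((by_high, "high"), (by_low, "low")):
        if expr[ordering[top_n - 1]] == expr[ordering[top_n]]:
            logger.info(
                "cellline_enrichment(%s): tie at the top_%d boundary of the %s "
                "tail broken by cell id", diffsen.drug_id, top_n, label,
            )
    out = {}
    for ordering, label in ((by_high, "p_high"), (by_low, "p_low")):
        tail = ordering[:top_n]
        rest = ordering[top_n:]
        _, p = stats.mannwhitneyu(
            y[tail].to_numpy(), y[rest].to_numpy(), alternative="greater",
            method="asymptotic",
        )
        out[label] = float(p)
    return out


def importance_scores(
    group_lists: dict[str, RankedFeatureList], group_members: dict[str, list[str]]
) -> dict[str, pd.Series]:
    """Per-drug overall feature importance after structure-group integration.

    importance = (n - mean_rank + 1) / n, monotone decreasing in mean rank:
    the top feature scores 1.0, the bottom 1/n.  Every drug inherits its
    structure group's aggregated list.
    """
    scores: dict[str, pd.Series] = {}
    for gid, ranked in group_lists.items():
        n = len(ranked.entries)
        s = pd.Series(
            [(n - mr + 1.0) / n for _, mr in ranked.entries],
            index=[f for f, _ in ranked.entries],
        )
        for drug in group_members.get(gid, []):
            scores[drug] = s.copy()
            scores[drug].name = drug
    return scores
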