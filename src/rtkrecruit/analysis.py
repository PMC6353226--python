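"""Comparative analyses: ranking metrics, rank deviations, panel summaries,
numerical-vs-analytical agreement, and hierarchical clustering of cell
lines by recruitment profile.

Five ranking metrics are supported: full numerical simulation (bound
copies at steady state), the single-occupancy analytical approximation,
copy number alone, K_D alone (ascending; a multi-site partner is scored
by its strongest edge), and the copy-number/K_D ratio.  Rank 1 is always
the most-recruited / most-favored partner, with alphabetical tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .cell_model import RecruitmentResult, CellProfile, InteractionMap
from .analytical import AnalyticalResult

__all__ = [
    "RANK_METRICS",
    "Ranking",
    "RankDeviation",
    "rank_partners",
    "rank_deviation",
    "cross_cell_summary",
    "compare_numerical_vs_analytical",
    "cluster_cell_lines",
    "recruitment_matrix",
    "ClusterResult",
]

RANK_METRICS = ("simulation", "analytical", "copy_number", "kd", "copy_over_kd")


@dataclass(frozen=True)
class Ranking:
    metric: str
    order: tuple                  # rank 1 first
    values: dict                  # partner -> metric value
    unexpressed: tuple = ()

    @property
    def ranks(self) -> dict:
        return {p: i + 1 for i, p in enumerate(self.order)}

    def rank_of(self, partner) -> int:
        return self.ranks[partner]


def rank_partners(metric: str, result: RecruitmentResult = None,
                  analytical: AnalyticalResult = None,
                  profile: CellProfile = None, imap: InteractionMap = None,
                  partners=None) -> Ranking:
    """Rank the expressed partners of one cell line under one metric.

    Only partners expressed in the cell are ranked; the excluded set is
    reported on the result.  Which inputs are required depends on the
    metric: `simulation` needs a RecruitmentResult, `analytical` an
    AnalyticalResult, and the three naive metrics need the profile and/or
    interaction map.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")

    if partners is None:
        if result is not None:
            partners = list(result.partners)
        elif analytical is not None:
            partners = list(analytical.names)
        elif profile is not None and imap is not None:
            partners = profile.expressed_partners(imap)
        else:
            raise ValueError("cannot infer the partner set from the given inputs")
    if not partners:
        raise ValueError("empty partner set")

    unexpressed = ()
    if profile is not None:
        unexpressed = tuple(sorted(
            p for p in partners if profile.copies.get(p, 0.0) <= 0))
        partners = [p for p in partners if p not in unexpressed]

    if metric == "simulation":
        if result is None:
            raise ValueError("simulation metric needs a RecruitmentResult")
        values = {p: result.bound_copies[p] for p in partners}
        key = lambda p: (-values[p], p)
    elif metric == "analytical":
        if analytical is None:
            raise ValueError("analytical metric needs an AnalyticalResult")
        values = {p: analytical.bound[p] for p in partners}
        key = lambda p: (-values[p], p)
    elif metric == "copy_number":
        if profile is None:
            raise ValueError("copy_number metric needs a CellProfile")
        values = {p: profile.copies.get(p, 0.0) for p in partners}
        key = lambda p: (-values[p], p)
    elif metric == "kd":
        if imap is None:
            raise ValueError("kd metric needs an InteractionMap")
        values = {p: imap.min_kd(p) for p in partners}
        key = lambda p: (values[p], p)      # strongest binder (lowest K_D) first
    else:  # copy_over_kd
        if profile is None or imap is None:
            raise ValueError("copy_over_kd needs a CellProfile and InteractionMap")
        values = {p: profile.copies.get(p, 0.0) / imap.min_kd(p) for p in partners}
        key = lambda p: (-values[p], p)

    return Ranking(metric=metric, order=tuple(sorted(partners, key=key)),
                   values=values, unexpressed=unexpressed)


@dataclass(frozen=True)
class RankDeviation:
    """Signed rank differences (simulation rank minus alternative rank).

    A negative deviation means the alternative metric predicted less
    binding (a worse rank) than the numerical simulation did.
    """

    reference: str
    alternative: str
    deviations: dict
    n_discrepant: int


def rank_deviation(sim: Ranking, alt: Ranking) -> RankDeviation:
    if set(sim.order) != set(alt.order):
        raise ValueError("rankings cover different partner sets")
    dev = {p: sim.rank_of(p) - alt.rank_of(p) for p in sim.order}
    return RankDeviation(
        reference=sim.metric, alternative=alt.metric, deviations=dev,
        n_discrepant=sum(1 for d in dev.values() if d != 0),
    )


def cross_cell_summary(rankings: dict, top_k: int = 5,
                       unexpressed: str = "exclude") -> pd.DataFrame:
    """Per-protein rank statistics across cell lines.

    ``rankings`` maps cell-line name -> Ranking.  For each protein:
    mean and SD of its rank over the lines where it is expressed, the
    expression count, and the fraction of lines where it ranks 1st..k-th.
    With ``unexpressed="last"`` an unexpressed protein is instead assigned
    rank (m+1) in that line, m = number of ranked partners there.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    if unexpressed not in ("exclude", "last"):
        raise ValueError("unexpressed must be 'exclude' or 'last'")
    proteins = sorted({p for r in rankings.values()
                       for p in list(r.order) + list(r.unexpressed)})
    rows = []
    for p in proteins:
        ranks, n_expr, tops = [], 0, np.zeros(top_k)
        for r in rankings.values():
            if p in r.ranks:
                rk = r.rank_of(p)
                n_expr += 1
                ranks.append(rk)
                if rk <= top_k:
                    tops[rk - 1] += 1
            elif unexpressed == "last" and p in r.unexpressed:
                ranks.append(len(r.order) + 1)
        arr = np.asarray(ranks, dtype=float)
        rows.append({
            "protein": p,
            "mean_rank": arr.mean() if arr.size else np.nan,
            "sd_rank": arr.std(ddof=1) if arr.size > 1 else 0.0,
            "n_expressed": n_expr,
            **{f"share_rank{i + 1}": tops[i] / len(rankings) for i in range(top_k)},
        })
    return pd.DataFrame(rows).set_index("protein")


def compare_numerical_vs_analytical(result: RecruitmentResult,
                                    analytical: AnalyticalResult,
                                    volume: float) -> tuple:
    """Pearson r between per-partner bound molecules from the two methods.

    Returns (r, p_value, scatter DataFrame).  Needs at least 3 shared
    partners for a defined correlation.
    """
    shared = sorted(set(result.partners) & set(analytical.names))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared partners for a correlation")
    a = analytical.bound_copies(volume)
    tab = pd.DataFrame({
        "numerical": [result.bound_copies[p] for p in shared],
        "analytical": [a[p] for p in shared],
    }, index=shared)
    r, p = stats.pearsonr(tab["numerical"], tab["analytical"])
    return float(r), float(p), tab


def recruitment_matrix(results: list, denominator: str = "monomers") -> pd.DataFrame:
    """Cell-line x protein matrix of normalized recruitment (absent -> 0)."""
    from .cell_model import normalized_recruitment

    rows = {}
    for res in results:
        rows[res.cell] = normalized_recruitment(res, denominator=denominator)
    return pd.DataFrame(rows).T.fillna(0.0)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    matrix: pd.DataFrame            # reordered

    def heatmap_table(self) -> pd.DataFrame:
        return self.matrix


def cluster_cell_lines(matrix: pd.DataFrame) -> ClusterResult:
    """Ward hierarchical clustering of cell lines (rows) and proteins (cols).

    Euclidean distances feed Ward linkage; leaf order is the deterministic
    scipy dendrogram order.  NaNs are rejected.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaNs; fill unexpressed entries with 0")
    if len(matrix) < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    row_link = hierarchy.ward(matrix.to_numpy())
    col_link = hierarchy.ward(matrix.to_numpy().T)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(
        row_linkage=row_link, col_linkage=col_link,
        row_order=row_order, col_order=col_order,
        matrix=matrix.loc[row_order, col_order],
    )
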