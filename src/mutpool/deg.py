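"""DEG threshold filtering, multi-set overlap/concordance, and clustering.

A differential-expression contrast is a table of (gene_id, log2fc, pvalue)
rows.  DEGs are genes with P <= 0.05 and |log2FC| >= 1 (both bounds
inclusive); the fold-change bound is two-sided so both up- and downregulated
genes qualify, with the sign of log2FC giving the direction.  Overlap
summaries report exact set-algebra counts between two or three contrasts —
intersections, direction-concordant subsets, down-down subsets — and the
derived percentages, rounded half-up to one decimal.  Log2FC matrices of
shared DEGs are clustered hierarchically (complete linkage, Euclidean
distance) for heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .mapping import IntegrityError


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (printed-table style)."""
    if denominator == 0:
        return 0.0
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class DEGTable:
    """One mutant-vs-wild-type contrast.

    ``data`` columns: gene_id, log2fc, pvalue, and (after filtering)
    direction in {"up", "down"}.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pvalue"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DEGTable {self.name!r} missing columns {sorted(missing)}")
        if self.data["gene_id"].duplicated().any():
            dup = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise IntegrityError(f"duplicate gene {dup!r} in table {self.name!r}")
        p = self.data["pvalue"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"p-values outside [0, 1] in table {self.name!r}")

    @property
    def is_filtered(self) -> bool:
        return "direction" in self.data.columns

    def genes(self) -> set[str]:
        return set(self.data["gene_id"])

    def direction_of(self) -> dict[str, str]:
        if not self.is_filtered:
            raise ValueError(f"table {self.name!r} has no direction labels; run filter_degs")
        return dict(zip(self.data["gene_id"], self.data["direction"]))


def filter_degs(
    table: DEGTable, p_max: float = 0.05, min_abs_log2fc: float = 1.0
) -> DEGTable:
    """Restrict a contrast to its DEGs and label each with a direction.

    Keeps rows with p <= p_max and |log2fc| >= min_abs_log2fc (inclusive).
    Idempotent.  A log2fc of exactly 0 cannot survive a positive fold-change
    bound, so every kept gene has a well-defined direction.
    """
    df = table.data
    keep = (df["pvalue"] <= p_max) & (df["log2fc"].abs() >= min_abs_log2fc)
    out = df.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return DEGTable(name=table.name, data=out.reset_index(drop=True))


@dataclass(frozen=True)
class SetStats:
    name: str
    n_deg: int
    n_up: int
    n_down: int


@dataclass(frozen=True)
class PairStats:
    """Overlap between two DEG sets, with printed-style percentages."""

    a: str
    b: str
    n_intersection: int
    n_same_direction: int
    n_down_down: int
    n_up_up: int
    pct_of_a: float            # intersection as % of set a
    pct_of_b: float
    pct_same_direction: float  # concordant as % of intersection
    pct_down_down: float       # down-down as % of concordant
    pct_down_a_in_b: float     # down(a) also down in b, as % of down(a)
    pct_down_b_in_a: float


@dataclass(frozen=True)
class FocalStats:
    """Three-set statistics viewed against one focal contrast (e.g. the
    double mutant): how the pair's downregulated genes behave there."""

    pair: tuple[str, str]
    focal: str
    n_down_pair: int                  # down in both pair members
    n_down_pair_down_focal: int
    pct_down_pair_down_focal: float   # e.g. 654/666 -> 98.2
    n_union_down: int                 # down in either pair member
    n_union_down_deg_focal: int       # of those, DEG (any direction) in focal
    pct_union_down_deg_focal: float   # e.g. 1197/1328 -> 90.1
    n_down_focal_only: int            # down in focal, DEG in neither pair member


@dataclass
class OverlapSummary:
    sets: list[SetStats]
    pairs: list[PairStats]
    n_triple: int | None = None
    n_all_down: int | None = None
    focal: list[FocalStats] = field(default_factory=list)

    def pair(self, a: str, b: str) -> PairStats:
        for p in self.pairs:
            if {p.a, p.b} == {a, b}:
                return p
        raise KeyError((a, b))

    def focal_view(self, focal: str) -> FocalStats:
        for f in self.focal:
            if f.focal == focal:
                return f
        raise KeyError(focal)


def overlap_summary(tables: Sequence[DEGTable]) -> OverlapSummary:
    """Exact overlap/concordance accounting for two or three filtered tables."""
    if not 2 <= len(tables) <= 3:
        raise ValueError("overlap_summary takes 2 or 3 tables")
    names = [t.name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("tables must have distinct names")
    dirs = {t.name: t.direction_of() for t in tables}
    sets = {t.name: set(dirs[t.name]) for t in tables}
    downs = {n: {g for g, d in dirs[n].items() if d == "down"} for n in names}
    ups = {n: {g for g, d in dirs[n].items() if d == "up"} for n in names}

    set_stats = [
        SetStats(name=n, n_deg=len(sets[n]), n_up=len(ups[n]), n_down=len(downs[n]))
        for n in names
    ]
    pair_stats = []
    for a, b in combinations(names, 2):
        inter = sets[a] & sets[b]
        same = {g for g in inter if dirs[a][g] == dirs[b][g]}
        dd = downs[a] & downs[b]
        uu = ups[a] & ups[b]
        pair_stats.append(
            PairStats(
                a=a,
                b=b,
                n_intersection=len(inter),
                n_same_direction=len(same),
                n_down_down=len(dd),
                n_up_up=len(uu),
                pct_of_a=pct(len(inter), len(sets[a])),
                pct_of_b=pct(len(inter), len(sets[b])),
                pct_same_direction=pct(len(same), len(inter)),
                pct_down_down=pct(len(dd), len(same)),
                pct_down_a_in_b=pct(len(dd), len(downs[a])),
                pct_down_b_in_a=pct(len(dd), len(downs[b])),
            )
        )

    summary = OverlapSummary(sets=set_stats, pairs=pair_stats)
    if len(tables) == 3:
        summary.n_triple = len(sets[names[0]] & sets[names[1]] & sets[names[2]])
        summary.n_all_down = len(downs[names[0]] & downs[names[1]] & downs[names[2]])
        for focal in names:
            a, b = [n for n in names if n != focal]
            down_pair = downs[a] & downs[b]
            down_pair_focal = down_pair & downs[focal]
            union_down = downs[a] | downs[b]
            union_in_focal = union_down & sets[focal]
            summary.focal.append(
                FocalStats(
                    pair=(a, b),
                    focal=focal,
                    n_down_pair=len(down_pair),
                    n_down_pair_down_focal=len(down_pair_focal),
                    pct_down_pair_down_focal=pct(len(down_pair_focal), len(down_pair)),
                    n_union_down=len(union_down),
                    n_union_down_deg_focal=len(union_in_focal),
                    pct_union_down_deg_focal=pct(len(union_in_focal), len(union_down)),
                    n_down_focal_only=len(downs[focal] - sets[a] - sets[b]),
                )
            )
    return summary


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    ordered: pd.DataFrame


def cluster_log2fc(matrix: pd.DataFrame, impute_zero: bool = False) -> ClusterResult:
    """Hierarchical clustering of a genes x contrasts log2FC matrix.

    Complete linkage on Euclidean distances, applied to rows and columns;
    returns both merge trees and the leaf-ordered matrix for heat-map
    display.  Missing values are an error unless ``impute_zero`` is set.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 contrast columns")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_zero:
            raise ValueError("matrix contains NaN; pass impute_zero=True to zero-fill")
        values = np.nan_to_num(values)
    row_linkage = linkage(values, method="complete", metric="euclidean")
    col_linkage = linkage(values.T, method="complete", metric="euclidean")
    row_order = [matrix.index[i] for i in leaves_list(row_linkage)]
    col_order = [matrix.columns[i] for i in leaves_list(col_linkage)]
    ordered = matrix.loc[row_order, col_order]
    return ClusterResult(
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_order=row_order,
        col_order=col_order,
        ordered=ordered,
    )
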