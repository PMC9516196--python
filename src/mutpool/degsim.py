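"""Constructed DEG tables and term annotations with plantable structure.

The DEG simulator is deliberately *constructive*: the caller specifies, as
membership/direction "cells", exactly how many genes fall into each
combination of contrasts and directions, and the simulator assigns genes to
cells deterministically under a seed.  Realized intersection sizes and
concordance fractions therefore equal their targets exactly, which makes
printed overlap percentages reproducible without sampling noise.  Only the
nuisance quantities — which genes land where, DEG P-values and fold-change
magnitudes, non-DEG statistics — are random.

The annotation simulator draws gene sets per ontology term, optionally
oversampling a designated DEG-like subset by a stated fold so that
enrichment power can be measured against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .deg import DEGTable


@dataclass(frozen=True)
class OverlapCell:
    """``count`` genes share this membership pattern: contrast -> direction."""

    pattern: tuple[tuple[str, str], ...]  # ((contrast, "up"/"down"), ...)
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("cell count must be >= 0")
        if not self.pattern:
            raise ValueError("cell pattern must name at least one contrast")
        for _, direction in self.pattern:
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be up/down, got {direction!r}")

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(self.pattern)


def cell(pattern: Mapping[str, str], count: int) -> OverlapCell:
    return OverlapCell(pattern=tuple(sorted(pattern.items())), count=count)


@dataclass
class DEGSimSpec:
    """Recipe for a family of contrasts sharing one gene universe."""

    n_genes: int
    contrasts: tuple[str, ...]
    cells: tuple[OverlapCell, ...]
    deg_p_max: float = 0.05
    lfc_min: float = 1.0        # DEG |log2FC| = lfc_min + Exponential(lfc_scale)
    lfc_scale: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = sum(c.count for c in self.cells)
        if total > self.n_genes:
            raise ValueError(
                f"cells place {total} genes but the universe holds {self.n_genes}"
            )
        for c in self.cells:
            unknown = set(c.as_dict) - set(self.contrasts)
            if unknown:
                raise ValueError(f"cell names unknown contrasts {sorted(unknown)}")


def two_set_cells(
    a: str,
    n_a: int,
    b: str,
    n_b: int,
    n_shared: int,
    concordance: float = 1.0,
    down_fraction: float = 0.8,
) -> list[OverlapCell]:
    """Cells realizing a planted pairwise overlap.

    ``n_shared`` genes are DEGs in both contrasts; ``round(concordance *
    n_shared)`` of them share a direction, split between down-down and up-up
    by ``down_fraction``.  Private DEGs are split by ``down_fraction`` too.
    """
    if n_shared > min(n_a, n_b):
        raise ValueError("planted intersection exceeds a set size")
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must be in [0, 1]")
    n_same = round(concordance * n_shared)
    n_disc = n_shared - n_same
    n_dd = round(down_fraction * n_same)
    n_uu = n_same - n_dd
    d1, d2 = n_disc // 2, n_disc - n_disc // 2
    cells = []
    for pattern, count in [
        ({a: "down", b: "down"}, n_dd),
        ({a: "up", b: "up"}, n_uu),
        ({a: "down", b: "up"}, d1),
        ({a: "up", b: "down"}, d2),
    ]:
        if count:
            cells.append(cell(pattern, count))
    for name, n_total in ((a, n_a), (b, n_b)):
        private = n_total - n_shared
        n_down = round(down_fraction * private)
        if n_down:
            cells.append(cell({name: "down"}, n_down))
        if private - n_down:
            cells.append(cell({name: "up"}, private - n_down))
    return cells


def seedling_preset(n_genes: int = 20_000, seed: int = 0) -> DEGSimSpec:
    """Three seedling contrasts (single mutants and their double mutant) with
    the overlap structure of the motivating study.

    Set sizes: s140 1,214 DEGs (866 down / 348 up), dlt 1,345 (1,128 / 217),
    d140 2,066 (1,853 / 213); 757 genes shared by s140 and dlt of which 729
    are direction-concordant and 666 down in both; 654 of those 666 are also
    down in the double mutant, and 1,197 of the 1,328 genes down in either
    single mutant are DEGs in the double mutant.  Degrees of freedom the
    printed figures do not pin down (e.g. the double-mutant status of
    discordant genes) are fixed to the simplest consistent assignment.
    """
    cells = [
        cell({"s140": "down", "dlt": "down", "d140": "down"}, 654),
        cell({"s140": "down", "dlt": "down"}, 12),
        cell({"s140": "down", "dlt": "up"}, 14),
        cell({"s140": "up", "dlt": "down"}, 14),
        cell({"s140": "down", "d140": "down"}, 147),
        cell({"s140": "down"}, 39),
        cell({"dlt": "down", "d140": "down"}, 396),
        cell({"dlt": "down"}, 52),
        cell({"s140": "up", "dlt": "up"}, 63),
        cell({"s140": "up"}, 271),
        cell({"dlt": "up"}, 140),
        cell({"d140": "down"}, 656),
        cell({"d140": "up"}, 213),
    ]
    return DEGSimSpec(
        n_genes=n_genes,
        contrasts=("dlt", "s140", "d140"),
        cells=tuple(cells),
        seed=seed,
    )


def gene_universe(n_genes: int) -> list[str]:
    width = max(6, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_deg_tables(spec: DEGSimSpec) -> dict[str, DEGTable]:
    """Materialize full per-gene tables for every contrast in the spec.

    Every table covers the whole gene universe.  Genes assigned to a cell are
    DEGs in exactly the cell's contrasts with the cell's directions (P drawn
    uniformly in (0, deg_p_max], |log2FC| = lfc_min + Exponential(lfc_scale));
    all other (gene, contrast) entries are nulls with uniform P on [0, 1] and
    |log2FC| strictly below 1 so no gene crosses a threshold by accident.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array(gene_universe(spec.n_genes))
    order = rng.permutation(spec.n_genes)
    assignment: dict[str, dict[str, str]] = {}
    cursor = 0
    for c in spec.cells:
        for g in genes[order[cursor : cursor + c.count]]:
            assignment[g] = c.as_dict
        cursor += c.count

    tables = {}
    for contrast in spec.contrasts:
        p = rng.uniform(0.0, 1.0, size=spec.n_genes)
        lfc = rng.normal(0.0, 0.3, size=spec.n_genes).clip(-0.99, 0.99)
        frame = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "pvalue": p})
        idx = frame.index.to_numpy()
        for i, g in zip(idx, genes):
            direction = assignment.get(g, {}).get(contrast)
            if direction is None:
                continue
            magnitude = spec.lfc_min + rng.exponential(spec.lfc_scale)
            frame.at[i, "log2fc"] = magnitude if direction == "up" else -magnitude
            frame.at[i, "pvalue"] = rng.uniform(0.0, spec.deg_p_max)
        tables[contrast] = DEGTable(name=contrast, data=frame)
    return tables


@dataclass(frozen=True)
class PlantedTerm:
    term_id: str
    fold: float
    size: int | None = None

    def __post_init__(self) -> None:
        if self.fold < 0:
            raise ValueError("fold-enrichment must be >= 0")


@dataclass
class AnnotationSimSpec:
    """Recipe for a flat term -> genes annotation collection."""

    n_terms: int
    term_size_range: tuple[int, int] = (20, 200)
    planted: tuple[PlantedTerm, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if lo < 1 or hi < lo:
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi")
        if self.n_terms < len(self.planted):
            raise ValueError("more planted terms than terms")


def simulate_annotations(
    spec: AnnotationSimSpec,
    gene_universe: Sequence[str],
    target_genes: Iterable[str] = (),
) -> dict[str, frozenset[str]]:
    """Draw term gene sets over ``gene_universe``.

    Unplanted terms sample genes uniformly without replacement (an exact
    null for enrichment testing).  A planted term of size s and fold f draws
    ``Binomial(s, min(1, f*|target|/|universe|))`` genes from ``target_genes``
    (the DEG-like subset) and the rest from outside it, so its expected
    overlap with the target is f times the null expectation.
    """
    universe = list(dict.fromkeys(gene_universe))
    if not universe:
        raise ValueError("gene_universe must be nonempty")
    n = len(universe)
    rng = np.random.default_rng(spec.seed)
    target = [g for g in dict.fromkeys(target_genes) if g in set(universe)]
    target_set = set(target)
    others = [g for g in universe if g not in target_set]

    lo, hi = spec.term_size_range
    if hi > n:
        raise ValueError(f"term size range {spec.term_size_range} exceeds universe size {n}")
    annotations: dict[str, frozenset[str]] = {}
    planted_ids = {p.term_id: p for p in spec.planted}
    n_plain = spec.n_terms - len(spec.planted)
    term_ids = [f"TERM:{i:04d}" for i in range(1, n_plain + 1)]

    for tid in term_ids:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n, size=size, replace=False)
        annotations[tid] = frozenset(universe[i] for i in members)

    for p in planted_ids.values():
        size = p.size if p.size is not None else int(rng.integers(lo, hi + 1))
        if size > n:
            raise ValueError(f"planted term {p.term_id} larger than the universe")
        if p.fold != 1.0 and not target:
            raise ValueError("planted fold != 1 requires target_genes")
        if p.fold == 1.0 or not target:
            members_idx = rng.choice(n, size=size, replace=False)
            annotations[p.term_id] = frozenset(universe[i] for i in members_idx)
            continue
        p_target = min(1.0, p.fold * len(target) / n)
        k = int(rng.binomial(size, p_target))
        k = min(k, len(target), size)
        n_other = size - k
        if n_other > len(others):
            raise ValueError(f"planted term {p.term_id} cannot avoid the target subset")
        chosen = list(rng.choice(len(target), size=k, replace=False))
        members = [target[i] for i in chosen]
        members += [others[i] for i in rng.choice(len(others), size=n_other, replace=False)]
        annotations[p.term_id] = frozenset(members)
    return annotations
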