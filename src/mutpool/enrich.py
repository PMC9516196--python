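"""Fisher-exact term enrichment with permutation-based multiple-testing
correction.

Each ontology term is tested against an expressed-gene background with a 2x2
table (DEG/non-DEG x in-term/out-of-term).  Both one-sided hypergeometric
tails are computed and the smaller is reported together with its direction
(enriched or depleted).  Multiplicity is handled empirically: DEG-sized gene
sets are drawn uniformly from the background, each term's Fisher P is
recomputed per draw, and the corrected P for a term is the add-one-smoothed
fraction of permutations achieving a P at least as small as observed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence, AbstractSet

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term 2x2 counts and test results.

    Counts: ``n_deg_term`` DEGs in the term, ``n_deg_other`` DEGs outside it,
    ``n_term_other`` non-DEG background genes in the term, ``n_rest`` the
    remainder; the four sum to the background size.
    """

    term_id: str
    n_deg_term: int
    n_deg_other: int
    n_term_other: int
    n_rest: int
    fisher_p: float
    direction: str  # enriched | depleted | undefined
    corrected_p: float | None = None
    significant: bool | None = None

    @property
    def background_size(self) -> int:
        return self.n_deg_term + self.n_deg_other + self.n_term_other + self.n_rest


def _tail_p(k: int, n_bg: int, n_term: int, n_deg: int) -> tuple[float, str]:
    """Smaller one-sided hypergeometric tail for overlap ``k`` and its
    direction."""
    upper = float(hypergeom.sf(k - 1, n_bg, n_term, n_deg))  # P(X >= k), enrichment
    lower = float(hypergeom.cdf(k, n_bg, n_term, n_deg))     # P(X <= k), depletion
    if upper < lower:
        return upper, "enriched"
    if lower < upper:
        return lower, "depleted"
    expected = n_deg * n_term / n_bg if n_bg else 0.0
    return upper, "enriched" if k >= expected else "depleted"


def fisher_term_test(
    deg_set: AbstractSet[str],
    term_genes: AbstractSet[str],
    background: AbstractSet[str],
) -> tuple[float, str]:
    """One term's Fisher exact test against the background.

    The term is intersected with the background first.  Returns
    ``(fisher_p, direction)`` where the P-value is the smaller of the two
    one-sided hypergeometric tails.  An empty term-background intersection
    yields (1.0, "undefined").
    """
    if not background:
        raise ValueError("background must be nonempty")
    deg = set(deg_set)
    if not deg <= set(background):
        raise ValueError("deg_set must be a subset of the background")
    term = set(term_genes) & set(background)
    if not term:
        return 1.0, "undefined"
    k = len(deg & term)
    return _tail_p(k, len(background), len(term), len(deg))


def term_table(
    deg_set: AbstractSet[str], term_genes: AbstractSet[str], background: AbstractSet[str]
) -> tuple[int, int, int, int]:
    """The 2x2 contingency counts (summing to the background size)."""
    deg = set(deg_set)
    term = set(term_genes) & set(background)
    a = len(deg & term)
    b = len(deg - term)
    c = len(term - deg)
    d = len(background) - a - b - c
    return a, b, c, d


def term_tests(
    deg_set: AbstractSet[str],
    annotations: Mapping[str, AbstractSet[str]],
    background: AbstractSet[str],
) -> list[EnrichmentResult]:
    """Fisher test of every term, without correction (term order preserved)."""
    results = []
    for term_id, genes in annotations.items():
        p, direction = fisher_term_test(deg_set, genes, background)
        a, b, c, d = term_table(deg_set, genes, background)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                n_deg_term=a,
                n_deg_other=b,
                n_term_other=c,
                n_rest=d,
                fisher_p=p,
                direction=direction,
            )
        )
    return results


def permutation_correct(
    observed: Sequence[EnrichmentResult],
    deg_size: int,
    background: AbstractSet[str],
    annotations: Mapping[str, AbstractSet[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Empirical multiple-testing correction by gene-label permutation.

    For each of ``n_perm`` permutations a gene set of size ``deg_size`` is
    drawn uniformly without replacement from the background and every term's
    Fisher P is recomputed; the corrected P of a term is
    ``(1 + #{permutations with p <= observed}) / (1 + n_perm)`` (add-one
    smoothing, so corrected P is never 0 and always >= 1/(n_perm+1)).

    The permuted statistics depend on the permuted set only through each
    term's overlap count, so per-term P-values are precomputed as a function
    of the count and the permutation loop reduces to sparse set-membership
    counting — numerically identical to naive recomputation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bg = sorted(background)
    n_bg = len(bg)
    if deg_size > n_bg:
        raise ValueError("deg_size exceeds the background size")
    index = {g: i for i, g in enumerate(bg)}
    term_ids = [r.term_id for r in observed]
    obs_p = np.array([r.fisher_p for r in observed])

    # per-term P-value lookup tables over all possible overlap counts
    lookups: list[np.ndarray] = []
    sizes: list[int] = []
    for tid in term_ids:
        term = set(annotations[tid]) & set(bg)
        s = len(term)
        sizes.append(s)
        if s == 0:
            lookups.append(np.ones(1))
            continue
        ks = np.arange(0, min(s, deg_size) + 1)
        upper = hypergeom.sf(ks - 1, n_bg, s, deg_size)
        lower = hypergeom.cdf(ks, n_bg, s, deg_size)
        lookups.append(np.minimum(upper, lower))

    membership = np.zeros((len(term_ids), n_bg), dtype=np.float32)
    for t, tid in enumerate(term_ids):
        for g in annotations[tid]:
            i = index.get(g)
            if i is not None:
                membership[t, i] = 1.0

    rng = np.random.default_rng(seed)
    perm = np.zeros((n_bg, n_perm), dtype=np.float32)
    for j in range(n_perm):
        perm[rng.choice(n_bg, size=deg_size, replace=False), j] = 1.0
    counts = np.rint(membership @ perm).astype(np.int64)  # (n_terms, n_perm)

    exceed = np.zeros(len(term_ids), dtype=np.int64)
    for t in range(len(term_ids)):
        perm_p = lookups[t][np.minimum(counts[t], len(lookups[t]) - 1)]
        exceed[t] = int(np.sum(perm_p <= obs_p[t]))
    corrected = (1 + exceed) / (1 + n_perm)
    return [
        replace(r, corrected_p=float(cp)) for r, cp in zip(observed, corrected)
    ]


def significant_terms(
    results: Iterable[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Terms with corrected P strictly below ``alpha``, sorted ascending by
    corrected P with ties broken by term id."""
    out = []
    for r in results:
        if r.corrected_p is None:
            raise ValueError(f"term {r.term_id} has no corrected_p; run permutation_correct")
        if r.corrected_p < alpha:
            out.append(replace(r, significant=True))
    out.sort(key=lambda r: (r.corrected_p, r.term_id))
    return out


def enrichment_analysis(
    deg_set: AbstractSet[str],
    annotations: Mapping[str, AbstractSet[str]],
    background: AbstractSet[str],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Observed Fisher tests plus permutation correction and significance
    flags, for every term (order preserved)."""
    observed = term_tests(deg_set, annotations, background)
    corrected = permutation_correct(
        observed, len(set(deg_set)), background, annotations, n_perm=n_perm, seed=seed
    )
    return [replace(r, significant=r.corrected_p < alpha) for r in corrected]


def background_from_counts(
    counts: Mapping[str, float] | "pd.Series", min_count: int = 2
) -> set[str]:
    """Expressed-gene background: genes with at least ``min_count`` reads."""
    items = counts.items() if hasattr(counts, "items") else counts.iteritems()
    return {g for g, c in items if c >= min_count}
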