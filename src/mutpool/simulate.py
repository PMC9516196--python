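"""Forward simulation of a mutagenized line and its F2 mapping pools.

The model: a mutagenized line (homozygous for one recessive causal SNP plus a
set of background SNPs) is crossed to its progenitor wild type; the F1 is
heterozygous at every line variant.  F2 individuals are produced by drawing
two recombinant gametes per individual (Haldane map function, no
interference).  Selecting F2 individuals that are homozygous for the causal
allele (the recessive mutant phenotype, fully penetrant) drives the pooled
alt-allele frequency to 1 at the causal locus, to 1 - r at a site at
recombination fraction r from it, and leaves unlinked sites at 0.5 in
expectation.  Pooled sequencing is modelled as Poisson site depth with
binomial alt-read counts, optionally perturbed by a symmetric per-base error
rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import BASES, GenomeSpec, Variant, toy_rice_genome
from .mapping import VariantRecord

# Strand-symmetric single-nucleotide substitution classes.  Sodium azide, like
# EMS, is dominated by G:C -> A:T transitions, which is why the default
# spectrum is heavily weighted toward that class.
SUBSTITUTION_CLASSES = ("GC>AT", "AT>GC", "GC>TA", "GC>CG", "AT>TA", "AT>CG")

DEFAULT_SPECTRUM = {
    "GC>AT": 0.85,
    "AT>GC": 0.03,
    "GC>TA": 0.03,
    "GC>CG": 0.03,
    "AT>TA": 0.03,
    "AT>CG": 0.03,
}

# For each class, the two strand-equivalent (ref, alt) realisations.
_CLASS_PAIRS = {
    "GC>AT": (("G", "A"), ("C", "T")),
    "AT>GC": (("A", "G"), ("T", "C")),
    "GC>TA": (("G", "T"), ("C", "A")),
    "GC>CG": (("G", "C"), ("C", "G")),
    "AT>TA": (("A", "T"), ("T", "A")),
    "AT>CG": (("A", "C"), ("T", "G")),
}


class SimulationError(RuntimeError):
    """Raised when a simulation spec cannot plausibly be satisfied."""


def substitution_class(ref: str, alt: str) -> str:
    """Map a (ref, alt) substitution to its strand-symmetric class."""
    for cls, pairs in _CLASS_PAIRS.items():
        if (ref, alt) in pairs:
            return cls
    raise ValueError(f"not a single-base substitution: {ref}>{alt}")


@dataclass(frozen=True)
class MutantLine:
    """Simulated truth for one mutagenized line.

    ``causal`` is the single recessive phenotype-causing SNP; ``background``
    are the unlinked-or-linked passenger mutations induced by the mutagen.
    All variants are homozygous in the line.
    """

    line_id: str
    causal: Variant
    background: tuple[Variant, ...]
    spectrum_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_SPECTRUM.items())

    def __post_init__(self) -> None:
        keys = {(v.chrom, v.pos) for v in self.background}
        if len(keys) != len(self.background):
            raise ValueError("background variants share a (chrom, pos)")
        if (self.causal.chrom, self.causal.pos) in keys:
            raise ValueError("causal variant collides with a background variant")

    @property
    def variants(self) -> list[Variant]:
        """All line variants (causal first, then background in position order)."""
        return [self.causal, *sorted(self.background)]


@dataclass(frozen=True)
class F2PoolSpec:
    """How an F2 pool is selected and sequenced."""

    n_individuals: int = 76
    depth: float = 20.0
    error_rate: float = 0.0
    selection: str = "mutant_phenotype"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.selection not in ("mutant_phenotype", "unselected"):
            raise ValueError(f"unknown selection mode {self.selection!r}")


def simulate_mutagenesis(
    genome: GenomeSpec,
    n_background: int,
    causal_position: tuple | Variant,
    seed: int = 0,
    spectrum_weights: dict[str, float] | None = None,
    line_id: str = "line",
    exclude_positions: Iterable[tuple[str, int]] = (),
) -> MutantLine:
    """Draw a mutagenized line: one causal SNP plus uniform background SNPs.

    ``causal_position`` is either ``(chrom, pos)`` (ref/alt drawn from the
    spectrum) or ``(chrom, pos, ref, alt)``.  Background positions are uniform
    over the genome; position collisions (within the line or with
    ``exclude_positions``, e.g. another line sharing the same reference) are
    resolved by redrawing, so the requested count is always realised.
    Substitutions are drawn from ``spectrum_weights`` (default: 85%
    G:C->A:T transitions).
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    weights = dict(spectrum_weights or DEFAULT_SPECTRUM)
    unknown = set(weights) - set(SUBSTITUTION_CLASSES)
    if unknown:
        raise ValueError(f"unknown substitution classes: {sorted(unknown)}")
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("spectrum weights must sum to a positive value")
    classes = [c for c in SUBSTITUTION_CLASSES if weights.get(c, 0) > 0]
    probs = np.array([weights[c] for c in classes]) / total_w

    rng = np.random.default_rng(seed)

    causal = tuple(causal_position)
    chrom, pos = causal[0], int(causal[1])
    if not genome.contains(chrom, pos):
        raise ValueError(f"causal position {chrom}:{pos} outside genome bounds")
    if len(causal) == 4:
        ref, alt = str(causal[2]).upper(), str(causal[3]).upper()
        substitution_class(ref, alt)  # validates
    elif len(causal) == 2:
        ref, alt = _draw_substitution(rng, classes, probs)
    else:
        raise ValueError("causal_position must be (chrom, pos) or (chrom, pos, ref, alt)")
    causal_variant = Variant(chrom, pos, ref, alt)

    lengths = genome.lengths
    names = genome.names
    chrom_p = np.array([lengths[n] for n in names], dtype=float)
    chrom_p /= chrom_p.sum()

    taken = {(chrom, pos)} | set(exclude_positions)
    background: list[Variant] = []
    while len(background) < n_background:
        c = names[rng.choice(len(names), p=chrom_p)]
        p = int(rng.integers(1, lengths[c] + 1))
        if (c, p) in taken:
            continue  # redraw on collision, never drop
        taken.add((c, p))
        r, a = _draw_substitution(rng, classes, probs)
        background.append(Variant(c, p, r, a))

    return MutantLine(
        line_id=line_id,
        causal=causal_variant,
        background=tuple(sorted(background)),
        spectrum_weights=tuple(sorted(weights.items())),
    )


def _draw_substitution(rng: np.random.Generator, classes, probs) -> tuple[str, str]:
    cls = classes[rng.choice(len(classes), p=probs)]
    pairs = _CLASS_PAIRS[cls]
    return pairs[int(rng.integers(2))]


def _simulate_gametes(
    rng: np.random.Generator,
    positions: np.ndarray,
    rate_cm_per_mb: float,
    n_gametes: int,
) -> np.ndarray:
    """Boolean (n_gametes, n_sites) array: True where the gamete carries the
    mutant-parent haplotype.  Markov crossover process along the chromosome
    with Haldane inter-site recombination fractions (consistent under
    composition, i.e. no interference)."""
    m = positions.size
    start = rng.random((n_gametes, 1)) < 0.5
    if m == 1:
        return start
    d_morgan = np.diff(positions) * rate_cm_per_mb / 1e6 / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    switches = rng.random((n_gametes, m - 1)) < r
    parity = np.cumsum(switches, axis=1) % 2 == 1
    return np.concatenate([start, start ^ parity], axis=1)


def _simulate_genotypes(
    rng: np.random.Generator,
    line: MutantLine,
    genome: GenomeSpec,
    sites: list[Variant],
    n_individuals: int,
) -> np.ndarray:
    """(n_individuals, n_sites) int8 genotype matrix (count of alt alleles)."""
    geno = np.empty((n_individuals, len(sites)), dtype=np.int8)
    col = {(v.chrom, v.pos): i for i, v in enumerate(sites)}
    for name in genome.names:
        chrom_sites = [v for v in sites if v.chrom == name]
        if not chrom_sites:
            continue
        pos = np.array([v.pos for v in chrom_sites], dtype=float)
        g = _simulate_gametes(rng, pos, genome.rate(name), 2 * n_individuals)
        alleles = g[0::2].astype(np.int8) + g[1::2].astype(np.int8)
        idx = [col[(v.chrom, v.pos)] for v in chrom_sites]
        geno[:, idx] = alleles
    return geno


def simulate_f2_pool(
    line: MutantLine,
    genome: GenomeSpec,
    spec: F2PoolSpec,
    pool_id: str | None = None,
) -> list[VariantRecord]:
    """Simulate pooled sequencing of a selected (or unselected) F2 population.

    Returns one :class:`VariantRecord` per line variant, in (chrom, pos)
    order, with the true pooled alt-allele frequency retained on the record as
    ``true_alt_freq``.  Under ``mutant_phenotype`` selection only individuals
    homozygous for the causal alt allele enter the pool.
    """
    for v in line.variants:
        if not genome.contains(v.chrom, v.pos):
            raise ValueError(f"line variant {v} outside genome bounds")
    rng = np.random.default_rng(spec.seed)
    sites = sorted(line.variants)
    causal_idx = sites.index(line.causal)
    n = spec.n_individuals

    if spec.selection == "unselected":
        geno = _simulate_genotypes(rng, line, genome, sites, n)
    else:
        kept: list[np.ndarray] = []
        n_kept = 0
        attempts = 0
        max_attempts = 100 * n
        while n_kept < n:
            batch = min(max(int((n - n_kept) * 4.5) + 16, 32), max_attempts - attempts)
            if batch <= 0:
                raise SimulationError(
                    f"no homozygous-mutant individuals obtained in {max_attempts} "
                    f"attempts; spec is implausible for this line/genome"
                )
            g = _simulate_genotypes(rng, line, genome, sites, batch)
            attempts += batch
            sel = g[g[:, causal_idx] == 2]
            if sel.size:
                kept.append(sel)
                n_kept += sel.shape[0]
            if n_kept < n and attempts >= max_attempts:
                raise SimulationError(
                    f"only {n_kept}/{n} homozygous-mutant individuals after "
                    f"{max_attempts} simulated F2 plants"
                )
        geno = np.concatenate(kept, axis=0)[:n]

    freq = geno.sum(axis=0) / (2.0 * n)
    return _sequence_pool(rng, sites, freq, spec, pool_id or f"{line.line_id}_pool")


def _sequence_pool(
    rng: np.random.Generator,
    sites: Sequence[Variant],
    freq: np.ndarray,
    spec: F2PoolSpec,
    pool_id: str,
) -> list[VariantRecord]:
    depth = rng.poisson(spec.depth, size=len(sites))
    e = spec.error_rate
    p_obs = freq * (1.0 - e) + (1.0 - freq) * e
    alt = rng.binomial(depth, p_obs)
    records = []
    for v, f, d, a in zip(sites, freq, depth, alt):
        records.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref_base=v.ref,
                alt_base=v.alt,
                alt_depth=int(a),
                total_depth=int(d),
                mapping_quality=60.0,
                base_quality=35.0,
                pool_id=pool_id,
                true_alt_freq=float(f),
            )
        )
    return records


def simulate_fixed_pool(
    variants: Sequence[Variant],
    depth: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
    pool_id: str = "wt_pool",
) -> list[VariantRecord]:
    """Sequence a set of variants fixed (homozygous alt) in every pooled plant.

    Models wild-type-versus-reference SNPs: differences between the cross
    parent and the reference assembly that are homozygous in every derived
    pool, hence removable only by shared-SNP exclusion.
    """
    rng = np.random.default_rng(seed)
    sites = sorted(variants)
    freq = np.ones(len(sites))
    spec = F2PoolSpec(n_individuals=1, depth=depth, error_rate=error_rate, selection="unselected")
    return _sequence_pool(rng, sites, freq, spec, pool_id)


@dataclass
class CrossScenario:
    """Two mutagenized lines mapped against one wild type, with shared SNPs."""

    genome: GenomeSpec
    lines: dict[str, MutantLine]
    pools: dict[str, list[VariantRecord]]
    wildtype: list[VariantRecord]
    shared_variants: tuple[Variant, ...]


def simulate_cross_scenario(
    genome: GenomeSpec | None = None,
    n_background: int = 2000,
    n_shared: int = 30,
    causal_positions: dict[str, tuple] | None = None,
    pool_sizes: dict[str, int] | None = None,
    depth: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> CrossScenario:
    """Simulate the two-mutant mapping design: two independently mutagenized
    lines, each crossed to the same wild type, F2 mutant pools sequenced, and
    a set of wild-type-vs-reference SNPs shared by every pool.

    Defaults mirror the study conditions: mutant pools of 18 and 76 plants at
    ~20x, causal SNPs in the same region of chromosome 7, and 2000 background
    mutations per line.
    """
    genome = genome or toy_rice_genome()
    causal_positions = causal_positions or {
        "s76": ("chr7", 4_800_000, "G", "A"),
        "s140": ("chr7", 5_200_000, "C", "T"),
    }
    pool_sizes = pool_sizes or {"s76": 18, "s140": 76}
    rng = np.random.default_rng(seed)

    shared: list[Variant] = []
    taken: set[tuple[str, int]] = set()
    lengths = genome.lengths
    names = genome.names
    chrom_p = np.array([lengths[n] for n in names], dtype=float)
    chrom_p /= chrom_p.sum()
    while len(shared) < n_shared:
        c = names[rng.choice(len(names), p=chrom_p)]
        p = int(rng.integers(1, lengths[c] + 1))
        if (c, p) in taken:
            continue
        taken.add((c, p))
        ref = BASES[int(rng.integers(4))]
        alt = rng.choice([b for b in BASES if b != ref])
        shared.append(Variant(c, p, ref, str(alt)))
    shared_t = tuple(sorted(shared))

    lines: dict[str, MutantLine] = {}
    pools: dict[str, list[VariantRecord]] = {}
    for name, causal in causal_positions.items():
        line_seed = int(rng.integers(2**31))
        pool_seed = int(rng.integers(2**31))
        shared_seed = int(rng.integers(2**31))
        # lines share one reference: no two variants may disagree on a
        # position's ref base, so positions are kept disjoint across sets
        line = simulate_mutagenesis(
            genome, n_background, causal, seed=line_seed, line_id=name,
            exclude_positions=taken,
        )
        taken.update((v.chrom, v.pos) for v in line.variants)
        lines[name] = line
        spec = F2PoolSpec(
            n_individuals=pool_sizes[name],
            depth=depth,
            error_rate=error_rate,
            selection="mutant_phenotype",
            seed=pool_seed,
        )
        recs = simulate_f2_pool(line, genome, spec)
        # shared parental SNPs are fixed in every pool
        recs += simulate_fixed_pool(
            shared_t, depth=depth, error_rate=error_rate, seed=shared_seed,
            pool_id=f"{name}_pool",
        )
        pools[name] = sorted(recs, key=lambda r: (r.chrom, r.pos))

    wildtype = simulate_fixed_pool(
        shared_t, depth=depth, error_rate=error_rate,
        seed=int(rng.integers(2**31)), pool_id="wildtype",
    )
    return CrossScenario(
        genome=genome, lines=lines, pools=pools, wildtype=wildtype,
        shared_variants=shared_t,
    )
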