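"""Toy genome description and reference-sequence synthesis.

A :class:`GenomeSpec` carries chromosome names/lengths and a uniform
per-chromosome recombination rate (cM/Mb).  It stands in for the physical +
genetic map of a real reference genome at a scale where whole-genome forward
simulation of an F2 cross is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class Variant(NamedTuple):
    """A single-nucleotide substitution in genome coordinates (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes plus a uniform genetic map per chromosome.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    cm_per_mb
        Recombination rate in centimorgans per megabase.  Either a single
        number applied to every chromosome or a mapping ``name -> rate``.
    """

    chromosomes: tuple[tuple[str, int], ...]
    cm_per_mb: float | Mapping[str, float] = 4.0

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for name in names:
            if self.rate(name) < 0:
                raise ValueError(f"negative cM/Mb rate for chromosome {name!r}")
        object.__setattr__(self, "chromosomes", tuple((n, int(l)) for n, l in self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def rate(self, chrom: str) -> float:
        """cM/Mb rate for ``chrom``."""
        if isinstance(self.cm_per_mb, Mapping):
            return float(self.cm_per_mb[chrom])
        return float(self.cm_per_mb)

    def contains(self, chrom: str, pos: int) -> bool:
        length = self.lengths.get(chrom)
        return length is not None and 1 <= pos <= length

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def toy_rice_genome(
    n_chromosomes: int = 12,
    chrom_length: int = 10_000_000,
    cm_per_mb: float = 4.0,
) -> GenomeSpec:
    """A 12-chromosome toy genome with rice-like recombination density.

    The physical scale is reduced (10 Mb per chromosome by default) so that
    forward simulation of hundreds of F2 individuals over thousands of
    variant sites stays fast, while the genetic length per chromosome
    (20 cM at the defaults) still produces the characteristic allele
    frequency decay around a selected locus.
    """
    chroms = tuple((f"chr{i}", chrom_length) for i in range(1, n_chromosomes + 1))
    return GenomeSpec(chromosomes=chroms, cm_per_mb=cm_per_mb)


def synthesize_reference(
    genome: GenomeSpec,
    variants: Sequence[Variant] = (),
    seed: int = 0,
) -> dict[str, str]:
    """Generate a random reference sequence consistent with ``variants``.

    Every variant's ``ref`` base is written into the sequence at its
    position, so the invariant "variant ref matches the reference" holds by
    construction.  Intended for the small genomes used in annotation and
    file-format round trips.
    """
    rng = np.random.default_rng(seed)
    base_arr = np.array(list("ACGT"))
    out: dict[str, str] = {}
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        if not genome.contains(v.chrom, v.pos):
            raise ValueError(f"variant {v} outside genome bounds")
        by_chrom.setdefault(v.chrom, []).append(v)
    for name, length in genome.chromosomes:
        seq = base_arr[rng.integers(0, 4, size=length)]
        for v in by_chrom.get(name, ()):
            seq[v.pos - 1] = v.ref
        out[name] = "".join(seq)
    return out


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
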