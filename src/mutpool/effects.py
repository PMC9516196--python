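"""Codon-level effect annotation of candidate SNPs against gene models.

Given a point substitution and a CDS gene model, locate the affected codon
(strand-aware), translate reference and mutated codons with the standard
nuclear genetic code, and classify the change as synonymous, missense or
nonsense; variants outside the CDS are classified noncoding, or
splice-adjacent when they fall within 2 bp of an intron-side CDS boundary.
A protein-domain table lets calls be flagged with the domain (for example a
homeodomain) containing the affected residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .genome import COMPLEMENT
from .mapping import IntegrityError, VariantRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD.stop_codons})

CDS_CATEGORIES = ("synonymous", "missense", "nonsense")
SPLICE_FLANK = 2  # bp of intron adjacent to a CDS boundary called splice-adjacent


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered CDS segments plus optional domains.

    ``cds`` segments are (start, end) 1-based inclusive genomic intervals,
    ordered 5'->3' in transcript orientation (descending genomic coordinates
    on the minus strand).  ``domains`` are (name, aa_start, aa_end) with
    1-based inclusive amino-acid coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds:
            raise ValueError("gene model needs at least one CDS segment")
        segs = tuple((int(a), int(b)) for a, b in self.cds)
        for a, b in segs:
            if a > b or a < 1:
                raise ValueError(f"bad CDS segment ({a}, {b})")
        genomic = sorted(segs)
        for (_s1, e1), (s2, _e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError("CDS segments overlap")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if segs != tuple(expected):
            raise ValueError("CDS segments must be ordered 5'->3' in transcript orientation")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.gene_id} not divisible by 3"
            )
        object.__setattr__(self, "cds", segs)
        object.__setattr__(self, "domains", tuple(self.domains))

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) of the CDS."""
        return min(a for a, _ in self.cds), max(b for _, b in self.cds)

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, in
        transcript orientation; None when pos is not coding."""
        offset = 0
        for a, b in self.cds:
            if a <= pos <= b:
                return offset + (pos - a if self.strand == "+" else b - pos)
            offset += b - a + 1
        return None

    def genomic_position(self, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset`."""
        if not 0 <= cds_offset < self.cds_length:
            raise ValueError("cds_offset out of range")
        remaining = cds_offset
        for a, b in self.cds:
            seg_len = b - a + 1
            if remaining < seg_len:
                return a + remaining if self.strand == "+" else b - remaining
            remaining -= seg_len
        raise AssertionError("unreachable")

    def is_splice_adjacent(self, pos: int) -> bool:
        """True when ``pos`` lies in an intron within SPLICE_FLANK bp of a
        CDS segment boundary."""
        genomic = sorted(self.cds)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if e1 < pos < s2 and (pos - e1 <= SPLICE_FLANK or s2 - pos <= SPLICE_FLANK):
                return True
        return False


@dataclass(frozen=True)
class EffectCall:
    """Consequence of one substitution on one gene model (or none)."""

    gene_id: str | None
    category: str  # synonymous | missense | nonsense | noncoding | splice-adjacent
    codon_number: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    domain_hit: str | None = None
    stop_loss: bool = False

    def __post_init__(self) -> None:
        if self.codon_number is not None and self.codon_number < 1:
            raise ValueError("codon_number must be >= 1")
        if self.category == "nonsense" and not (self.alt_aa == "*" and self.ref_aa != "*"):
            raise ValueError("nonsense requires alt stop and non-stop ref")


def get_base(reference, chrom: str, pos: int) -> str:
    """Fetch the reference base at a 1-based position.

    Accepts a plain mapping of chromosome -> sequence string, or any object
    with a samtools-style ``fetch(chrom, start0, end0)`` method (for example
    ``pysam.FastaFile``).
    """
    fetch = getattr(reference, "fetch", None)
    if fetch is not None:
        return fetch(chrom, pos - 1, pos).upper()
    return str(reference[chrom][pos - 1]).upper()


def translate_codon(codon: str) -> str:
    try:
        return CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"cannot translate codon {codon!r}") from None


def annotate_variant(
    record: VariantRecord,
    models: Sequence[GeneModel],
    reference,
) -> list[EffectCall]:
    """Classify one SNP against every overlapping gene model.

    For a coding position the affected codon is read 5'->3' on the coding
    strand (minus-strand variants are complemented), both codons are
    translated, and the call is synonymous / missense / nonsense.  A variant
    overlapping no model, or a model's intron away from splice boundaries,
    yields a single noncoding call.
    """
    try:
        ref_base = get_base(reference, record.chrom, record.pos)
    except KeyError as exc:
        raise IntegrityError(f"chromosome {record.chrom!r} absent from reference") from exc
    if ref_base != record.ref_base.upper():
        raise IntegrityError(
            f"record ref {record.ref_base} does not match reference {ref_base} "
            f"at {record.chrom}:{record.pos}"
        )

    calls: list[EffectCall] = []
    for model in models:
        if model.chrom != record.chrom:
            continue
        lo, hi = model.span
        if not lo <= record.pos <= hi:
            continue
        offset = model.cds_offset(record.pos)
        if offset is None:
            category = "splice-adjacent" if model.is_splice_adjacent(record.pos) else "noncoding"
            calls.append(EffectCall(gene_id=model.gene_id, category=category))
            continue
        codon_number = offset // 3 + 1
        within = offset % 3
        codon_start = offset - within
        bases = []
        for i in range(3):
            gpos = model.genomic_position(codon_start + i)
            b = get_base(reference, model.chrom, gpos)
            bases.append(b if model.strand == "+" else COMPLEMENT[b])
        ref_codon = "".join(bases)
        alt = record.alt_base.upper() if model.strand == "+" else COMPLEMENT[record.alt_base.upper()]
        alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        stop_loss = False
        if ref_aa == alt_aa:
            category = "synonymous"
        elif alt_aa == "*":
            category = "nonsense"
        else:
            category = "missense"
            stop_loss = ref_aa == "*"
        call = EffectCall(
            gene_id=model.gene_id,
            category=category,
            codon_number=codon_number,
            ref_codon=ref_codon,
            alt_codon=alt_codon,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            stop_loss=stop_loss,
        )
        calls.append(domain_overlap(call, model))
    if not calls:
        calls.append(EffectCall(gene_id=None, category="noncoding"))
    return calls


def domain_overlap(call: EffectCall, model: GeneModel) -> EffectCall:
    """Fill ``domain_hit`` with the protein domain containing the affected
    codon (inclusive amino-acid bounds), if any."""
    if call.codon_number is None:
        return call
    for name, aa_start, aa_end in model.domains:
        if aa_start <= call.codon_number <= aa_end:
            return replace(call, domain_hit=name)
    return call
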