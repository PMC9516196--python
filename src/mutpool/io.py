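"""Readers and writers for the pipeline's on-disk formats.

Variant records travel as VCF v4.2 (pysam) with per-sample AD/DP, MQ and BQ
in INFO, and the simulator's hidden true allele frequency as INFO/TF when
present.  References are FASTA (Biopython), gene models GFF3 (gffutils on
read), DEG tables and annotations tab-separated text (pandas), and tracks /
peak regions BED-compatible text.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .deg import DEGTable
from .effects import EffectCall, GeneModel
from .enrich import EnrichmentResult
from .mapping import PeakRegion, ScanResult, VariantRecord

# ---------------------------------------------------------------- VCF

_VCF_HEADER_LINES = [
    ('INFO', 'MQ', '1', 'Float', 'RMS mapping quality'),
    ('INFO', 'BQ', '1', 'Float', 'Mean base quality at the site'),
    ('INFO', 'TF', '1', 'Float', 'True pooled alt-allele frequency (simulation truth)'),
    ('FORMAT', 'AD', 'R', 'Integer', 'Allelic depths (ref, alt)'),
    ('FORMAT', 'DP', '1', 'Integer', 'Total read depth'),
]


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int],
    sample: str | None = None,
) -> None:
    """Write pool records as an uncompressed VCF 4.2 with one sample column."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for kind, key, number, vtype, desc in _VCF_HEADER_LINES:
        header.add_meta(
            kind, items=[("ID", key), ("Number", number), ("Type", vtype), ("Description", desc)]
        )
    sample_name = sample or (records[0].pool_id if records else "pool") or "pool"
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda x: (x.chrom, x.pos)):
            rec = vcf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos,
                alleles=(r.ref_base, r.alt_base),
            )
            rec.info["MQ"] = float(r.mapping_quality)
            rec.info["BQ"] = float(r.base_quality)
            if r.true_alt_freq is not None:
                rec.info["TF"] = float(r.true_alt_freq)
            rec.samples[sample_name]["AD"] = (r.total_depth - r.alt_depth, r.alt_depth)
            rec.samples[sample_name]["DP"] = r.total_depth
            vcf.write(rec)


def read_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Read pool records from a single-sample VCF with AD/DP."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, found {len(samples)} samples")
        sample = samples[0]
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"expected biallelic records, got {rec.alts} at {rec.pos}")
            ad = rec.samples[sample]["AD"]
            dp = rec.samples[sample].get("DP", sum(ad))
            tf = rec.info.get("TF")
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    alt_depth=int(ad[1]),
                    total_depth=int(dp),
                    mapping_quality=float(rec.info.get("MQ", 60.0)),
                    base_quality=float(rec.info.get("BQ", 30.0)),
                    pool_id=sample,
                    true_alt_freq=None if tf is None else float(tf),
                )
            )
    return out


# ---------------------------------------------------------------- FASTA

def write_fasta(reference: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 gene + CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"{m.chrom}\tmutpool\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            phase = 0
            for a, b in m.cds:
                fh.write(
                    f"{m.chrom}\tmutpool\tCDS\t{min(a, b)}\t{max(a, b)}\t.\t{m.strand}\t"
                    f"{phase}\tID={m.gene_id}.cds;Parent={m.gene_id}\n"
                )
                phase = (3 - ((b - a + 1) - phase) % 3) % 3


def read_gff3(
    path: str | os.PathLike,
    domains: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> list[GeneModel]:
    """Read gene models (gene + CDS features) from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        segs = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
        segs.sort()
        if gene.strand == "-":
            segs = segs[::-1]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds=tuple(segs),
                domains=tuple((domains or {}).get(gene_id, ())),
            )
        )
    return models


def read_domains(path: str | os.PathLike) -> dict[str, list[tuple[str, int, int]]]:
    """Side-car TSV: gene_id, domain, aa_start, aa_end."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, []).append((row.domain, int(row.aa_start), int(row.aa_end)))
    return out


# ---------------------------------------------------------------- TSV tables

def write_deg_table(table: DEGTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | os.PathLike, name: str | None = None) -> DEGTable:
    df = pd.read_csv(path, sep="\t")
    return DEGTable(name=name or os.path.splitext(os.path.basename(path))[0], data=df)


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    rows = [
        {"term_id": term, "gene_id": gene}
        for term, genes in annotations.items()
        for gene in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.term_id, set()).add(row.gene_id)
    return {term: frozenset(genes) for term, genes in out.items()}


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gene_list(path: str | os.PathLike) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_enrichment_results(
    results: Sequence[EnrichmentResult], path: str | os.PathLike
) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "n_deg_term": r.n_deg_term,
            "n_deg_other": r.n_deg_other,
            "n_term_other": r.n_term_other,
            "n_rest": r.n_rest,
            "fisher_p": r.fisher_p,
            "direction": r.direction,
            "corrected_p": r.corrected_p,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_effect_calls(calls: Sequence[EffectCall], path: str | os.PathLike) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "category": c.category,
            "codon_number": c.codon_number,
            "ref_codon": c.ref_codon,
            "alt_codon": c.alt_codon,
            "ref_aa": c.ref_aa,
            "alt_aa": c.alt_aa,
            "domain": c.domain_hit,
            "stop_loss": c.stop_loss,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- BED

def write_track_bed(scan: ScanResult, path: str | os.PathLike) -> None:
    """Per-site SNP-index track as BED (chrom, start0, end, index)."""
    df = scan.sites
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.snp_index:.4f}\n")


def write_peaks_bed(peaks: Sequence[PeakRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.mean_index:.4f}\t{p.n_sites}\n")
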