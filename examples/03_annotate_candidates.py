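"""Classify candidate SNPs by their codon consequence in a gene model.

Builds a KNOX-like homeodomain gene in which codon 276 is TGG (tryptophan)
and codon 277 is CCA (proline), then annotates the two kinds of candidate
mutations a mutagen screen typically yields: a G-to-A transition creating a
premature stop, and a C-to-T transition causing a proline-to-serine
substitution — both inside the homeodomain.
"""

from mutpool import GeneModel, VariantRecord, annotate_variant

codons = ["ATG"] + ["GCT"] * 274 + ["TGG"] + ["CCA"] * 9 + ["GCT"] * 14 + ["TAA"]
cds = "".join(codons)
start = 1001
reference = {"chr7": "A" * 1000 + cds + "A" * 1000}
model = GeneModel(
    gene_id="OSH15",
    chrom="chr7",
    strand="+",
    cds=((start, start + len(cds) - 1),),
    domains=(("homeodomain", 260, 320),),
)

for label, pos, ref, alt in [
    ("G-to-A at codon 276, 3rd base", start + 275 * 3 + 2, "G", "A"),
    ("C-to-T at codon 277, 1st base", start + 276 * 3, "C", "T"),
]:
    record = VariantRecord("chr7", pos, ref, alt, alt_depth=18, total_depth=20)
    call = annotate_variant(record, [model], reference)[0]
    print(f"{label}: {call.ref_codon}->{call.alt_codon}  "
          f"{call.ref_aa}{call.codon_number}{call.alt_aa}  [{call.category}]"
          + (f"  in {call.domain_hit}" if call.domain_hit else ""))

print("A nonsense call truncates the protein before the DNA-binding domain")
print("finishes; the missense call substitutes a conserved residue inside it.")
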