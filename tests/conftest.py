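import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from mutpool.effects import GeneModel
from mutpool.genome import GenomeSpec


@pytest.fixture(scope="session")
def knox_gene():
    """A single-exon plus-strand gene engineered so that codon 276 is TGG
    (Trp) inside a homeodomain and codons 277-285 are CCA (Pro) — the layout
    needed to exercise the premature-stop and P->S worked cases."""
    codons = ["ATG"] + ["GCT"] * 274 + ["TGG"] + ["CCA"] * 9 + ["GCT"] * 14 + ["TAA"]
    cds = "".join(codons)
    start = 1001
    reference = {"chr7": "A" * 1000 + cds + "A" * 1000}
    model = GeneModel(
        gene_id="OSH15",
        chrom="chr7",
        strand="+",
        cds=((start, start + len(cds) - 1),),
        domains=(("HD", 260, 320),),
    )
    return model, reference, start


@pytest.fixture(scope="session")
def tiny_genome():
    return GenomeSpec(chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000)), cm_per_mb=4.0)
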