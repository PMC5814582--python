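import numpy as np
import pandas as pd
import pytest

from svmosaic.genes import GeneModel
from svmosaic.synth import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A quick cohort exercising every feature at reduced scale."""
    return SyntheticSpec(
        seed=11,
        n_samples=40,
        n_snp_sites=800,
        n_genes=10,
        n_duplication_segments=4,
        n_duplications_without_artefact=1,
        chrom_length=600_000,
        block_size=60,
        sv_truth_counts={"DEL": 20, "INS": 8, "INV": 4, "TRA_intra": 2, "TRA_inter": 1},
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def toy_gene_fwd():
    """Forward-strand two-exon gene; CDS 2001-2150 + 2351-2500 (300 bp)."""
    return GeneModel(
        gene_id="gfwd",
        chrom="chrT",
        strand="+",
        start=2001,
        end=2500,
        exons=[(2001, 2150), (2351, 2500)],
        cds=[(2001, 2150), (2351, 2500)],
    )


@pytest.fixture(scope="session")
def toy_reference(toy_gene_fwd):
    """10-kb toy chromosome whose gene carries a clean ORF."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=10_000)]
    # build a 100-codon ORF: ATG + 98 non-stop codons + TAA
    codons = ["ATG"]
    while len(codons) < 99:
        c = "".join(bases[rng.integers(0, 4, size=3)])
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    codons.append("TAA")
    orf = "".join(codons)
    off = 0
    for s, e in toy_gene_fwd.cds:
        seq[s - 1 : e] = np.array(list(orf[off : off + e - s + 1]))
        off += e - s + 1
    return {"chrT": "".join(seq)}
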