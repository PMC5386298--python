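import pytest

import vectrace as vt


@pytest.fixture(scope="session")
def vector():
    return vt.default_vector(seed=101)


@pytest.fixture(scope="session")
def tiny_ref():
    """60 kb contig with a 10-exon, 30 kb gene (intron 1 enlarged)."""
    return vt.generate_reference(
        60_000,
        vt.GeneSpec(gene_id="Sorcs2", n_exons=10, exon_len=120, span=30_000, start=20_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_ref, vector):
    """One planted insertion (204 bp deletion, 5 kb into intron 1) plus
    error-free reads at ~25x coverage."""
    gene = tiny_ref.gene_models[0]
    left = gene.introns[0][0] + 5000
    sample, truth = vt.plant_insertions(
        tiny_ref, vector, [vt.InsertionSpec("chr5", left, left + 204)]
    )
    reads = vt.simulate_read_pairs(sample, 8000, seed=13)
    return {
        "ref": tiny_ref,
        "vector": vector,
        "sample": sample,
        "truth": truth,
        "reads": reads,
        "left": left,
        "right": left + 204,
    }
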