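import numpy as np
import pytest

from aseq.simulate import AmpliconSimConfig, GeneTemplate, simulate_amplicon_reads


def make_template(gene_id="fiz", seed=0, length=200, snp_offset=120,
                  allele_a="G", allele_b="A", anchor_len=20):
    """Random but reproducible amplicon template with one diagnostic SNP."""
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length)
    bases[snp_offset] = allele_a
    return GeneTemplate(
        gene_id=gene_id,
        amplicon_seq="".join(bases),
        snp_offset=snp_offset,
        allele_a=allele_a,
        allele_b=allele_b,
        anchor_len=anchor_len,
    )


@pytest.fixture
def template():
    return make_template()


@pytest.fixture
def second_template():
    # a different seed gives a distinct anchor with overwhelming probability;
    # asserted here so the fixture fails loudly if not
    t = make_template(gene_id="CG9512", seed=1, snp_offset=90, allele_a="C", allele_b="T")
    base = make_template()
    assert t.anchor != base.anchor
    return t


def simulate_counts_from_reads(template, true_prop_a, depth, error_rate=0.0, seed=0,
                               sample_id="s1"):
    """Full read-level pipeline: simulate -> assign -> count."""
    from aseq.amplicon import assign_reads_to_genes, count_alleles

    cfg = AmpliconSimConfig(true_prop_a=true_prop_a, depth=depth,
                            error_rate=error_rate, seed=seed)
    reads = simulate_amplicon_reads(template, cfg)
    assigned, _ = assign_reads_to_genes(reads, [template])
    return count_alleles(assigned[template.gene_id], template, sample_id=sample_id)
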