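import io

import pytest

import pharmsv as pv
from pharmsv import synthetic as syn


@pytest.fixture(scope="session")
def genome():
    return syn.generate_genome(n_genes=50, seed=7)


@pytest.fixture(scope="session")
def gene_set(genome):
    return genome.gene_set


@pytest.fixture(scope="session")
def cohort(gene_set):
    return syn.generate_sv_cohort(gene_set, seed=3)


@pytest.fixture(scope="session")
def filtered(cohort):
    return pv.filter_sv_records(cohort.table)


@pytest.fixture(scope="session")
def clusters(filtered):
    return pv.cluster_cohort(filtered)


@pytest.fixture(scope="session")
def member_to_cluster(clusters):
    return {m: c.cluster_id for c in clusters for m in c.members}


@pytest.fixture(scope="session")
def annotated(clusters, gene_set):
    return pv.annotate_svs(clusters, gene_set)


@pytest.fixture(scope="session")
def noncoding_candidates(cohort):
    """(sv_id, gene_id, chrom, start, end) for planted intronic SVs."""
    by_id = {r.sv_id: r for r in cohort.table}
    rows = cohort.truth[cohort.truth.kind.isin(["intronic_del", "intronic_ins"])]
    return [
        (row.sv_id, row.gene_id, by_id[row.sv_id].chrom,
         by_id[row.sv_id].start, by_id[row.sv_id].end)
        for row in rows.itertuples()
    ]


@pytest.fixture(scope="session")
def regulatory_layers(gene_set, noncoding_candidates):
    return syn.generate_regulatory_layers(
        gene_set, noncoding_candidates, n_planted=5, seed=11
    )


def make_gene(exons, panel_class="CYP", gene_id="G", chrom="chr1", flank=0):
    return pv.GeneModel(
        gene_id=gene_id, symbol=gene_id, chrom=chrom, strand="+",
        exons=tuple(exons), panel_class=panel_class, flank=flank,
    )


@pytest.fixture
def toy_gene():
    """Three-exon gene: exons [1000,1200), [2000,2300), [3000,3500)."""
    return make_gene([(1000, 1200), (2000, 2300), (3000, 3500)])
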