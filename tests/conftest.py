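import pytest

from vhcrss.simulate import GeneratorConfig, generate_repertoire


@pytest.fixture(scope="session")
def small_repertoire():
    """A 60-gene synthetic repertoire with decoys, shared across tests."""
    cfg = GeneratorConfig(
        seed=11,
        n_families=5,
        genes_per_family=12,
        n_pseudogenes=2,
        n_secondary_alleles=3,
    )
    rep, ledger = generate_repertoire(cfg)
    return cfg, rep, ledger


def make_gene(seq, gene_id="VHX-1*01", species="sp", family="VH1",
              functional=True, gapped=None):
    from vhcrss.repertoire_io import VhGene

    return VhGene(
        gene_id=gene_id,
        species=species,
        family=family,
        functional=functional,
        seq_nt=seq,
        gapped_nt=gapped,
    )
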