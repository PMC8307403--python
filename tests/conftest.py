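import pytest

from twaskit.simulate import (
    make_gene_annotation,
    simulate_cis_architecture,
    simulate_ld_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def two_pop_genotypes():
    """600 samples x 2000 variants, two populations, FST 0.1, blocked LD."""
    return simulate_ld_genotypes({"AA": 300, "EA": 300}, 2000, fst=0.1, block_size=50, seed=11)


@pytest.fixture(scope="session")
def small_panel():
    """One-population panel with two genes and a known cis architecture."""
    annot = make_gene_annotation(n_genes=2, spacing=1_500_000, start=600_000)
    gm = simulate_ld_genotypes({"AA": 500}, 1200, fst=0.0, pos_step=3500, seed=7)
    expr, truth = simulate_cis_architecture(gm, annot, n_causal_per_gene=3, h2_cis=0.3, seed=8)
    return {"genotypes": gm, "annotation": annot, "expression": expr, "truth": truth}


@pytest.fixture(scope="session")
def pheno_cohort(small_panel):
    gm = small_panel["genotypes"]
    truth = small_panel["truth"]
    duffy = gm.variants["id"].iloc[700]
    pheno = simulate_phenotypes(
        gm, truth,
        gene_trait_effects={"HGB": {small_panel["annotation"]["gene_id"].iloc[0]: 0.3}},
        covariate_effects={"HGB": {"age": 0.2, "sex": 0.3}},
        duffy_variant=duffy, duffy_effect=-0.4, outlier_rate=0.0, seed=9,
    )
    return {"phenotypes": pheno, "duffy": duffy, "truth": truth}
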