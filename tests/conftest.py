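import pytest

from pcscreen.simulate import default_config, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A 3,000-individual cohort drawn from the default study structure."""
    cfg = default_config(seed=424242, n_individuals=3000)
    return simulate_population(cfg)


def make_call(**overrides):
    """A quality-passing heterozygous pathogenic call, fields overridable."""
    from pcscreen.variants import VariantCall

    base = dict(
        individual_id="IND000001",
        gene="CFTR",
        variant_key="CFTR:c.100G>A",
        zygosity="heterozygous",
        depth=30.0,
        base_quality=30.0,
        het_allele_ratio=0.50,
        classification="P",
        population_maf=0.001,
    )
    base.update(overrides)
    return VariantCall(**base)
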