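import numpy as np
import pytest

from prsmap import pipeline
from prsmap.simulate import (
    GeneratorConfig,
    IntegrationSpec,
    generate_chromosome,
    generate_cohort,
)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240927)


#: one integration per anchor geometry, including a minus-strand host, a
#: gene-disrupting insertion with a replacement tRNA, and a nested element
PLANTED_SPECS = (
    IntegrationSpec(host_ordinal=30, anchor="three_prime", att_in_gene_bp=17,
                    att_spacer_bp=10, payload_len_bp=5000, prs_class="GI"),
    IntegrationSpec(host_ordinal=10, anchor="three_prime", att_in_gene_bp=40,
                    att_spacer_bp=6, payload_len_bp=4000, prs_class="int-Ph"),
    IntegrationSpec(host_ordinal=16, anchor="five_prime", att_in_gene_bp=20,
                    att_spacer_bp=0, payload_len_bp=3000, prs_class="q-Ph"),
    IntegrationSpec(host_ordinal=26, anchor="central", att_in_gene_bp=30,
                    att_spacer_bp=0, payload_len_bp=3000, prs_class="int-Ph",
                    carried_trnas=(("Leu", "TAG"),)),
    IntegrationSpec(host_ordinal=39, anchor="three_prime", att_in_gene_bp=46,
                    att_spacer_bp=0, payload_len_bp=20000, prs_class="GI",
                    nested=(15000, 46)),
)


@pytest.fixture(scope="session")
def planted_genome():
    cfg = GeneratorConfig(seed=7, integrations=PLANTED_SPECS)
    return generate_chromosome(cfg)


@pytest.fixture(scope="session")
def bare_genome():
    return generate_chromosome(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(n_strains=27, seed=100)


@pytest.fixture(scope="session")
def cohort_results(cohort):
    return [
        pipeline.analyze_strain(chrom, truth.all_features(), truth.probe)
        for chrom, truth in cohort
    ]
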