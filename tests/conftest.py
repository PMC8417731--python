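import numpy as np
import pytest

from fourway_qtl import linkscan, simdata


@pytest.fixture(scope="session")
def gmap():
    """Two chromosomes, 100 cM, 26 markers (4-cM spacing)."""
    return simdata.build_map(2, 100.0, 26)


@pytest.fixture(scope="session")
def parents(gmap):
    return simdata.simulate_parental_haplotypes(gmap, np.random.default_rng(11))


@pytest.fixture(scope="session")
def population(gmap):
    """144 FW-RIL lines, fixed seed."""
    return simdata.simulate_fwril(gmap, 144, rng=np.random.default_rng(12))


@pytest.fixture(scope="session")
def snp(gmap, parents, population):
    return simdata.founder_to_snp(population, parents)


@pytest.fixture(scope="session")
def phenotypes(gmap, population):
    design = simdata.default_design(seed=13)
    return simdata.simulate_phenotypes(
        population, gmap, simdata.default_qtl(gmap), design)


@pytest.fixture(scope="session")
def founder_probs(gmap, parents, snp):
    return linkscan.infer_founder_probs(snp, gmap, parents)
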