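import numpy as np
import pytest

from kinpen import simulate as sim


@pytest.fixture(scope="session")
def tiny_study():
    """Small complete synthetic dataset shared across test modules:
    4 pedigrees, 60 CV + 60 RV variants, covariates, causal trait."""
    peds = sim.simulate_pedigrees(4, (12, 20), 3, seed=101)
    G = sim.simulate_genotypes(peds, 60, 60, seed=102)
    rel = sim.expected_relationship(peds)
    cov = sim.simulate_covariates(peds.sample_ids, seed=103)
    spec = sim.default_causal_spec(
        G, seed=104, n_causal_cv=3, n_causal_rv=4, sigma_g2=20.0, sigma_r2=80.0
    )
    y = sim.simulate_phenotype(G, cov, spec, rel, seed=105)
    return {
        "peds": peds,
        "G": G,
        "rel": rel,
        "cov": cov,
        "spec": spec,
        "y": y,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_trio_pedigree() -> sim.PedigreeSet:
    """Two founders and two full-sib children, constructed explicitly."""
    fam = sim.Family(
        "T1",
        [
            sim.Member("T1_f", "T1", None, None, 0, 1),
            sim.Member("T1_m", "T1", None, None, 0, 2),
            sim.Member("T1_c1", "T1", "T1_f", "T1_m", 1, 1),
            sim.Member("T1_c2", "T1", "T1_f", "T1_m", 1, 2),
        ],
    )
    return sim.PedigreeSet([fam])
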