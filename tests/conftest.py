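import numpy as np
import pandas as pd
import pytest

from epinet.fitness import CompetitionAssay
from epinet.simulate import simulate_counts


def make_assay(ni_m, nf_m, ni_a, nf_a, dilution=100.0, genotype="mut", temp=42.2,
               rep="r0"):
    return CompetitionAssay(
        genotype_id=genotype, temperature=temp, replicate_id=rep,
        n_initial_mutant=ni_m, n_final_mutant=nf_m,
        n_initial_ancestor=ni_a, n_final_ancestor=nf_a,
        dilution_factor=dilution,
    )


@pytest.fixture(scope="session")
def counts_bundle():
    """One shared synthetic count matrix at study-like scale (n=4 reps)."""
    cm, truth = simulate_counts(n_genes=2000, n_replicates=4, seed=7)
    return cm, truth


@pytest.fixture()
def rng(request):
    # function-scoped and salted by test name: deterministic under any
    # execution order, decorrelated across tests
    import zlib
    salt = zlib.crc32(request.node.nodeid.encode())
    return np.random.default_rng([20240905, salt])
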