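"""Shared fixtures: small hand-built and simulated genotype matrices."""

import msprime
import numpy as np
import pytest

from vicfound import coalsim, demomodels, fitselect
from vicfound.coalsim import N_REF, demography_from_schedule
from vicfound.demomodels import DemographySchedule, EngineSettings, Epoch
from vicfound.sfs import JointSFS, fold_jsfs

ONE_POP_SPEC = demomodels.single_pop_size_change_spec(T=0.5)


def one_pop_data(nu=0.2, seed=5, n_loci=600, theta_locus=5.0, n=12):
    """1D folded SFS under a single-deme expansion (size nu -> 1 at T=0.5)."""
    sch = DemographySchedule(epochs=(Epoch(0.5, 1.0, None),), nuA=nu)
    dem = demography_from_schedule(sch)
    counts = np.zeros(n + 1)
    mu = theta_locus / (4.0 * N_REF)
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n, population="pop1", ploidy=1)],
        ploidy=2,
        demography=dem,
        sequence_length=1.0,
        num_replicates=n_loci,
        random_seed=seed,
    )
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, discrete_genome=False, random_seed=seed * 997 + k + 1
        )
        if mts.num_sites:
            h = (mts.genotype_matrix() > 0).astype(int)
            np.add.at(counts, h.sum(axis=1), 1.0)
    return fold_jsfs(JointSFS(counts[:, None]))


@pytest.fixture(scope="session")
def one_param_fit():
    """Default-protocol fit of the one-parameter expansion model (truth 0.2)."""
    data = one_pop_data(nu=0.2, seed=5, n_loci=1100, theta_locus=5.0)
    assert data.total() > 8000
    fit = fitselect.fit_model_multiround(
        data,
        ONE_POP_SPEC,
        protocol=fitselect.Protocol(
            maxfev=40, n_scatter=10, polish_reps=80000, polish_maxfev=25
        ),
        seed=5,
        engine=EngineSettings(n_reps=3000, seed=5),
    )
    return fit, 0.2


@pytest.fixture
def tiny_gm():
    """Two populations, 2 + 3 diploids, 5 SNP sites, no missing data.

    Site layout (alt-allele counts per individual):
      s0: popA het in ind0            -> derived 1/4 in A, 0/6 in B
      s1: fixed alt in A, absent in B
      s2: polymorphic in both
      s3: monomorphic reference everywhere
      s4: alt only in B
    """
    geno = np.array(
        [
            [1, 0, 0, 0, 0],
            [2, 2, 0, 0, 0],
            [1, 1, 1, 0, 2],
            [0, 0, 0, 0, 0],
            [0, 0, 1, 2, 0],
        ],
        dtype=np.int8,
    )
    depth = np.full(geno.shape, 20, dtype=np.int32)
    return coalsim.GenotypeMatrix(
        genotypes=geno,
        pop_labels=["A", "A", "B", "B", "B"],
        depth=depth,
        locus_ids=np.array([0, 0, 1, 2, 3]),
        positions=np.array([5, 9, 3, 1, 7]),
    )


@pytest.fixture(scope="session")
def sim_gm():
    """A moderate simulated dataset (vicariance scenario) reused across tests."""
    config = coalsim.ScenarioConfig(
        scenario_name="vicariance",
        n1=8,
        n2=8,
        n_loci=60,
        locus_length=200,
        theta_per_site=0.01,
        seed=11,
    )
    return coalsim.simulate_demography(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
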