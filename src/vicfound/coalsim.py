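"""Coalescent simulation of two-deme SNP data under divergence scenarios.

This is the package's synthetic-data generator: it simulates genealogies with
msprime under the same piecewise-constant demographic schedules used by the
model registry, drops infinite-sites mutations on them, and returns diploid
genotype matrices (optionally with missing calls and per-genotype depths)
that exercise every downstream stage without any external download.

Scaled units are converted to msprime's generation/individual units with an
arbitrary diploid reference size ``N_REF``; all observable quantities are
invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from . import demomodels
from .demomodels import DemographicParams, DemographySchedule
from .sfs import JointSFS

__all__ = [
    "ScenarioConfig",
    "GenotypeMatrix",
    "DepthModel",
    "SCENARIO_MODELS",
    "scenario_schedule",
    "demography_from_schedule",
    "simulate_demography",
    "simulate_joint_sfs",
    "simulate_panmictic_pi",
    "inject_missingness",
]

#: diploid reference size used to translate scaled units into msprime units
N_REF = 1000.0

#: scenario name -> (registered model, default parameters)
SCENARIO_MODELS: dict[str, tuple[str, DemographicParams]] = {
    # Old vicariance: fragmentation of the ancestral range well before the
    # last glacial; defaults follow the fitted no-migration vicariance row.
    "vicariance": (
        "vic_no_mig",
        DemographicParams(nuA=0.68, nu1=0.1, nu2=7.94, T=0.2, s=0.42),
    ),
    # Old founder event: the derived deme is founded by a small fraction of
    # the ancestral population and expands early, long before the present.
    "old_founder": (
        "founder_nomig_two_epoch",
        DemographicParams(nuA=1.0, nu1=1.0, nu2=0.5, T1=0.3, T2=0.1, s=0.1),
    ),
    # Recent founder event: same founding mechanism but with the split inside
    # the last 0.01 scaled time units (postglacial timing).
    "recent_founder": (
        "recent_founder_nomig_growth",
        DemographicParams(nuA=1.0, nu1=1.0, nu2=0.5, T=0.005, s=0.1),
    ),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of a synthetic two-deme divergence simulation.

    ``n1``/``n2`` are haploid sample sizes per deme (must be even for diploid
    output), ``theta_per_site`` is the scaled mutation rate ``4*N_ref*mu`` per
    site, and ``params=None`` selects the scenario's default parameters.
    """

    scenario_name: str
    n1: int
    n2: int
    n_loci: int = 100
    locus_length: int = 100
    theta_per_site: float = 0.004
    seed: int = 1
    params: DemographicParams | None = None

    def __post_init__(self) -> None:
        if self.scenario_name not in SCENARIO_MODELS:
            raise ValueError(
                f"unknown scenario {self.scenario_name!r}; "
                f"choose one of {sorted(SCENARIO_MODELS)}"
            )
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.theta_per_site < 0:
            raise ValueError("theta_per_site must be non-negative")

    def resolved_params(self) -> DemographicParams:
        model_name, defaults = SCENARIO_MODELS[self.scenario_name]
        return self.params if self.params is not None else defaults

    @property
    def model_name(self) -> str:
        return SCENARIO_MODELS[self.scenario_name][0]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with population labels and depths.

    ``genotypes`` is ``(n_sites, n_individuals)`` with values 0/1/2 counting
    alternate alleles and -1 for missing; ``depth`` has the same shape.
    ``locus_ids``/``positions`` give the site coordinates.
    """

    genotypes: np.ndarray
    pop_labels: list[str]
    depth: np.ndarray
    locus_ids: np.ndarray
    positions: np.ndarray
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.genotypes.shape != self.depth.shape:
            raise ValueError("genotypes and depth must have the same shape")
        if self.genotypes.shape[1] != len(self.pop_labels):
            raise ValueError("one population label per individual is required")
        if not self.sample_names:
            self.sample_names = [f"ind{i}" for i in range(self.genotypes.shape[1])]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class DepthModel:
    """Per-genotype sequencing depth model: Poisson means for called/missing."""

    mean_called: float = 20.0
    mean_missing: float = 0.0


def scenario_schedule(config: ScenarioConfig) -> DemographySchedule:
    """Demographic schedule for a scenario (validated against the registry)."""
    model = demomodels.get_model(config.model_name)
    params = config.resolved_params()
    model.validate(params)
    return model.builder(params)


def demography_from_schedule(schedule: DemographySchedule) -> msprime.Demography:
    """Translate a scaled piecewise-constant schedule into msprime units.

    Sizes become ``nu * N_REF`` diploids, scaled times ``T`` become
    ``2 * N_REF * T`` generations and scaled migration rates ``m`` become
    per-generation rates ``m / (2 * N_REF)``.
    """
    dem = msprime.Demography()
    two_pop = schedule.two_pop
    ep0 = schedule.epochs[0]
    dem.add_population(name="pop1", initial_size=ep0.nu1 * N_REF)
    if two_pop:
        dem.add_population(name="pop2", initial_size=ep0.nu2 * N_REF)
        dem.add_population(name="anc", initial_size=schedule.nuA * N_REF)
        # backwards rate of lineages in pop1 tracing to pop2 is m12
        dem.set_migration_rate(source="pop1", dest="pop2", rate=ep0.m12 / (2 * N_REF))
        dem.set_migration_rate(source="pop2", dest="pop1", rate=ep0.m21 / (2 * N_REF))
    t_edge = 0.0
    for prev, ep in zip(schedule.epochs[:-1], schedule.epochs[1:]):
        t_edge += prev.duration
        t_gen = 2 * N_REF * t_edge
        if ep.nu1 != prev.nu1:
            dem.add_population_parameters_change(
                time=t_gen, population="pop1", initial_size=ep.nu1 * N_REF
            )
        if two_pop and ep.nu2 != prev.nu2:
            dem.add_population_parameters_change(
                time=t_gen, population="pop2", initial_size=ep.nu2 * N_REF
            )
        if two_pop and (ep.m12 != prev.m12 or ep.m21 != prev.m21):
            dem.add_migration_rate_change(
                time=t_gen, source="pop1", dest="pop2", rate=ep.m12 / (2 * N_REF)
            )
            dem.add_migration_rate_change(
                time=t_gen, source="pop2", dest="pop1", rate=ep.m21 / (2 * N_REF)
            )
    t_split = 2 * N_REF * schedule.split_time
    if two_pop:
        dem.add_population_split(time=t_split, derived=["pop1", "pop2"], ancestral="anc")
    else:
        dem.add_population_parameters_change(
            time=t_split, population="pop1", initial_size=schedule.nuA * N_REF
        )
    dem.sort_events()
    return dem


def _sim_ancestry_replicates(config: ScenarioConfig, n_reps: int):
    schedule = scenario_schedule(config)
    dem = demography_from_schedule(schedule)
    if config.n1 % 2 or config.n2 % 2:
        raise ValueError(
            "odd haploid sample sizes cannot form diploid individuals; "
            "use even n1 and n2"
        )
    return msprime.sim_ancestry(
        samples={"pop1": config.n1 // 2, "pop2": config.n2 // 2},
        demography=dem,
        sequence_length=config.locus_length,
        recombination_rate=0.0,
        ploidy=2,
        num_replicates=n_reps,
        random_seed=_msprime_seed(config.seed),
    )


def _msprime_seed(seed: int, salt: int = 0) -> int:
    # msprime requires seeds in [1, 2**32); derive deterministically
    ss = np.random.SeedSequence([int(seed), salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**32 - 1) + 1


def _mutation_rate(config: ScenarioConfig) -> float:
    # theta_per_site = 4 * N_ref * mu  =>  per-generation, per-site rate
    return config.theta_per_site / (4.0 * N_REF)


def _place_infinite_sites(ts, rng: np.random.Generator, locus_length: int):
    """Integer site positions under the infinite-sites assumption.

    Mutations are dropped on continuous coordinates, so every mutation hits a
    fresh site; positions are mapped to distinct integers (collisions at the
    finite locus length are re-drawn among the free integers).
    """
    pos = np.array([s.position for s in ts.sites()])
    ints = np.floor(pos).astype(int) + 1
    used: set[int] = set()
    out = np.empty(len(ints), dtype=int)
    free = None
    for k, p in enumerate(ints):
        if p not in used:
            used.add(p)
            out[k] = p
        else:
            if free is None:
                free = [q for q in range(1, locus_length + 1) if q not in set(ints)]
                rng.shuffle(free)
            if not free:
                raise RuntimeError("more segregating sites than sites in the locus")
            out[k] = free.pop()
            used.add(out[k])
    return out


def simulate_demography(config: ScenarioConfig) -> GenotypeMatrix:
    """Simulate diploid genotypes for a scenario (fully seeded, biallelic).

    Returns ``n1/2 + n2/2`` diploid individuals typed at every segregating
    site across ``n_loci`` independent non-recombining loci; depths are set to
    the default depth model's called mean (no missingness; see
    :func:`inject_missingness`).
    """
    mu = _mutation_rate(config)
    rng = np.random.default_rng(config.seed)
    geno_blocks: list[np.ndarray] = []
    loci: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    n_ind = config.n1 // 2 + config.n2 // 2
    for k, ts in enumerate(_sim_ancestry_replicates(config, config.n_loci)):
        if mu > 0:
            mts = msprime.sim_mutations(
                ts,
                rate=mu,
                discrete_genome=False,
                random_seed=_msprime_seed(config.seed, salt=k + 1),
            )
        else:
            mts = ts
        if mts.num_sites == 0:
            continue
        hap = mts.genotype_matrix()  # (sites, haploids), 0/1
        hap = (hap > 0).astype(np.int8)
        dip = hap[:, 0::2] + hap[:, 1::2]
        geno_blocks.append(dip)
        loci.append(np.full(dip.shape[0], k, dtype=int))
        pos.append(_place_infinite_sites(mts, rng, config.locus_length))
    if geno_blocks:
        geno = np.concatenate(geno_blocks, axis=0)
        locus_ids = np.concatenate(loci)
        positions = np.concatenate(pos)
    else:
        geno = np.zeros((0, n_ind), dtype=np.int8)
        locus_ids = np.zeros(0, dtype=int)
        positions = np.zeros(0, dtype=int)
    labels = ["pop1"] * (config.n1 // 2) + ["pop2"] * (config.n2 // 2)
    depth = np.full(geno.shape, int(DepthModel().mean_called), dtype=np.int32)
    return GenotypeMatrix(
        genotypes=geno,
        pop_labels=labels,
        depth=depth,
        locus_ids=locus_ids,
        positions=positions,
    )


def simulate_joint_sfs(
    config: ScenarioConfig, n_reps: int, mean: bool = False
) -> JointSFS:
    """Unfolded joint SFS of mutation counts over replicate genealogies.

    Accumulates (or averages, with ``mean=True``) the SNP counts of ``n_reps``
    independent loci of ``locus_length`` sites each.  The monomorphic corners
    are zero by construction since only segregating mutations are counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = replace(config, n_loci=n_reps)
    mu = _mutation_rate(cfg)
    n1, n2 = cfg.n1, cfg.n2
    counts = np.zeros((n1 + 1, n2 + 1))
    for k, ts in enumerate(_sim_ancestry_replicates(cfg, n_reps)):
        if mu == 0:
            continue
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            discrete_genome=False,
            random_seed=_msprime_seed(cfg.seed, salt=k + 1),
        )
        if mts.num_sites == 0:
            continue
        hap = (mts.genotype_matrix() > 0).astype(int)
        d1 = hap[:, :n1].sum(axis=1)
        d2 = hap[:, n1:].sum(axis=1)
        np.add.at(counts, (d1, d2), 1.0)
    if mean:
        counts /= n_reps
    return JointSFS(counts=counts, folded=False, pop_ids=("pop1", "pop2"))


def simulate_panmictic_pi(
    n_haploids: int,
    n_loci: int,
    theta_locus: float,
    seed: int = 1,
) -> np.ndarray:
    """Mean pairwise differences per locus in a single constant-size deme.

    Control helper for calibration checks: under the standard neutral
    coalescent ``E[pi] = theta_locus`` per locus.
    """
    dem = msprime.Demography()
    dem.add_population(name="pop1", initial_size=N_REF)
    mu = theta_locus / (4.0 * N_REF)
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n_haploids, population="pop1", ploidy=1)],
        ploidy=2,
        demography=dem,
        sequence_length=1.0,
        num_replicates=n_loci,
        random_seed=_msprime_seed(seed),
    )
    out = np.empty(n_loci)
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, discrete_genome=False, random_seed=_msprime_seed(seed, k + 1)
        )
        out[k] = mts.diversity(span_normalise=False)
    return out


def inject_missingness(
    gm: GenotypeMatrix,
    missing_rate: float,
    depth_model: DepthModel | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Set genotypes missing independently and redraw per-genotype depths.

    Each genotype is set missing with probability ``missing_rate``; called
    genotypes get Poisson depths around ``depth_model.mean_called`` (at least
    1), missing ones around ``depth_model.mean_missing`` (possibly 0).
    Population labels and coordinates are unchanged.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if missing_rate == 0.0 and depth_model is None:
        return GenotypeMatrix(
            genotypes=gm.genotypes.copy(),
            pop_labels=list(gm.pop_labels),
            depth=gm.depth.copy(),
            locus_ids=gm.locus_ids.copy(),
            positions=gm.positions.copy(),
            sample_names=list(gm.sample_names),
        )
    depth_model = depth_model or DepthModel()
    miss = rng.random(gm.genotypes.shape) < missing_rate
    geno = np.where(miss, -1, gm.genotypes).astype(np.int8)
    depth_called = np.maximum(rng.poisson(depth_model.mean_called, gm.genotypes.shape), 1)
    depth_missing = rng.poisson(depth_model.mean_missing, gm.genotypes.shape)
    depth = np.where(miss, depth_missing, depth_called).astype(np.int32)
    return GenotypeMatrix(
        genotypes=geno,
        pop_labels=list(gm.pop_labels),
        depth=depth,
        locus_ids=gm.locus_ids.copy(),
        positions=gm.positions.copy(),
        sample_names=list(gm.sample_names),
    )
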