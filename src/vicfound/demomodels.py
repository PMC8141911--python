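"""Two-population island demographic models and the expected-SFS engine.

Scaling conventions (diffusion units throughout):

* population sizes ``nu`` are relative to an ancestral reference size
  ``N_ref``;
* times are in units of ``2 * N_ref`` generations;
* migration rates ``m12``/``m21`` are scaled as ``2 * N_ref`` times the
  fraction of deme 1 (resp. 2) replaced per generation by migrants from the
  other deme, so a lineage currently in deme 1 traces its ancestry to deme 2
  at rate ``m12`` per scaled time unit.

Every model is expressed as a :class:`DemographySchedule`: a sequence of
piecewise-constant epochs running from the present into the past, ending in a
merge of the two demes into a single ancestral population of size ``nuA``.
Exponential size change is represented by discretizing the trajectory into
geometric sub-steps, so the in-package Monte-Carlo engine and any external
coalescent simulator consume the identical model.

The expected joint SFS is computed by Monte-Carlo coalescent averaging: for
each replicate genealogy the branch length subtending every (i, j) descendant
configuration is accumulated, which gives the expected spectrum up to the
mutation-rate scale (absorbed downstream by optimal-theta scaling).  The
engine reseeds its generator on every call, so evaluations at different
parameter values share random numbers and the surface is smooth enough for a
derivative-free optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numba
import numpy as np

from .sfs import JointSFS, fold_jsfs

__all__ = [
    "DemographicParams",
    "Epoch",
    "DemographySchedule",
    "ModelSpec",
    "EngineSettings",
    "get_model",
    "list_models",
    "expected_sfs",
    "expected_sfs_from_schedule",
    "perturb_params",
    "single_pop_size_change_spec",
    "MODEL_NAMES",
]

#: number of piecewise-constant steps used to discretize exponential growth
GROWTH_STEPS = 16

_PARAM_FIELDS = ("theta", "nuA", "nu1", "nu2", "T", "T1", "T2", "s", "m12", "m21")


@dataclass(frozen=True)
class DemographicParams:
    """Scaled demographic parameters; unused fields stay ``None`` (absent).

    ``theta`` is the optimal-scaling constant reported alongside a fit; it is
    never optimized and never consumed by the model builders.
    """

    theta: float | None = None
    nuA: float | None = None
    nu1: float | None = None
    nu2: float | None = None
    T: float | None = None
    T1: float | None = None
    T2: float | None = None
    s: float | None = None
    m12: float | None = None
    m21: float | None = None

    def as_dict(self) -> dict[str, float]:
        """Mapping of the fields that are present."""
        return {
            name: getattr(self, name)
            for name in _PARAM_FIELDS
            if getattr(self, name) is not None
        }

    def replace(self, **kw) -> "DemographicParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return DemographicParams(**d)


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant interval of the two-deme phase (present -> past).

    ``nu2 is None`` denotes a single-deme schedule.  Migration rates follow
    the scaled convention in the module docstring and apply for the whole
    epoch.
    """

    duration: float
    nu1: float
    nu2: float | None = None
    m12: float = 0.0
    m21: float = 0.0


@dataclass(frozen=True)
class DemographySchedule:
    """Epochs from the present back to the merge, then a constant ancestor."""

    epochs: tuple[Epoch, ...]
    nuA: float

    @property
    def split_time(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    @property
    def two_pop(self) -> bool:
        return self.epochs[0].nu2 is not None


def _geometric_steps(nu_recent: float, nu_old: float, duration: float, n_steps: int):
    """Sizes and durations discretizing exponential change from past to present.

    Returned in present->past order; each step carries the geometric midpoint
    of the exponential trajectory over its sub-interval.
    """
    if n_steps < 1 or math.isclose(nu_recent, nu_old):
        return [(duration, nu_recent)]
    edges = np.linspace(0.0, duration, n_steps + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    # size at time-ago u: nu_recent * (nu_old / nu_recent) ** (u / duration)
    sizes = nu_recent * (nu_old / nu_recent) ** (mids / duration)
    step = duration / n_steps
    return [(step, float(s)) for s in sizes]


def _growth_epochs(
    duration: float,
    nu1: float,
    nu2_recent: float,
    nu2_old: float,
    m12: float = 0.0,
    m21: float = 0.0,
    n_steps: int = GROWTH_STEPS,
) -> list[Epoch]:
    """Epochs for a phase where deme 2 changes exponentially and deme 1 is constant."""
    if math.isclose(nu2_recent, nu2_old):
        return [Epoch(duration, nu1, nu2_recent, m12, m21)]
    steps = _geometric_steps(nu2_recent, nu2_old, duration, n_steps)
    return [Epoch(d, nu1, s, m12, m21) for d, s in steps]


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A named demographic model: free parameters, bounds, and schedule builder."""

    name: str
    free_params: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    builder: Callable[[DemographicParams], DemographySchedule]
    description: str = ""
    reconstructed: bool = False

    @property
    def k(self) -> int:
        """Number of free demographic parameters (theta excluded)."""
        return len(self.free_params)

    def validate(self, params: DemographicParams) -> None:
        for name in self.free_params:
            value = getattr(params, name)
            if value is None:
                raise ValueError(f"model {self.name!r} requires parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"parameter {name}={value} out of bounds [{lo}, {hi}] "
                    f"for model {self.name!r}"
                )

    def params_from_vector(self, x: Sequence[float]) -> DemographicParams:
        return DemographicParams(**dict(zip(self.free_params, map(float, x))))

    def vector_from_params(self, params: DemographicParams) -> np.ndarray:
        return np.array([getattr(params, n) for n in self.free_params], dtype=float)


_NU_BOUNDS = (1e-3, 100.0)
_T_BOUNDS = (1e-3, 10.0)
_S_BOUNDS = (0.01, 0.5)  # founding fraction; upper limit 0.5 by construction
_M_BOUNDS = (1e-2, 10.0)
_T_RECENT = (1e-4, 0.01)  # "recent" founder events: split inside the last 0.01


def _bounds(names, **overrides):
    base = {}
    for n in names:
        if n.startswith("nu"):
            base[n] = _NU_BOUNDS
        elif n.startswith("T"):
            base[n] = _T_BOUNDS
        elif n == "s":
            base[n] = _S_BOUNDS
        elif n.startswith("m"):
            base[n] = _M_BOUNDS
    base.update(overrides)
    return base


def _build_vic_no_mig(p: DemographicParams) -> DemographySchedule:
    # Split T ago; the daughters spend the older half of the divergence at the
    # founding sizes nuA*(1-s) / nuA*s and the recent half at nu1 / nu2.
    half = p.T / 2.0
    return DemographySchedule(
        epochs=(
            Epoch(half, p.nu1, p.nu2),
            Epoch(half, p.nuA * (1.0 - p.s), p.nuA * p.s),
        ),
        nuA=p.nuA,
    )


def _build_vic_anc_asym_mig(p: DemographicParams) -> DemographySchedule:
    # Epoch T1 (older): founding sizes with asymmetric migration ("ancestral
    # contact"); epoch T2 (recent): isolation at the current sizes.
    return DemographySchedule(
        epochs=(
            Epoch(p.T2, p.nu1, p.nu2),
            Epoch(p.T1, p.nuA * (1.0 - p.s), p.nuA * p.s, p.m12, p.m21),
        ),
        nuA=p.nuA,
    )


def _build_founder_two_epoch(p: DemographicParams, m12=0.0, m21=0.0) -> DemographySchedule:
    # Island (deme 2) founded at s*nuA, expands exponentially to nu2 during the
    # older epoch T1 (mainland at nuA*(1-s)), then both demes constant at
    # nu1/nu2 during the recent epoch T2.  Migration, when present, is
    # restricted to the contact epoch T1.
    recent = [Epoch(p.T2, p.nu1, p.nu2)]
    older = _growth_epochs(
        p.T1, p.nuA * (1.0 - p.s), nu2_recent=p.nu2, nu2_old=p.s * p.nuA, m12=m12, m21=m21
    )
    return DemographySchedule(epochs=tuple(recent + older), nuA=p.nuA)


def _build_founder_growth(p: DemographicParams) -> DemographySchedule:
    # Island grows exponentially from s*nuA at the split to nu2 today; the
    # mainland is constant at nu1.
    older = _growth_epochs(p.T, p.nu1, nu2_recent=p.nu2, nu2_old=p.s * p.nuA)
    return DemographySchedule(epochs=tuple(older), nuA=p.nuA)


def _build_founder_anc_asym_growth(p: DemographicParams) -> DemographySchedule:
    # Continuous island growth over T1 + T2; asymmetric migration only during
    # the older (contact) epoch T1.
    total = p.T1 + p.T2
    nu2_mid = p.nu2 * (p.s * p.nuA / p.nu2) ** (p.T2 / total)
    recent = _growth_epochs(p.T2, p.nu1, nu2_recent=p.nu2, nu2_old=nu2_mid)
    older = _growth_epochs(
        p.T1, p.nu1, nu2_recent=nu2_mid, nu2_old=p.s * p.nuA, m12=p.m12, m21=p.m21
    )
    return DemographySchedule(epochs=tuple(recent + older), nuA=p.nuA)


def _registry() -> dict[str, ModelSpec]:
    models = {}

    def add(name, free, builder, description, reconstructed, bound_overrides=None):
        models[name] = ModelSpec(
            name=name,
            free_params=tuple(free),
            bounds=_bounds(free, **(bound_overrides or {})),
            builder=builder,
            description=description,
            reconstructed=reconstructed,
        )

    add(
        "vic_no_mig",
        ("nuA", "nu1", "nu2", "T", "s"),
        _build_vic_no_mig,
        "Vicariance without migration: split T ago into fractions 1-s and s "
        "of the ancestral population, current sizes nu1/nu2.",
        reconstructed=False,
    )
    add(
        "vic_anc_asym_mig",
        ("nuA", "nu1", "nu2", "T1", "T2", "s", "m12", "m21"),
        _build_vic_anc_asym_mig,
        "Vicariance with ancestral asymmetric migration during the first "
        "epoch T1, followed by isolation for T2.",
        reconstructed=False,
    )
    add(
        "founder_nomig_two_epoch",
        ("nuA", "nu1", "nu2", "T1", "T2", "s"),
        lambda p: _build_founder_two_epoch(p),
        "Founder event without migration: island founded at s*nuA, early "
        "expansion to nu2 during T1, constant sizes during T2.",
        reconstructed=True,
    )
    add(
        "founder_anc_asym_two_epoch",
        ("nuA", "nu1", "nu2", "T1", "T2", "s", "m12", "m21"),
        lambda p: _build_founder_two_epoch(p, m12=p.m12, m21=p.m21),
        "Founder event with ancestral asymmetric migration during the "
        "expansion epoch T1, then isolation at constant sizes for T2.",
        reconstructed=False,
    )
    add(
        "founder_nomig_growth",
        ("nuA", "nu1", "nu2", "T", "s"),
        _build_founder_growth,
        "Founder event without migration: island grows exponentially from "
        "s*nuA to nu2 over the whole divergence time T.",
        reconstructed=True,
    )
    add(
        "founder_anc_asym_growth",
        ("nuA", "nu1", "nu2", "T1", "T2", "s", "m12", "m21"),
        _build_founder_anc_asym_growth,
        "Founder event with continuous island growth and ancestral "
        "asymmetric migration during the contact epoch T1.",
        reconstructed=True,
    )
    add(
        "recent_founder_nomig_growth",
        ("nuA", "nu1", "nu2", "T", "s"),
        _build_founder_growth,
        "Recent founder event (T bounded below 0.01) with continuous island "
        "growth and no migration.",
        reconstructed=True,
        bound_overrides={"T": _T_RECENT},
    )
    add(
        "recent_founder_nomig_two_epoch",
        ("nuA", "nu1", "nu2", "T1", "T2", "s"),
        lambda p: _build_founder_two_epoch(p),
        "Recent founder event (T1 + T2 bounded below 0.01) with early "
        "expansion then constant sizes and no migration.",
        reconstructed=True,
        bound_overrides={"T1": (5e-5, 0.005), "T2": (5e-5, 0.005)},
    )
    return models


_MODELS = _registry()
MODEL_NAMES = tuple(_MODELS)


def get_model(name: str) -> ModelSpec:
    """Look up a registered model by name."""
    try:
        return _MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: {', '.join(MODEL_NAMES)}"
        ) from None


def list_models() -> tuple[ModelSpec, ...]:
    return tuple(_MODELS.values())


def single_pop_size_change_spec(T: float = 0.5, name: str = "one_pop_size_change") -> ModelSpec:
    """One-parameter control model: a single-deme step size change at time T.

    The deme has the reference size 1 today and size ``nuA`` before the
    change; ``nuA < 1`` is an expansion, which leaves the classic
    rare-variant excess in the folded spectrum.  Not part of the island-model
    registry; used for parameter-recovery checks where a one-dimensional,
    well-identified likelihood surface is wanted.
    """

    def build(p: DemographicParams) -> DemographySchedule:
        return DemographySchedule(epochs=(Epoch(T, 1.0, None),), nuA=p.nuA)

    return ModelSpec(
        name=name,
        free_params=("nuA",),
        bounds={"nuA": _NU_BOUNDS},
        builder=build,
        description=f"Single deme of present size 1, size nuA before the change {T} ago.",
        reconstructed=True,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo expected-SFS engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EngineSettings:
    """Settings of the Monte-Carlo expected-SFS engine.

    ``n_reps`` replicate genealogies are averaged; the generator is reseeded
    with ``seed`` at every evaluation (common random numbers across parameter
    values).
    """

    n_reps: int = 20000
    seed: int = 2718
    max_events: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@numba.njit(cache=True)
def _mc_core(
    seed, n_reps, n1, n2, t_ends, nu1s, nu2s, m12s, m21s, two_pop, F
):  # pragma: no cover - exercised through expected_sfs
    np.random.seed(seed)
    ntot = n1 + n2
    ncols = n2 + 1
    n_iv = t_ends.shape[0]
    pop = np.empty(ntot, np.int8)
    alive = np.empty(ntot, np.bool_)
    d1 = np.empty(ntot, np.int64)
    d2 = np.empty(ntot, np.int64)
    for _rep in range(n_reps):
        for l in range(ntot):
            pop[l] = 0 if l < n1 else 1
            alive[l] = True
            d1[l] = 1 if l < n1 else 0
            d2[l] = 0 if l >= n1 else 0
        for l in range(n1, ntot):
            d2[l] = 1
        k1 = n1
        k2 = n2
        t = 0.0
        for iv in range(n_iv):
            t_end = t_ends[iv]
            nu1_c = nu1s[iv]
            nu2_c = nu2s[iv]
            m12_c = m12s[iv]
            m21_c = m21s[iv]
            ancestral = iv == n_iv - 1
            if ancestral and two_pop:
                for l in range(ntot):
                    if alive[l]:
                        pop[l] = 0
                k1 = k1 + k2
                k2 = 0
            while t < t_end and k1 + k2 > 1:
                rc1 = k1 * (k1 - 1) / 2.0 / nu1_c
                rc2 = 0.0
                rm1 = 0.0
                rm2 = 0.0
                if nu2_c > 0.0:
                    rc2 = k2 * (k2 - 1) / 2.0 / nu2_c
                    rm1 = k1 * m12_c
                    rm2 = k2 * m21_c
                tot = rc1 + rc2 + rm1 + rm2
                if tot <= 0.0:
                    t_new = t_end
                else:
                    dt = np.random.exponential(1.0 / tot)
                    t_new = t + dt
                    if t_new > t_end:
                        t_new = t_end
                w = t_new - t
                for l in range(ntot):
                    if alive[l]:
                        F[d1[l] * ncols + d2[l]] += w
                t = t_new
                if t >= t_end or tot <= 0.0:
                    break
                u = np.random.random() * tot
                if u < rc1 or u < rc1 + rc2:
                    which = 0 if u < rc1 else 1
                    kp = k1 if which == 0 else k2
                    ia = int(np.random.random() * kp)
                    ib = int(np.random.random() * (kp - 1))
                    if ib >= ia:
                        ib += 1
                    # map ranks to lineage slots within the deme
                    a = -1
                    b = -1
                    rank = 0
                    for l in range(ntot):
                        if alive[l] and pop[l] == which:
                            if rank == ia:
                                a = l
                            if rank == ib:
                                b = l
                            rank += 1
                    d1[a] += d1[b]
                    d2[a] += d2[b]
                    alive[b] = False
                    if which == 0:
                        k1 -= 1
                    else:
                        k2 -= 1
                else:
                    which = 0 if u < rc1 + rc2 + rm1 else 1
                    kp = k1 if which == 0 else k2
                    ia = int(np.random.random() * kp)
                    rank = 0
                    for l in range(ntot):
                        if alive[l] and pop[l] == which:
                            if rank == ia:
                                pop[l] = 1 - which
                                break
                            rank += 1
                    if which == 0:
                        k1 -= 1
                        k2 += 1
                    else:
                        k2 -= 1
                        k1 += 1


def _branch_sfs_mc(
    schedule: DemographySchedule, n1: int, n2: int, engine: EngineSettings
) -> np.ndarray:
    """Unfolded expected joint SFS by branch-length accumulation.

    Simulates ``engine.n_reps`` genealogies of ``n1 + n2`` haploid lineages
    under the piecewise-constant schedule (a compiled per-replicate Gillespie
    loop) and accumulates, for every branch, its length into the cell indexed
    by the branch's descendant counts in the two demes.  The result is the
    mean over replicates, in units of scaled branch length per site-mutation
    rate.
    """
    ntot = n1 + n2
    if ntot < 2:
        raise ValueError("need at least two haploid samples in total")
    two_pop = schedule.two_pop
    t_ends, nu1s, nu2s, m12s, m21s = [], [], [], [], []
    t_edge = 0.0
    for ep in schedule.epochs:
        t_edge += ep.duration
        t_ends.append(t_edge)
        nu1s.append(ep.nu1)
        nu2s.append(ep.nu2 if ep.nu2 is not None else -1.0)
        m12s.append(ep.m12)
        m21s.append(ep.m21)
    t_ends.append(np.inf)
    nu1s.append(schedule.nuA)
    nu2s.append(-1.0)
    m12s.append(0.0)
    m21s.append(0.0)
    F = np.zeros((n1 + 1) * (n2 + 1))
    _mc_core(
        int(engine.seed) % (2**31 - 1),
        int(engine.n_reps),
        n1,
        n2,
        np.asarray(t_ends),
        np.asarray(nu1s),
        np.asarray(nu2s),
        np.asarray(m12s),
        np.asarray(m21s),
        two_pop,
        F,
    )
    return F.reshape(n1 + 1, n2 + 1) / engine.n_reps


def expected_sfs_from_schedule(
    schedule: DemographySchedule,
    sizes: tuple[int, int],
    engine: EngineSettings | None = None,
    fold: bool = True,
) -> JointSFS:
    """Expected joint SFS (arbitrary normalization) for an explicit schedule."""
    engine = engine or EngineSettings()
    n1, n2 = int(sizes[0]), int(sizes[1])
    if schedule.two_pop and (n1 < 2 or n2 < 2):
        raise ValueError("two-population spectra need at least 2 haploids per deme")
    counts = _branch_sfs_mc(schedule, n1, n2, engine)
    out = JointSFS(counts=counts, folded=False)
    return fold_jsfs(out) if fold else out


def expected_sfs(
    model: ModelSpec,
    params: DemographicParams,
    sizes: tuple[int, int],
    engine: EngineSettings | None = None,
    fold: bool = True,
) -> JointSFS:
    """Expected (folded) joint SFS under a registered model at given parameters.

    Deterministic for a fixed engine seed; smooth in the parameters under the
    engine's common random numbers.
    """
    model.validate(params)
    schedule = model.builder(params)
    return expected_sfs_from_schedule(schedule, sizes, engine=engine, fold=fold)


def perturb_params(
    p: np.ndarray,
    fold: float,
    bounds: Sequence,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Multiply each coordinate by ``2**u``, ``u ~ U(-fold, fold)``, then clip.

    This is the standard "fold-perturbation" used to scatter optimizer starting
    points around a base parameter vector.
    """
    if fold < 0:
        raise ValueError("fold must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    u = rng.uniform(-fold, fold, size=p.shape)
    out = p * 2.0**u
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    return np.clip(out, lo, hi)
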