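"""Model fitting with the multi-round perturbation protocol and AIC ranking.

Each demographic model is fitted to a data spectrum by repeatedly perturbing
starting parameters ("fold" perturbations, ``p * 2**U(-fold, fold)``) and
running a bounded derivative-free simplex search in log-parameter space on
the Poisson/multinomial composite log-likelihood.  The default protocol is
four rounds of 3-, 2-, 2- and 1-fold perturbations with 10, 20, 30 and 60
replicates; later rounds perturb the best parameters found so far.  The
mutation-rate scale theta is profiled out by optimal scaling and reported,
never optimized, and is excluded from the parameter count ``k`` used by AIC.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .demomodels import (
    DemographicParams,
    EngineSettings,
    ModelSpec,
    expected_sfs,
    perturb_params,
)
from .sfs import JointSFS, hellinger_distance, loglik_multinom

__all__ = [
    "Protocol",
    "FitResult",
    "optimal_scaling_theta",
    "fit_model_multiround",
    "model_selection_table",
]


@dataclass(frozen=True)
class Protocol:
    """Perturbation folds and replicate counts per optimization round."""

    folds: tuple[float, ...] = (3.0, 2.0, 2.0, 1.0)
    replicates: tuple[int, ...] = (10, 20, 30, 60)
    maxfev: int = 200  # likelihood evaluations per replicate
    xtol: float = 1e-3  # simplex tolerance in log10-parameter space
    ftol: float = 1e-4  # tolerance in log-likelihood units
    n_scatter: int = 30  # random probes used to pick the round-1 base point
    reseed_rounds: bool = True  # fresh engine noise stream per round
    polish_reps: int | None = None  # engine replicates for a final polish stage
    polish_maxfev: int = 30  # evaluations of the polish stage
    objective: str = "poisson"  # search-stage objective: "poisson" | "hellinger"

    def __post_init__(self) -> None:
        if len(self.folds) != len(self.replicates):
            raise ValueError("folds and replicates must have equal length")
        if self.objective not in ("poisson", "hellinger"):
            raise ValueError("objective must be 'poisson' or 'hellinger'")


@dataclass
class FitResult:
    """Best fit of one model: parameters, log-likelihood and round trace."""

    model_name: str
    best_params: DemographicParams
    log_likelihood: float
    theta_hat: float
    round_trace: list[float]
    seed: int
    n_evaluations: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "model_name": self.model_name,
            "best_params": self.best_params.as_dict(),
            "log_likelihood": self.log_likelihood,
            "theta_hat": self.theta_hat,
            "round_trace": self.round_trace,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            payload = json.load(fh)
        payload["best_params"] = DemographicParams(**payload["best_params"])
        return cls(**payload)

    @property
    def k(self) -> int:
        return len(self.best_params.as_dict()) - (
            1 if self.best_params.theta is not None else 0
        )


def optimal_scaling_theta(data: JointSFS, model: JointSFS) -> float:
    """Optimal scaling factor ``theta_hat = sum(data) / sum(model)`` (unmasked)."""
    if data.shape != model.shape or not np.array_equal(data.mask, model.mask):
        raise ValueError("data and model spectra have different shapes or masks")
    sm = float(model.counts[~model.mask].sum())
    if sm == 0.0:
        raise ValueError("model spectrum has zero total mass")
    return float(data.counts[~data.mask].sum()) / sm


def _replicate_seed(master: int, round_idx: int, rep_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master), round_idx, rep_idx])
    )


def _local_search(objective, x0, lo, hi, protocol: Protocol, method: str, step: float = 0.3):
    """One bounded derivative-free search in log10-parameter space."""
    options = {"maxfev": protocol.maxfev}
    if method == "Nelder-Mead":
        # explicit initial simplex with ~2-fold steps per parameter; the
        # scipy default scales steps with |x0| and degenerates near 0
        simplex = np.vstack([x0] + [x0 for _ in range(len(x0))])
        for i in range(len(x0)):
            s = step if x0[i] + step <= hi[i] else -step
            simplex[i + 1, i] = x0[i] + s
        options.update(
            xatol=protocol.xtol, fatol=protocol.ftol, initial_simplex=simplex
        )
    else:
        options.update(xtol=protocol.xtol, ftol=protocol.ftol)
    return minimize(
        objective, x0, method=method, bounds=list(zip(lo, hi)), options=options
    )


def fit_model_multiround(
    data: JointSFS,
    model: ModelSpec,
    protocol: Protocol | None = None,
    seed: int = 0,
    engine: EngineSettings | None = None,
    init_params: DemographicParams | None = None,
) -> FitResult:
    """Fit one model with the multi-round perturbed-restart protocol.

    Round 1 perturbs a random (log-uniform within bounds) or supplied starting
    vector; each later round perturbs the best vector of the previous rounds.
    Every replicate runs a bounded Nelder-Mead search in log10-parameter space.
    Replicates whose optimizer fails are skipped with a warning; if every
    replicate fails an error is raised.  Fully deterministic given ``seed``.
    """
    protocol = protocol or Protocol()
    engine = engine or EngineSettings()
    sizes = (data.n1, data.n2)
    round_engine = engine
    bounds = [model.bounds[n] for n in model.free_params]
    lo = np.log10([b[0] for b in bounds])
    hi = np.log10([b[1] for b in bounds])
    n_eval = 0

    def objective(logx: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = model.params_from_vector(10.0**logx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exp = expected_sfs(model, params, sizes, engine=round_engine)
            if protocol.objective == "hellinger":
                return hellinger_distance(data, exp)
            ll = loglik_multinom(data, exp)
        return -ll if np.isfinite(ll) else 1e12

    rng0 = _replicate_seed(seed, 0, 0)
    if init_params is not None:
        bases = [model.vector_from_params(init_params)]
    else:
        # round-1 bases: best few of a log-uniform random scatter over the
        # bounds, so the first round explores several candidate basins
        probes = rng0.uniform(lo, hi, size=(max(protocol.n_scatter, 1), lo.size))
        values = np.array([objective(x) for x in probes])
        order = np.argsort(values)[: max(1, min(3, len(values)))]
        bases = [10.0 ** probes[i] for i in order]

    best_x: np.ndarray | None = None
    best_ll = -np.inf
    round_trace: list[float] = []
    n_failed = 0
    n_total = 0
    for r, (fold, n_rep) in enumerate(zip(protocol.folds, protocol.replicates), start=1):
        # fresh common-random-numbers stream per round: an optimum that only
        # reflects one stream's Monte-Carlo noise does not survive rounds
        if protocol.reseed_rounds:
            round_engine = EngineSettings(n_reps=engine.n_reps, seed=engine.seed + 1009 * r)
            if best_x is not None:
                best_ll = -objective(np.log10(best_x))  # revalue incumbent
        round_best = -np.inf
        for rep in range(n_rep):
            n_total += 1
            rng = _replicate_seed(seed, r, rep + 1)
            if best_x is None:
                center = bases[rep % len(bases)]
            else:
                center = best_x
            if rep == 0 and best_x is not None:
                # un-perturbed restart at the incumbent best: a fresh simplex
                # there lets the search continue where the last run stalled
                start = center.copy()
            else:
                start = perturb_params(center, fold, bounds, rng)
            x0 = np.clip(np.log10(start), lo, hi)
            try:
                res = _local_search(
                    objective,
                    x0,
                    lo,
                    hi,
                    protocol,
                    # alternate simplex and direction-set searches: the two
                    # stall in different ways on ridged likelihood surfaces
                    method="Powell" if rep % 2 == 1 else "Nelder-Mead",
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"replicate {r}.{rep + 1} failed: {exc}")
                n_failed += 1
                continue
            ll = -res.fun
            if ll > round_best:
                round_best = ll
            if ll > best_ll:
                best_ll = ll
                best_x = 10.0**res.x
        round_trace.append(max(round_best, best_ll))
    if best_x is None:
        raise RuntimeError(f"all {n_total} optimizer replicates failed")
    if protocol.polish_reps is not None:
        # final short search at higher engine precision: recovers optima that
        # the noisier rounds displaced by chasing their Monte-Carlo jitter
        round_engine = EngineSettings(
            n_reps=protocol.polish_reps, seed=engine.seed + 99991
        )
        x0 = np.log10(best_x)
        polish_protocol = dataclasses.replace(protocol, maxfev=protocol.polish_maxfev)
        res = _local_search(objective, x0, lo, hi, polish_protocol, "Nelder-Mead", step=0.1)
        best_ll = -res.fun
        best_x = 10.0**res.x
        round_trace.append(best_ll)
    best_params = model.params_from_vector(best_x)
    exp = expected_sfs(model, best_params, sizes, engine=engine)
    theta_hat = optimal_scaling_theta(data, exp)
    best_params = best_params.replace(theta=theta_hat)
    if protocol.objective == "hellinger":
        # the trace carries negated Hellinger distances; report the Poisson
        # log-likelihood of the final point so fits stay AIC-comparable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best_ll = loglik_multinom(data, exp)
    return FitResult(
        model_name=model.name,
        best_params=best_params,
        log_likelihood=float(best_ll),
        theta_hat=float(theta_hat),
        round_trace=round_trace,
        seed=seed,
        n_evaluations=n_eval,
    )


def model_selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """AIC / delta-AIC / Akaike weights for a set of fitted models.

    ``AIC = 2k - 2 logL`` with ``k`` the number of free demographic parameters
    (theta excluded); rows are sorted by AIC ascending and the weights
    ``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)`` sum to one.
    """
    if not fits:
        raise ValueError("need at least one fit")
    names = [f.model_name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names in fits")
    rows = []
    for f in fits:
        aic = 2.0 * f.k - 2.0 * f.log_likelihood
        rows.append(
            {
                "model_name": f.model_name,
                "k": f.k,
                "log_likelihood": f.log_likelihood,
                "theta": f.theta_hat,
                "AIC": aic,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_AIC"] = table["AIC"] - table["AIC"].min()
    w = np.exp(-table["delta_AIC"] / 2.0)
    table["akaike_weight"] = w / w.sum()
    return table.sort_values("AIC", ignore_index=True)
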