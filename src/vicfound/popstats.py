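"""Per-population diversity descriptors and rank-based group comparisons.

Computes, per population or group, the number of called sites, the
percentage of polymorphic sites, expected heterozygosity, nucleotide
diversity (pi, with the unbiased ``n/(n-1)`` correction on called alleles),
and the number of private alleles (alleles observed in that unit and in no
other unit of the analysis).  Distributions of such descriptors between
groups are compared with a Mann-Whitney U test (exact permutation for small
samples, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = ["DiversityStats", "diversity_stats", "mann_whitney_u"]

#: combined sample size up to which the exact permutation p-value is used
EXACT_LIMIT = 12


@dataclass(frozen=True)
class DiversityStats:
    """Diversity descriptors of one population/group."""

    unit: str
    sites_recovered: int
    pct_polymorphic: float
    expected_heterozygosity: float
    nucleotide_diversity_pi: float
    private_alleles: int
    defined: bool = True


def _unit_site_counts(geno: np.ndarray, depth: np.ndarray, idx: np.ndarray, min_depth: int):
    """Called-allele and alternate-allele counts per site for one unit."""
    called = (geno[:, idx] >= 0) & (depth[:, idx] >= min_depth)
    g = np.where(called, geno[:, idx], 0)
    n = 2 * called.sum(axis=1)
    d = g.sum(axis=1)
    return n, d


def diversity_stats(gm, grouping: dict[str, str] | None = None, min_depth: int = 0) -> pd.DataFrame:
    """Diversity descriptors per unit (population or group).

    ``grouping`` maps sample names to units; by default each individual's own
    population label is its unit.  Sites with fewer than two called alleles in
    a unit are skipped for that unit's frequency-based statistics.  A unit
    with no called alleles anywhere is flagged undefined.
    """
    geno = np.asarray(gm.genotypes)
    depth = np.asarray(gm.depth)
    if grouping is None:
        unit_of = dict(zip(gm.sample_names, gm.pop_labels))
    else:
        unit_of = dict(grouping)
        missing = [s for s in gm.sample_names if s not in unit_of]
        if missing:
            raise ValueError(f"individuals without a unit assignment: {missing}")
    units = sorted(set(unit_of[s] for s in gm.sample_names))
    names = np.asarray(gm.sample_names)
    labels = np.asarray([unit_of[s] for s in gm.sample_names])

    per_unit = {}
    for u in units:
        idx = np.flatnonzero(labels == u)
        n, d = _unit_site_counts(geno, depth, idx, min_depth)
        per_unit[u] = (n, d)

    rows = []
    for u in units:
        n, d = per_unit[u]
        usable = n >= 2
        recovered = int((n > 0).sum())
        if recovered == 0:
            rows.append(
                DiversityStats(u, 0, float("nan"), float("nan"), float("nan"), 0, defined=False)
            )
            continue
        p = np.where(usable, d / np.where(n > 0, n, 1), 0.0)
        het = 2.0 * p * (1.0 - p)
        with np.errstate(invalid="ignore"):
            corr = np.where(usable, n / np.maximum(n - 1, 1), 0.0)
        pi = corr * het
        poly = usable & (d > 0) & (d < n)
        # private alleles: allele present here and absent from all other units
        private = 0
        for allele in (0, 1):
            here = d > 0 if allele == 1 else d < n
            here &= n > 0
            elsewhere = np.zeros(len(n), dtype=bool)
            for v in units:
                if v == u:
                    continue
                nv, dv = per_unit[v]
                present = (dv > 0 if allele == 1 else dv < nv) & (nv > 0)
                elsewhere |= present
            private += int((here & ~elsewhere).sum())
        rows.append(
            DiversityStats(
                unit=u,
                sites_recovered=recovered,
                pct_polymorphic=100.0 * poly.sum() / usable.sum() if usable.any() else float("nan"),
                expected_heterozygosity=float(het[usable].mean()) if usable.any() else float("nan"),
                nucleotide_diversity_pi=float(pi[usable].mean()) if usable.any() else float("nan"),
                private_alleles=private,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y, using midranks for ties."""
    nx = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(x, y) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation distribution (all label reassignments of the
    combined sample) when the combined size is at most ``EXACT_LIMIT``, and
    the tie-corrected normal approximation otherwise.  Returns ``{"U":
    ..., "p_two_sided": ...}`` with U computed for the first sample using
    midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    n, m = len(x), len(y)
    if n + m <= EXACT_LIMIT:
        combined = np.concatenate([x, y])
        center = n * m / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        for pick in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(combined[mask], combined[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                count += 1
        p = count / total
    else:
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return {"U": u_obs, "p_two_sided": float(min(p, 1.0))}
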