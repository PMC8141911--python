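"""Joint site frequency spectra: construction, projection, folding and likelihood.

The central container is :class:`JointSFS`, a two-dimensional array whose cell
``(i, j)`` holds the number of SNPs (possibly fractional, after hypergeometric
down-projection) at which the alternate allele was seen ``i`` times in
population 1 and ``j`` times in population 2.  The two monomorphic corners
``(0, 0)`` and ``(n1, n2)`` carry no information about polymorphism and are
always masked; masked cells are excluded from the likelihood.

A single-population spectrum is represented as a degenerate joint spectrum of
shape ``(n1 + 1, 1)`` with ``n2 == 0``; every operation below handles that case
through the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb, gammaln

__all__ = [
    "JointSFS",
    "SfsFilterConfig",
    "jsfs_from_genotypes",
    "choose_projection",
    "project_jsfs",
    "fold_jsfs",
    "loglik_multinom",
    "read_sfs",
    "write_sfs",
]


def corner_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask with only the two monomorphic corners set."""
    m = np.zeros(shape, dtype=bool)
    m[0, 0] = True
    m[-1, -1] = True
    return m


@dataclass
class JointSFS:
    """A (possibly folded) joint site frequency spectrum.

    Parameters
    ----------
    counts
        Array of shape ``(n1 + 1, n2 + 1)``; non-negative.
    folded
        Whether the spectrum has been folded over ancestral-state uncertainty.
    mask
        Boolean array of the same shape; ``True`` marks excluded cells.
        Defaults to the two monomorphic corners.
    pop_ids
        Optional pair of population identifiers ``(pop1, pop2)``.
    """

    counts: np.ndarray
    folded: bool = False
    mask: np.ndarray | None = None
    pop_ids: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if self.counts.ndim != 2:
            raise ValueError("JointSFS counts must be 1- or 2-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("JointSFS counts must be non-negative")
        if self.mask is None:
            self.mask = corner_mask(self.counts.shape)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape does not match counts shape")

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> float:
        """Total mass over unmasked cells."""
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(
            counts=self.counts.copy(),
            folded=self.folded,
            mask=self.mask.copy(),
            pop_ids=self.pop_ids,
        )


@dataclass(frozen=True)
class SfsFilterConfig:
    """Site/genotype filters applied before building a spectrum.

    ``min_depth`` mirrors a 5x depth-of-coverage genotype filter and
    ``max_missing_fraction`` a 50%-missing site filter; both are the standard
    RADseq defaults.  ``one_snp_per_locus`` keeps only the first SNP of each
    locus as a linkage-thinning step.
    """

    max_missing_fraction: float = 0.5
    min_depth: int = 5
    one_snp_per_locus: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def _fold_line(shape: tuple[int, int]) -> np.ndarray:
    """Fractional derived-allele position of every cell relative to the fold.

    Returns ``f`` such that the fold keeps cells with ``f < thresh``, masks
    cells with ``f > thresh`` and splits mass evenly on ``f == thresh``, where
    ``thresh`` is half the value of ``f`` at the all-derived corner.
    """
    n1 = shape[0] - 1
    n2 = shape[1] - 1
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    f = np.zeros(shape, dtype=float)
    if n1 > 0:
        f = f + i / n1
    if n2 > 0:
        f = f + j / n2
    return f


def fold_jsfs(sfs: JointSFS) -> JointSFS:
    """Fold a spectrum over ancestral-state uncertainty.

    Cell ``(i, j)`` is combined with its complement ``(n1 - i, n2 - j)``; the
    redundant half beyond the fold line is masked and cells lying exactly on
    the line (including self-complementary cells) keep half of the combined
    mass so that nothing is double counted.
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    f = _fold_line(sfs.shape)
    npop = int(sfs.n1 > 0) + int(sfs.n2 > 0)
    thresh = npop / 2.0
    comp = sfs.counts[::-1, ::-1]
    out = sfs.counts + comp
    on_line = np.isclose(f, thresh)
    out[on_line] *= 0.5
    new_mask = (f > thresh + 1e-9) | sfs.mask | sfs.mask[::-1, ::-1]
    out = np.where(new_mask, 0.0, out)
    return JointSFS(counts=out, folded=True, mask=new_mask, pop_ids=sfs.pop_ids)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """Hypergeometric down-projection weights from ``n`` to ``m`` haploids.

    ``W[d, k] = C(d, k) * C(n - d, m - k) / C(n, m)`` is the probability that a
    subsample of size ``m`` contains ``k`` copies of an allele seen ``d`` times
    in the full sample of ``n``.
    """
    if m > n:
        raise ValueError(f"cannot project from {n} up to {m}")
    d = np.arange(n + 1)[:, None]
    k = np.arange(m + 1)[None, :]
    w = comb(d, k) * comb(n - d, m - k) / comb(n, m)
    return w


def project_jsfs(sfs: JointSFS, target: tuple[int, int]) -> JointSFS:
    """Down-project an unfolded spectrum to smaller haploid sample sizes.

    Each cell redistributes its mass according to the hypergeometric
    expectation over subsamples; total mass is conserved, with mass that
    becomes monomorphic after projection landing in the masked corners.
    """
    if sfs.folded:
        raise ValueError("projection operates on unfolded spectra; fold afterwards")
    m1, m2 = int(target[0]), int(target[1])
    if m1 > sfs.n1 or m2 > sfs.n2:
        raise ValueError(
            f"projection target ({m1}, {m2}) exceeds source sizes ({sfs.n1}, {sfs.n2})"
        )
    w1 = _projection_matrix(sfs.n1, m1)
    w2 = _projection_matrix(sfs.n2, m2)
    out = w1.T @ sfs.counts @ w2
    return JointSFS(counts=out, folded=False, mask=corner_mask(out.shape), pop_ids=sfs.pop_ids)


def hellinger_distance(data: JointSFS, model: JointSFS) -> float:
    """Squared Hellinger-type distance ``sum (sqrt(D) - sqrt(theta_hat M))^2``.

    The model spectrum is rescaled by the optimal factor
    ``theta_hat = sum(data) / sum(model)`` over unmasked cells first.  The
    square-root transform stabilizes the Poisson variance of each cell, so the
    distance is far less sensitive than the log-likelihood to Monte-Carlo
    noise in near-empty model cells (no singularity at zero), which makes it
    a robust search-stage objective; minimum-Hellinger estimates are
    asymptotically equivalent to maximum likelihood.
    """
    if data.shape != model.shape:
        raise ValueError("data and model spectra have different shapes")
    if data.folded != model.folded:
        raise ValueError("data and model spectra have different folded states")
    if not np.array_equal(data.mask, model.mask):
        raise ValueError("data and model spectra have different masks")
    keep = ~data.mask
    d = data.counts[keep]
    m = model.counts[keep]
    sd = d.sum()
    if sd == 0.0:
        return 0.0
    sm = m.sum()
    if sm == 0.0:
        warnings.warn("model spectrum is identically zero")
        return float(sd)
    lam = (sd / sm) * m
    return float(np.sum((np.sqrt(d) - np.sqrt(lam)) ** 2))


def loglik_multinom(data: JointSFS, model: JointSFS) -> float:
    """Poisson-form multinomial composite log-likelihood of ``data`` given ``model``.

    The model spectrum is first rescaled by the optimal factor
    ``theta_hat = sum(data) / sum(model)`` over unmasked cells, which makes the
    result invariant to the model's normalization; the Poisson log-likelihood
    ``sum(D ln(lam) - lam - ln D!)`` is then returned over unmasked cells.

    A model cell of zero where the data are positive yields ``-inf``.
    """
    if data.shape != model.shape:
        raise ValueError("data and model spectra have different shapes")
    if data.folded != model.folded:
        raise ValueError("data and model spectra have different folded states")
    if not np.array_equal(data.mask, model.mask):
        raise ValueError("data and model spectra have different masks")
    keep = ~data.mask
    d = data.counts[keep]
    m = model.counts[keep]
    sd = d.sum()
    if sd == 0.0:
        # No data: optimal scaling is theta_hat = 0 and the likelihood is empty.
        return 0.0
    sm = m.sum()
    if sm == 0.0:
        warnings.warn("model spectrum is identically zero; log-likelihood is -inf")
        return float("-inf")
    lam = (sd / sm) * m
    bad = (lam == 0.0) & (d > 0.0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} model cells are zero where data are positive; "
            "log-likelihood is -inf"
        )
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(d > 0, d * np.log(np.where(lam > 0, lam, 1.0)), 0.0)
    return float(np.sum(terms - lam - gammaln(d + 1)))


# ---------------------------------------------------------------------------
# Building spectra from genotype matrices
# ---------------------------------------------------------------------------


def _site_allele_counts(gm, pops: tuple[str, str], filters: SfsFilterConfig):
    """Per-site called/derived haploid counts for the two populations.

    Returns ``(c1, d1, c2, d2, keep)`` arrays over sites, where ``c`` is the
    number of called haploid alleles (after the depth filter), ``d`` the
    alternate-allele count among them, and ``keep`` flags sites passing the
    missing-data (and optional one-SNP-per-locus) filters.
    """
    labels = np.asarray(gm.pop_labels)
    idx1 = np.flatnonzero(labels == pops[0])
    idx2 = np.flatnonzero(labels == pops[1])
    if idx1.size == 0:
        raise ValueError(f"population {pops[0]!r} has no individuals")
    if idx2.size == 0:
        raise ValueError(f"population {pops[1]!r} has no individuals")
    geno = np.asarray(gm.genotypes)
    depth = np.asarray(gm.depth)
    called = (geno >= 0) & (depth >= filters.min_depth)
    both = np.concatenate([idx1, idx2])
    miss_frac = 1.0 - called[:, both].mean(axis=1)
    keep = miss_frac <= filters.max_missing_fraction
    if filters.one_snp_per_locus:
        loci = np.asarray(gm.locus_ids)
        first = np.zeros(len(loci), dtype=bool)
        _, first_idx = np.unique(loci, return_index=True)
        first[first_idx] = True
        keep &= first

    def pop_counts(idx):
        cal = called[:, idx]
        g = np.where(cal, geno[:, idx], 0)
        c = 2 * cal.sum(axis=1)
        d = g.sum(axis=1)
        return c, d

    c1, d1 = pop_counts(idx1)
    c2, d2 = pop_counts(idx2)
    return c1, d1, c2, d2, keep


def _hyp_weights(c: int, d: int, m: int) -> np.ndarray:
    """Hypergeometric projection weights of a single site onto 0..m copies."""
    k = np.arange(m + 1)
    return comb(d, k) * comb(c - d, m - k) / comb(c, m)


def jsfs_from_genotypes(
    gm,
    pops: tuple[str, str],
    filters: SfsFilterConfig | None = None,
    projection: tuple[int, int] | None = None,
) -> JointSFS:
    """Build the folded joint SFS for two populations from diploid genotypes.

    Genotypes below the depth threshold are treated as missing; sites whose
    missing fraction (across the two populations) exceeds the threshold are
    dropped; every remaining site contributes its hypergeometric projection
    mass at the requested haploid sizes (``projection=None`` chooses them with
    :func:`choose_projection`).  The result is folded.
    """
    filters = filters or SfsFilterConfig()
    labels = np.asarray(gm.pop_labels)
    for p in pops:
        if not np.any(labels == p):
            raise ValueError(f"population {p!r} has no individuals")
    if projection is None:
        projection = choose_projection(gm, pops, filters)
    m1, m2 = int(projection[0]), int(projection[1])
    h1 = 2 * int((labels == pops[0]).sum())
    h2 = 2 * int((labels == pops[1]).sum())
    if m1 > h1 or m2 > h2:
        raise ValueError(
            f"projection ({m1}, {m2}) exceeds available haploid sizes ({h1}, {h2})"
        )
    c1, d1, c2, d2, keep = _site_allele_counts(gm, pops, filters)
    counts = np.zeros((m1 + 1, m2 + 1))
    cache: dict[tuple[int, int, int], np.ndarray] = {}

    def weights(c, d, m):
        key = (c, d, m)
        if key not in cache:
            cache[key] = _hyp_weights(c, d, m)
        return cache[key]

    usable = keep & (c1 >= m1) & (c2 >= m2)
    for s in np.flatnonzero(usable):
        w1 = weights(int(c1[s]), int(d1[s]), m1)
        w2 = weights(int(c2[s]), int(d2[s]), m2)
        counts += np.outer(w1, w2)
    unfolded = JointSFS(counts=counts, folded=False, pop_ids=tuple(pops))
    return fold_jsfs(unfolded)


def choose_projection(
    gm,
    pops: tuple[str, str],
    filters: SfsFilterConfig | None = None,
) -> tuple[int, int]:
    """Choose projection sizes maximizing the expected number of segregating sites.

    For every candidate pair of haploid sizes, each retained site contributes
    the probability that it remains polymorphic in the projected joint
    spectrum; the pair with the largest expected total wins, ties broken
    toward larger sizes.
    """
    filters = filters or SfsFilterConfig()
    c1, d1, c2, d2, keep = _site_allele_counts(gm, pops, filters)
    labels = np.asarray(gm.pop_labels)
    h1 = 2 * int((labels == pops[0]).sum())
    h2 = 2 * int((labels == pops[1]).sum())
    sites = np.flatnonzero(keep)
    best = None
    for m1 in range(2, h1 + 1):
        for m2 in range(2, h2 + 1):
            expected = 0.0
            for s in sites:
                if c1[s] < m1 or c2[s] < m2:
                    continue
                p0 = _hyp_weights(int(c1[s]), int(d1[s]), m1)[0] * _hyp_weights(
                    int(c2[s]), int(d2[s]), m2
                )[0]
                pfix = _hyp_weights(int(c1[s]), int(d1[s]), m1)[m1] * _hyp_weights(
                    int(c2[s]), int(d2[s]), m2
                )[m2]
                expected += 1.0 - p0 - pfix
            cand = (expected, m1 + m2, m1, (m1, m2))
            if best is None or cand[:3] > best[:3]:
                best = cand
    assert best is not None
    return best[3]


# ---------------------------------------------------------------------------
# Flat-text exchange format
# ---------------------------------------------------------------------------


def write_sfs(sfs: JointSFS, path) -> None:
    """Write a spectrum in the three-line flat-text exchange format."""
    with open(path, "w") as fh:
        fh.write(f"{sfs.n1 + 1} {sfs.n2 + 1} {'folded' if sfs.folded else 'unfolded'}\n")
        fh.write(" ".join(f"{v:.17g}" for v in sfs.counts.ravel()) + "\n")
        fh.write(" ".join(str(int(v)) for v in sfs.mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    """Read a spectrum written by :func:`write_sfs` (bit-exact round trip)."""
    with open(path) as fh:
        header = fh.readline().split()
        r, c = int(header[0]), int(header[1])
        folded = header[2] == "folded"
        counts = np.array([float(v) for v in fh.readline().split()]).reshape(r, c)
        mask = np.array([int(v) for v in fh.readline().split()], dtype=bool).reshape(r, c)
    return JointSFS(counts=counts, folded=folded, mask=mask)
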