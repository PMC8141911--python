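"""Paleoclimate delta-method downscaling and the pseudo-absence GLM SDM.

The downscaling chain reconstructs fine-resolution historic climate in two
steps: anomalies ("deltas") between a historic window and a reference window
of a coarse simulated series are interpolated with a thin plate spline and
applied to a finer observational series; the procedure is repeated from the
mid-resolution series onto a fine reference climatology.  Temperature deltas
are differences, precipitation deltas are ratios.

Bioclim summaries (bio1, bio4, bio12, bio15) and topographic roughness feed a
binomial GLM with linear + quadratic terms per predictor, fitted on presence
cells against randomly drawn pseudo-absences; refugial augmentation adds the
historically most suitable cell of each refugial area as a presence and
refits.

Grids are kept in a small plain-text matrix format (header: ncols, nrows,
xllcorner, yllcorner, cellsize, nodata; then rows top-down), plus in-package
synthetic generators for monthly climate series and elevation with known
spatial structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import RBFInterpolator

__all__ = [
    "ClimateGrid",
    "EnvLayerSet",
    "SdmModel",
    "PeriodsConfig",
    "window_mean",
    "compute_deltas",
    "interpolate_field",
    "apply_deltas",
    "downscale_two_step",
    "derive_bioclim",
    "topo_roughness",
    "screen_collinearity",
    "draw_pseudoabsences",
    "fit_occurrence_glm",
    "augment_with_refugia",
    "read_grid",
    "write_grid",
    "synthetic_monthly_series",
    "synthetic_elevation",
]

_TEMP_KINDS = {"t_min", "t_max", "t_mean"}
_KINDS = _TEMP_KINDS | {"precip", "elevation", "delta", "bio", "other"}


@dataclass
class ClimateGrid:
    """A (stack of) co-registered raster layer(s).

    ``values`` has shape ``(..., nrows, ncols)`` — e.g. ``(nrows, ncols)`` for
    a single layer, ``(12, nrows, ncols)`` for a monthly climatology or
    ``(nyears, 12, nrows, ncols)`` for a monthly series starting at
    ``start_year``.  Missing cells are NaN.  The origin is the lower-left
    corner; row 0 of ``values`` is the northernmost row.
    """

    values: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    kind: str = "other"
    start_year: int | None = None
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.kind == "precip" and np.nanmin(self.values) < 0:
            raise ValueError("precipitation grids must be non-negative")

    @property
    def nrows(self) -> int:
        return self.values.shape[-2]

    @property
    def ncols(self) -> int:
        return self.values.shape[-1]

    def same_registration(self, other: "ClimateGrid") -> bool:
        return (
            self.values.shape[-2:] == other.values.shape[-2:]
            and math.isclose(self.cellsize, other.cellsize)
            and math.isclose(self.xll, other.xll)
            and math.isclose(self.yll, other.yll)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, row-major (row 0 = top)."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "ClimateGrid":
        return ClimateGrid(
            values=values,
            cellsize=self.cellsize,
            xll=self.xll,
            yll=self.yll,
            kind=kind or self.kind,
            start_year=None,
        )


@dataclass
class EnvLayerSet:
    """The five co-registered SDM predictors."""

    bio1: ClimateGrid
    bio4: ClimateGrid
    bio12: ClimateGrid
    bio15: ClimateGrid
    roughness: ClimateGrid | None = None

    def layers(self) -> dict[str, ClimateGrid]:
        out = {"bio1": self.bio1, "bio4": self.bio4, "bio12": self.bio12, "bio15": self.bio15}
        if self.roughness is not None:
            out["roughness"] = self.roughness
        return out

    def __post_init__(self) -> None:
        grids = list(self.layers().values())
        for g in grids[1:]:
            if not grids[0].same_registration(g):
                raise ValueError("EnvLayerSet layers are not co-registered")

    def stack(self) -> np.ndarray:
        """(n_layers, nrows, ncols) array in layer order."""
        return np.stack([g.values for g in self.layers().values()])

    @property
    def names(self) -> list[str]:
        return list(self.layers())


def _require_coregistered(a: ClimateGrid, b: ClimateGrid) -> None:
    if not a.same_registration(b):
        raise ValueError("grids are not co-registered")


# ---------------------------------------------------------------------------
# Downscaling chain
# ---------------------------------------------------------------------------


def window_mean(series: ClimateGrid, window: tuple[int, int]) -> ClimateGrid:
    """Per-cell, per-month arithmetic mean over a year window (inclusive)."""
    if series.values.ndim != 4 or series.start_year is None:
        raise ValueError("window_mean needs a (nyears, 12, nrows, ncols) series with start_year")
    y0, y1 = window
    first = series.start_year
    last = first + series.values.shape[0] - 1
    if y0 < first or y1 > last or y0 > y1:
        raise ValueError(f"window {window} outside series span [{first}, {last}]")
    sel = series.values[y0 - first : y1 - first + 1]
    out = series.with_values(sel.mean(axis=0))
    out.kind = series.kind
    return out


def compute_deltas(historic: ClimateGrid, reference: ClimateGrid, kind: str) -> ClimateGrid:
    """Deltas between a historic and a reference climatology.

    Temperature deltas are differences ``historic - reference``; precipitation
    deltas are ratios ``historic / reference`` (a zero-reference cell gets
    delta 1, i.e. "no change", and is flagged).
    """
    _require_coregistered(historic, reference)
    if kind == "temperature":
        out = historic.with_values(historic.values - reference.values, kind="delta")
    elif kind == "precipitation":
        zero = reference.values == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(zero, 1.0, historic.values / np.where(zero, 1.0, reference.values))
        out = historic.with_values(ratio, kind="delta")
        if np.any(zero):
            out.flagged = zero
    else:
        raise ValueError("kind must be 'temperature' or 'precipitation'")
    return out


def interpolate_field(coarse: ClimateGrid, target_resolution: float) -> ClimateGrid:
    """Thin-plate-spline interpolation of a field to a finer resolution.

    Fits an exact (zero-smoothing) thin plate spline through the coarse cell
    centers and evaluates it at the fine cell centers; affine fields are
    reproduced exactly and node values are honoured.  Monthly stacks are
    interpolated per month.
    """
    if target_resolution > coarse.cellsize:
        raise ValueError("target resolution must be finer than the source grid")
    ncols_f = int(round(coarse.ncols * coarse.cellsize / target_resolution))
    nrows_f = int(round(coarse.nrows * coarse.cellsize / target_resolution))
    fine_shape = ClimateGrid(
        values=np.zeros((nrows_f, ncols_f)),
        cellsize=target_resolution,
        xll=coarse.xll,
        yll=coarse.yll,
    )
    fx, fy = fine_shape.cell_centers()
    fine_pts = np.column_stack([fx.ravel(), fy.ravel()])
    cx, cy = coarse.cell_centers()
    layers = coarse.values if coarse.values.ndim == 3 else coarse.values[None]
    out = np.empty((layers.shape[0], nrows_f, ncols_f))
    for k, layer in enumerate(layers):
        ok = np.isfinite(layer)
        if ok.sum() < 3:
            raise ValueError("thin plate spline needs at least 3 non-missing nodes")
        pts = np.column_stack([cx[ok], cy[ok]])
        rbf = RBFInterpolator(pts, layer[ok], kernel="thin_plate_spline", smoothing=0.0)
        out[k] = rbf(fine_pts).reshape(nrows_f, ncols_f)
    if coarse.values.ndim == 2:
        out = out[0]
    result = fine_shape.with_values(out, kind=coarse.kind)
    return result


def apply_deltas(fine_reference: ClimateGrid, fine_delta: ClimateGrid, kind: str) -> ClimateGrid:
    """Apply interpolated deltas to a fine reference climatology.

    Temperature: reference + delta.  Precipitation: reference * delta, with
    negative results clamped to zero and flagged.
    """
    _require_coregistered(fine_reference, fine_delta)
    if kind == "temperature":
        return fine_reference.with_values(fine_reference.values + fine_delta.values)
    if kind == "precipitation":
        vals = fine_reference.values * fine_delta.values
        neg = vals < 0
        out = fine_reference.with_values(np.where(neg, 0.0, vals))
        if np.any(neg):
            out.flagged = neg
        return out
    raise ValueError("kind must be 'temperature' or 'precipitation'")


@dataclass(frozen=True)
class PeriodsConfig:
    """Year windows used by the two-step downscaling chain.

    ``target`` is the historic window to reconstruct; ``coarse_reference`` the
    coarse-series reference window shared with the mid series (classically
    1950-1980); ``mid_reference`` the mid-series window shared with the fine
    climatology (classically 1979-2013).
    """

    target: tuple[int, int]
    coarse_reference: tuple[int, int] = (1950, 1980)
    mid_reference: tuple[int, int] = (1979, 2013)


def downscale_two_step(
    paleo_coarse: ClimateGrid,
    mid_series: ClimateGrid,
    fine_climatology: ClimateGrid,
    periods: PeriodsConfig,
    kind: str,
) -> ClimateGrid:
    """Two-step delta-method downscaling of a historic window to the fine grid.

    Step 1 chains the coarse-series anomalies of the target window (relative
    to the coarse reference window) onto the mid-resolution series; step 2
    chains the resulting mid-resolution anomalies (relative to the mid
    reference window) onto the fine climatology.  If the target window equals
    the reference climate everywhere, the output equals the fine climatology.
    """
    if not (paleo_coarse.cellsize > mid_series.cellsize > fine_climatology.cellsize):
        raise ValueError(
            "resolutions must be strictly ordered coarse > mid > fine"
        )
    # step 1: coarse deltas onto the mid series
    hist_c = window_mean(paleo_coarse, periods.target)
    ref_c = window_mean(paleo_coarse, periods.coarse_reference)
    delta_c = compute_deltas(hist_c, ref_c, kind)
    delta_mid = interpolate_field(delta_c, mid_series.cellsize)
    mid_ref_for_step1 = window_mean(mid_series, periods.coarse_reference)
    mid_hist = apply_deltas(mid_ref_for_step1, delta_mid, kind)
    # step 2: mid deltas onto the fine climatology
    mid_ref2 = window_mean(mid_series, periods.mid_reference)
    delta_m = compute_deltas(mid_hist, mid_ref2, kind)
    delta_fine = interpolate_field(delta_m, fine_climatology.cellsize)
    return apply_deltas(fine_climatology, delta_fine, kind)


# ---------------------------------------------------------------------------
# Bioclim predictors
# ---------------------------------------------------------------------------


def derive_bioclim(monthly_temp: ClimateGrid, monthly_precip: ClimateGrid) -> EnvLayerSet:
    """bio1/bio4/bio12/bio15 from 12-month temperature and precipitation stacks.

    bio1 = annual mean of monthly mean temperature; bio4 = population SD of
    the 12 monthly means x 100; bio12 = annual precipitation sum; bio15 =
    precipitation seasonality, 100 x SD / mean of monthly precipitation
    (coefficient of variation; NaN-flagged where mean precipitation is zero).
    Population (n-denominator) standard deviations are used throughout.
    """
    if monthly_temp.values.ndim != 3 or monthly_temp.values.shape[0] != 12:
        raise ValueError("monthly_temp must have 12 monthly layers")
    if monthly_precip.values.ndim != 3 or monthly_precip.values.shape[0] != 12:
        raise ValueError("monthly_precip must have 12 monthly layers")
    _require_coregistered(monthly_temp, monthly_precip)
    t = monthly_temp.values
    p = monthly_precip.values
    bio1 = t.mean(axis=0)
    bio4 = t.std(axis=0, ddof=0) * 100.0
    bio12 = p.sum(axis=0)
    pmean = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bio15 = np.where(pmean > 0, 100.0 * p.std(axis=0, ddof=0) / np.where(pmean > 0, pmean, 1.0), np.nan)
    mk = lambda v: monthly_temp.with_values(v, kind="bio")
    return EnvLayerSet(bio1=mk(bio1), bio4=mk(bio4), bio12=mk(bio12), bio15=mk(bio15))


def topo_roughness(elevation_fine: ClimateGrid, coarse_cell_size: float) -> ClimateGrid:
    """Topographic roughness: population SD of fine elevations per coarse cell.

    The fine resolution must divide the coarse cell size; partial cells at the
    right/bottom edge use the available fine cells and are flagged.
    """
    ratio = coarse_cell_size / elevation_fine.cellsize
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fine resolution must divide the coarse cell size")
    r = int(round(ratio))
    v = elevation_fine.values
    nr = math.ceil(v.shape[0] / r)
    nc = math.ceil(v.shape[1] / r)
    out = np.empty((nr, nc))
    flagged = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            block = v[i * r : (i + 1) * r, j * r : (j + 1) * r]
            out[i, j] = np.nanstd(block, ddof=0)
            if block.size < r * r:
                flagged[i, j] = True
    grid = ClimateGrid(
        values=out,
        cellsize=coarse_cell_size,
        xll=elevation_fine.xll,
        yll=elevation_fine.yll + (elevation_fine.nrows - nr * r) * elevation_fine.cellsize,
        kind="other",
    )
    if flagged.any():
        grid.flagged = flagged
    return grid


def screen_collinearity(layers: EnvLayerSet, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations over non-missing cells, flagging |r| > threshold.

    A constant layer has undefined correlations; its pairs are flagged with
    ``r = NaN``.
    """
    named = layers.layers()
    if len(named) < 2:
        raise ValueError("need at least two layers")
    rows = []
    for (na, ga), (nb, gb) in _combinations(named.items(), 2):
        a = ga.values.ravel()
        b = gb.values.ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.std() == 0 or b.std() == 0:
            r = float("nan")
            flag = True
        else:
            r = float(np.corrcoef(a, b)[0, 1])
            flag = abs(r) > threshold
        rows.append({"layer_a": na, "layer_b": nb, "pearson_r": r, "flagged": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pseudo-absence GLM
# ---------------------------------------------------------------------------


def draw_pseudoabsences(
    domain_mask: np.ndarray,
    n: int,
    exclusion_masks: list[np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n`` distinct cells uniformly from the domain minus exclusions.

    Returns an ``(n, 2)`` array of (row, col) indices; raises if fewer than
    ``n`` cells are available.
    """
    allowed = np.asarray(domain_mask, dtype=bool).copy()
    for m in exclusion_masks or []:
        allowed &= ~np.asarray(m, dtype=bool)
    cells = np.flatnonzero(allowed)
    if cells.size < n:
        raise ValueError(f"only {cells.size} cells available, {n} requested")
    rng = np.random.default_rng(seed)
    pick = rng.choice(cells, size=n, replace=False)
    return np.column_stack(np.unravel_index(pick, allowed.shape))


@dataclass
class SdmModel:
    """Binomial GLM with linear + quadratic terms per standardized predictor."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    predictor_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    n_presences: int
    n_absences: int
    seed: int | None = None
    separation_flagged: bool = False
    presence_X: np.ndarray | None = None  # raw predictor values of the presences
    absence_X: np.ndarray | None = None  # raw predictor values of the absences

    def _design(self, X: np.ndarray) -> np.ndarray:
        if len(self.predictor_names) == 0:
            return np.ones((X.shape[0], 1))
        Z = (X - self.means) / self.sds
        return np.column_stack([np.ones(len(Z)), Z, Z**2])

    def predict_values(self, X: np.ndarray) -> np.ndarray:
        """Occurrence probability for raw predictor rows (in [0, 1])."""
        beta = np.array(
            [self.coefficients["intercept"]]
            + [self.coefficients[f"{n}"] for n in self.predictor_names]
            + [self.coefficients[f"{n}^2"] for n in self.predictor_names]
        )
        eta = self._design(np.atleast_2d(X)) @ beta
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, layers: EnvLayerSet) -> np.ndarray:
        """Occurrence-probability grid for a co-registered layer set."""
        stack = layers.stack()
        flat = stack.reshape(stack.shape[0], -1).T
        ok = np.isfinite(flat).all(axis=1)
        out = np.full(flat.shape[0], np.nan)
        if ok.any():
            out[ok] = self.predict_values(flat[ok])
        return out.reshape(stack.shape[1:])


def _extract(layers: EnvLayerSet, cells: np.ndarray) -> np.ndarray:
    stack = layers.stack()
    return stack[:, cells[:, 0], cells[:, 1]].T


def fit_occurrence_glm(
    presences: np.ndarray,
    absences: np.ndarray,
    layers: EnvLayerSet | None,
    presence_values: np.ndarray | None = None,
    absence_values: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> SdmModel:
    """Fit the binomial logit GLM of occurrence on the environmental layers.

    ``presences``/``absences`` are (n, 2) cell-index arrays into ``layers``
    (or pass raw value matrices directly via ``presence_values`` /
    ``absence_values``; with ``layers=None`` and no values an intercept-only
    model is fitted).  Predictors are standardized internally; each enters
    with a linear and a quadratic term.  Perfect separation is caught and
    flagged, returning the coefficients at the iteration cap.
    """
    if presence_values is None:
        presence_values = (
            _extract(layers, np.atleast_2d(presences)) if layers is not None else
            np.zeros((len(presences), 0))
        )
    if absence_values is None:
        absence_values = (
            _extract(layers, np.atleast_2d(absences)) if layers is not None else
            np.zeros((len(absences), 0))
        )
    if len(presence_values) == 0 or len(absence_values) == 0:
        raise ValueError("both presences and absences are required")
    X = np.vstack([presence_values, absence_values])
    y = np.concatenate([np.ones(len(presence_values)), np.zeros(len(absence_values))])
    names = layers.names if (layers is not None and X.shape[1]) else (
        [f"x{i}" for i in range(X.shape[1])]
    )
    if X.shape[1] == 0:
        names = []
        means = np.zeros(0)
        sds = np.ones(0)
        design = np.ones((len(y), 1))
    else:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        sds = np.where(sds == 0, 1.0, sds)
        Z = (X - means) / sds
        design = np.column_stack([np.ones(len(Z)), Z, Z**2])
    flagged = False
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=tol, maxiter=maxiter
            )
            params = fit.params
        except Exception:
            flagged = True
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                    tol=tol, maxiter=maxiter
                )
                params = fit.params
    bse = fit.bse
    coefs = {"intercept": float(params[0])}
    ses = {"intercept": float(bse[0])}
    for i, nme in enumerate(names):
        coefs[nme] = float(params[1 + i])
        coefs[f"{nme}^2"] = float(params[1 + len(names) + i])
        ses[nme] = float(bse[1 + i])
        ses[f"{nme}^2"] = float(bse[1 + len(names) + i])
    return SdmModel(
        coefficients=coefs,
        standard_errors=ses,
        predictor_names=list(names),
        means=means,
        sds=sds,
        n_presences=int(y.sum()),
        n_absences=int(len(y) - y.sum()),
        separation_flagged=flagged,
        presence_X=presence_values,
        absence_X=absence_values,
    )


def augment_with_refugia(
    model: SdmModel,
    refugial_areas: list[np.ndarray],
    historic_layers: EnvLayerSet,
    layers_current: EnvLayerSet,
    seed: int = 0,
    n_per_source: int = 5000,
    glaciated_mask: np.ndarray | None = None,
    current_distribution_mask: np.ndarray | None = None,
) -> SdmModel:
    """Refit the SDM after adding the best historic cell of each refugium.

    For every refugial area the historic-climate cell with the highest
    occurrence probability under the current model is appended as a presence
    (with its historic climate).  Pseudo-absences are regenerated as
    ``n_per_source`` cells from the historic and ``n_per_source`` from the
    current climate, excluding refugia, glaciated areas and the current
    distribution, and the GLM is refitted on the combined data.
    """
    if not refugial_areas:
        raise ValueError("at least one refugial area is required")
    prob = model.predict(historic_layers)
    new_presence_values = []
    for k, mask in enumerate(refugial_areas):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"refugial area {k} is empty")
        masked = np.where(mask, prob, -np.inf)
        best = np.unravel_index(np.nanargmax(masked), masked.shape)
        new_presence_values.append(_extract(historic_layers, np.array([best]))[0])
    presence_values = model.presence_X
    if presence_values is None:
        raise ValueError("model does not carry its training presences")
    presence_values = np.vstack([presence_values] + new_presence_values)

    shape = historic_layers.bio1.values.shape
    domain = np.isfinite(historic_layers.stack()).all(axis=0)
    domain_cur = np.isfinite(layers_current.stack()).all(axis=0)
    exclusions = [np.asarray(m, dtype=bool) for m in refugial_areas]
    if glaciated_mask is not None:
        exclusions.append(np.asarray(glaciated_mask, dtype=bool))
    if current_distribution_mask is not None:
        exclusions.append(np.asarray(current_distribution_mask, dtype=bool))
    abs_hist = draw_pseudoabsences(domain, n_per_source, exclusions, seed=seed)
    abs_cur = draw_pseudoabsences(domain_cur, n_per_source, exclusions, seed=seed + 1)
    absence_values = np.vstack(
        [_extract(historic_layers, abs_hist), _extract(layers_current, abs_cur)]
    )
    out = fit_occurrence_glm(
        presences=None,
        absences=None,
        layers=layers_current,
        presence_values=presence_values,
        absence_values=absence_values,
    )
    out.seed = seed
    return out


# ---------------------------------------------------------------------------
# Plain-text grid format and synthetic generators
# ---------------------------------------------------------------------------


def write_grid(grid: ClimateGrid, path) -> None:
    """Write a single-layer grid in the plain-text matrix format."""
    if grid.values.ndim != 2:
        raise ValueError("only single-layer grids are written to text")
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.10g}\n")
        fh.write(f"yllcorner {grid.yll:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write("nodata -9999\n")
        for row in grid.values:
            fh.write(" ".join("-9999" if not np.isfinite(v) else f"{v:.10g}" for v in row) + "\n")


def read_grid(path, kind: str = "other") -> ClimateGrid:
    """Read a grid written by :func:`write_grid`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        rows = [[float(v) for v in line.split()] for line in fh if line.strip()]
    values = np.array(rows)
    values[values == header["nodata"]] = np.nan
    return ClimateGrid(
        values=values,
        cellsize=header["cellsize"],
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        kind=kind,
    )


def _smooth_surface(rng, nrows, ncols, xx, yy, amplitude, n_bumps=4):
    out = rng.normal(0.0, 0.1 * amplitude) + rng.normal(0, amplitude / 10) * xx + rng.normal(
        0, amplitude / 10
    ) * yy
    for _ in range(n_bumps):
        cx, cy = rng.uniform(0, 1, 2)
        w = rng.uniform(0.1, 0.4)
        out = out + rng.normal(0, amplitude) * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * w**2)
        )
    return out


def synthetic_monthly_series(
    nrows: int = 12,
    ncols: int = 12,
    cellsize: float = 1.0,
    years: tuple[int, int] = (1900, 2020),
    kind: str = "t_mean",
    seed: int = 0,
    annual_mean: float | None = None,
) -> ClimateGrid:
    """Seeded synthetic monthly climate series with smooth spatial structure.

    Emulates a gridded monthly product: a smooth spatial mean field, a
    sinusoidal seasonal cycle and small interannual noise.  Temperature-like
    kinds are in degrees Celsius, precipitation in mm/month (non-negative).
    """
    rng = np.random.default_rng(seed)
    y0, y1 = years
    nyears = y1 - y0 + 1
    xx, yy = np.meshgrid(np.linspace(0, 1, ncols), np.linspace(0, 1, nrows))
    is_precip = kind == "precip"
    base_level = annual_mean if annual_mean is not None else (80.0 if is_precip else 8.0)
    spatial = base_level + _smooth_surface(rng, nrows, ncols, xx, yy, 3.0 if not is_precip else 25.0)
    months = np.arange(12)
    seasonal_amp = 8.0 if not is_precip else 30.0
    seasonal = seasonal_amp * np.sin(2 * np.pi * (months - 3) / 12.0)
    vals = (
        spatial[None, None]
        + seasonal[None, :, None, None]
        + rng.normal(0, 0.5 if not is_precip else 5.0, size=(nyears, 12, nrows, ncols))
    )
    if is_precip:
        vals = np.clip(vals, 0.0, None)
    return ClimateGrid(
        values=vals, cellsize=cellsize, xll=0.0, yll=0.0, kind=kind, start_year=y0
    )


def synthetic_elevation(
    nrows: int = 60,
    ncols: int = 60,
    cellsize: float = 0.1,
    seed: int = 0,
    relief: float = 800.0,
) -> ClimateGrid:
    """Seeded synthetic elevation grid with ridges and valleys (meters)."""
    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(np.linspace(0, 1, ncols), np.linspace(0, 1, nrows))
    vals = 500.0 + _smooth_surface(rng, nrows, ncols, xx, yy, relief, n_bumps=8)
    vals += rng.normal(0, relief / 40.0, size=vals.shape)
    return ClimateGrid(values=vals, cellsize=cellsize, xll=0.0, yll=0.0, kind="elevation")
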