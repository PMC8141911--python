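"""Downscaling chain, bioclim derivation, collinearity screen and the SDM."""

import numpy as np
import pytest
from scipy.stats import chisquare

from vicfound.paleosdm import (
    ClimateGrid,
    EnvLayerSet,
    PeriodsConfig,
    apply_deltas,
    augment_with_refugia,
    compute_deltas,
    derive_bioclim,
    downscale_two_step,
    draw_pseudoabsences,
    fit_occurrence_glm,
    interpolate_field,
    read_grid,
    screen_collinearity,
    synthetic_elevation,
    synthetic_monthly_series,
    topo_roughness,
    window_mean,
    write_grid,
)


def const_series(value, n, cellsize, years, kind="t_mean"):
    ny = years[1] - years[0] + 1
    return ClimateGrid(
        np.full((ny, 12, n, n), float(value)), cellsize=cellsize, start_year=years[0], kind=kind
    )


def grid2d(values, cellsize=1.0, kind="other"):
    return ClimateGrid(np.asarray(values, dtype=float), cellsize=cellsize, kind=kind)


# ---------------------------------------------------------------------------
# window means and deltas
# ---------------------------------------------------------------------------


def test_window_mean_constant_and_alternating():
    s = const_series(3.0, 4, 1.0, (2000, 2009))
    assert np.all(window_mean(s, (2001, 2004)).values == 3.0)
    vals = np.zeros((10, 12, 2, 2))
    vals[::2] = 2.0  # alternating 2/0 over years
    s2 = ClimateGrid(vals, cellsize=1.0, start_year=2000, kind="t_mean")
    assert np.allclose(window_mean(s2, (2000, 2009)).values, 1.0)


def test_window_mean_matches_brute_force(rng):
    vals = rng.normal(size=(15, 12, 3, 3))
    s = ClimateGrid(vals, cellsize=1.0, start_year=1990, kind="t_mean")
    got = window_mean(s, (1995, 2001)).values
    np.testing.assert_allclose(got, vals[5:12].mean(axis=0))


def test_window_outside_span_is_error():
    s = const_series(1.0, 2, 1.0, (2000, 2005))
    with pytest.raises(ValueError, match="outside"):
        window_mean(s, (1990, 2001))


def test_deltas_identity_and_offset(rng):
    ref = grid2d(rng.normal(10, 2, (12, 4, 4)))
    same = compute_deltas(ref, ref, "temperature")
    assert np.allclose(same.values, 0.0)
    shifted = grid2d(ref.values - 5.0)
    assert np.allclose(compute_deltas(shifted, ref, "temperature").values, -5.0)
    p = grid2d(np.abs(ref.values) + 1.0)
    assert np.allclose(compute_deltas(p, p, "precipitation").values, 1.0)


def test_precip_delta_zero_reference_flagged():
    hist = grid2d([[1.0, 2.0]])
    ref = grid2d([[0.0, 2.0]])
    d = compute_deltas(hist, ref, "precipitation")
    assert d.values[0, 0] == 1.0
    assert d.flagged[0, 0] and not d.flagged[0, 1]


def test_apply_deltas_matches_hand_computation(rng):
    ref = grid2d(np.abs(rng.normal(5, 1, (3, 3))))
    d = grid2d(rng.normal(0, 1, (3, 3)))
    np.testing.assert_allclose(
        apply_deltas(ref, d, "temperature").values, ref.values + d.values
    )
    ratio = grid2d(np.abs(rng.normal(1, 0.2, (3, 3))))
    np.testing.assert_allclose(
        apply_deltas(ref, ratio, "precipitation").values, ref.values * ratio.values
    )


# ---------------------------------------------------------------------------
# thin plate spline
# ---------------------------------------------------------------------------


def test_tps_reproduces_constant_field():
    c = grid2d(np.full((5, 5), 7.3), cellsize=2.0)
    f = interpolate_field(c, 0.5)
    assert np.allclose(f.values, 7.3, atol=1e-8)


def test_tps_reproduces_affine_field_exactly():
    c = grid2d(np.zeros((6, 6)), cellsize=2.0)
    x, y = c.cell_centers()
    c.values = 1.5 + 0.25 * x - 0.4 * y
    f = interpolate_field(c, 0.5)
    fx, fy = f.cell_centers()
    np.testing.assert_allclose(f.values, 1.5 + 0.25 * fx - 0.4 * fy, atol=1e-8)


def test_tps_is_exact_at_the_nodes(rng):
    c = grid2d(rng.normal(size=(5, 5)), cellsize=2.0)
    f = interpolate_field(c, 1.0)
    cx, cy = c.cell_centers()
    fx, fy = f.cell_centers()
    for i in range(5):
        for j in range(5):
            hit = np.isclose(fx, cx[i, j]) & np.isclose(fy, cy[i, j])
            assert np.allclose(f.values[hit], c.values[i, j], atol=1e-8)


def test_tps_needs_three_nodes():
    c = grid2d(np.full((3, 3), np.nan), cellsize=2.0)
    c.values[0, 0] = 1.0
    with pytest.raises(ValueError, match="at least 3"):
        interpolate_field(c, 1.0)


# ---------------------------------------------------------------------------
# two-step chain
# ---------------------------------------------------------------------------

PERIODS = PeriodsConfig(target=(1905, 1935))


def test_two_step_identity_chain_returns_fine_climatology(rng):
    coarse = const_series(4.0, 5, 4.0, (1900, 1990))
    mid = const_series(9.0, 10, 2.0, (1900, 2020))
    fine_vals = rng.normal(12, 3, size=(12, 40, 40))
    fine = ClimateGrid(fine_vals, cellsize=0.5, kind="t_mean")
    out = downscale_two_step(coarse, mid, fine, PERIODS, "temperature")
    np.testing.assert_allclose(out.values, fine_vals, atol=1e-8)


def test_two_step_constant_offset_propagates(rng):
    # historic window 3 degrees colder everywhere at the coarse scale
    ny = 91
    coarse_vals = np.full((ny, 12, 5, 5), 4.0)
    coarse_vals[: 1940 - 1900] -= 3.0  # covers the target window
    coarse = ClimateGrid(coarse_vals, cellsize=4.0, start_year=1900, kind="t_mean")
    mid = const_series(9.0, 10, 2.0, (1900, 2020))
    fine_vals = rng.normal(12, 3, size=(12, 40, 40))
    fine = ClimateGrid(fine_vals, cellsize=0.5, kind="t_mean")
    out = downscale_two_step(coarse, mid, fine, PERIODS, "temperature")
    np.testing.assert_allclose(out.values, fine_vals - 3.0, atol=1e-7)


def test_two_step_requires_ordered_resolutions():
    coarse = const_series(4.0, 5, 1.0, (1900, 1990))
    mid = const_series(9.0, 10, 2.0, (1900, 2020))
    fine = ClimateGrid(np.zeros((12, 4, 4)), cellsize=0.5, kind="t_mean")
    with pytest.raises(ValueError, match="ordered"):
        downscale_two_step(coarse, mid, fine, PERIODS, "temperature")


# ---------------------------------------------------------------------------
# bioclim + roughness + collinearity
# ---------------------------------------------------------------------------


def test_bioclim_constant_inputs():
    t = ClimateGrid(np.full((12, 3, 3), 10.0), cellsize=1.0, kind="t_mean")
    p = ClimateGrid(np.full((12, 3, 3), 100.0), cellsize=1.0, kind="precip")
    L = derive_bioclim(t, p)
    assert np.allclose(L.bio1.values, 10.0)
    assert np.allclose(L.bio4.values, 0.0)
    assert np.allclose(L.bio12.values, 1200.0)
    assert np.allclose(L.bio15.values, 0.0)


def test_bioclim_alternating_precip_matches_brute_force():
    months = np.array([50.0, 150.0] * 6)
    p = ClimateGrid(np.tile(months[:, None, None], (1, 2, 2)), cellsize=1.0, kind="precip")
    t = ClimateGrid(np.zeros((12, 2, 2)), cellsize=1.0, kind="t_mean")
    L = derive_bioclim(t, p)
    # brute-force oracle with the package's population-SD convention
    sd = np.sqrt(((months - months.mean()) ** 2).sum() / 12)
    expected_bio15 = 100.0 * sd / months.mean()
    assert np.allclose(L.bio12.values, 1200.0)
    assert np.allclose(L.bio15.values, expected_bio15)


def test_bioclim_invariant_to_month_permutation(rng):
    t_vals = rng.normal(8, 6, size=(12, 4, 4))
    p_vals = np.abs(rng.normal(80, 30, size=(12, 4, 4)))
    perm = rng.permutation(12)
    mk = lambda v, k: ClimateGrid(v, cellsize=1.0, kind=k)
    a = derive_bioclim(mk(t_vals, "t_mean"), mk(p_vals, "precip"))
    b = derive_bioclim(mk(t_vals[perm], "t_mean"), mk(p_vals[perm], "precip"))
    for name in ("bio1", "bio4", "bio12", "bio15"):
        np.testing.assert_allclose(
            getattr(a, name).values, getattr(b, name).values, atol=1e-10
        )


def test_bioclim_zero_precip_flagged_missing():
    t = ClimateGrid(np.zeros((12, 2, 2)), cellsize=1.0, kind="t_mean")
    p_vals = np.zeros((12, 2, 2))
    p_vals[:, 0, 0] = 10.0
    p = ClimateGrid(p_vals, cellsize=1.0, kind="precip")
    L = derive_bioclim(t, p)
    assert np.isnan(L.bio15.values[1, 1])
    assert np.isfinite(L.bio15.values[0, 0])


def test_roughness_flat_and_binary_terrain():
    flat = grid2d(np.zeros((8, 8)), cellsize=0.5, kind="elevation")
    assert np.allclose(topo_roughness(flat, 1.0).values, 0.0)
    halves = np.zeros((8, 8))
    halves[:, ::2] = 10.0
    g = grid2d(halves, cellsize=0.5, kind="elevation")
    assert np.allclose(topo_roughness(g, 1.0).values, 5.0)


def test_roughness_matches_brute_force(rng):
    vals = rng.normal(500, 100, size=(9, 12))
    g = grid2d(vals, cellsize=1.0, kind="elevation")
    r = topo_roughness(g, 3.0)
    for i in range(3):
        for j in range(4):
            block = vals[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            assert np.isclose(r.values[i, j], block.std(ddof=0))


def test_roughness_partial_edge_cells_flagged(rng):
    vals = rng.normal(size=(7, 7))
    r = topo_roughness(grid2d(vals, cellsize=1.0, kind="elevation"), 3.0)
    assert r.flagged is not None
    assert r.flagged[-1, -1]
    assert not r.flagged[0, 0]


def layerset_from(arrs):
    names = ["bio1", "bio4", "bio12", "bio15", "roughness"]
    grids = {n: grid2d(a) for n, a in zip(names, arrs)}
    return EnvLayerSet(**grids)


def test_collinearity_flags_self_and_anticorrelation(rng):
    a = rng.normal(size=(10, 10))
    L = layerset_from([a, a.copy(), -a, rng.normal(size=(10, 10)), rng.normal(size=(10, 10))])
    rep = screen_collinearity(L).set_index(["layer_a", "layer_b"])
    assert np.isclose(rep.loc[("bio1", "bio4"), "pearson_r"], 1.0)
    assert rep.loc[("bio1", "bio4"), "flagged"]
    assert np.isclose(rep.loc[("bio1", "bio12"), "pearson_r"], -1.0)
    assert rep.loc[("bio1", "bio12"), "flagged"]
    assert not rep.loc[("bio15", "roughness"), "flagged"]


def test_collinearity_constant_layer_flagged_undefined(rng):
    L = layerset_from(
        [np.ones((5, 5)), rng.normal(size=(5, 5)), rng.normal(size=(5, 5)),
         rng.normal(size=(5, 5)), rng.normal(size=(5, 5))]
    )
    rep = screen_collinearity(L)
    row = rep[(rep.layer_a == "bio1") & (rep.layer_b == "bio4")].iloc[0]
    assert np.isnan(row.pearson_r) and row.flagged


# ---------------------------------------------------------------------------
# pseudo-absences and GLM
# ---------------------------------------------------------------------------


def test_pseudoabsences_exact_remainder():
    domain = np.ones((4, 5), dtype=bool)
    excl = domain.copy()
    excl[1, 2] = excl[3, 4] = excl[0, 0] = False
    pts = draw_pseudoabsences(domain, 3, [excl], seed=0)
    assert sorted(map(tuple, pts)) == [(0, 0), (1, 2), (3, 4)]


def test_pseudoabsences_avoid_exclusions_and_are_distinct(rng):
    domain = np.ones((30, 30), dtype=bool)
    excl = rng.random((30, 30)) < 0.3
    pts = draw_pseudoabsences(domain, 200, [excl], seed=3)
    assert len({tuple(p) for p in pts}) == 200
    assert not excl[pts[:, 0], pts[:, 1]].any()


def test_pseudoabsences_uniform_over_quadrants():
    domain = np.ones((120, 120), dtype=bool)
    pts = draw_pseudoabsences(domain, 10000, seed=9)
    quad = 2 * (pts[:, 0] >= 60) + (pts[:, 1] >= 60)
    counts = np.bincount(quad, minlength=4)
    assert chisquare(counts).pvalue > 0.01


def test_pseudoabsences_insufficient_cells_error():
    with pytest.raises(ValueError, match="available"):
        draw_pseudoabsences(np.ones((2, 2), bool), 5, seed=0)


def test_intercept_only_glm_equals_logit_of_prevalence():
    m = fit_occurrence_glm(
        None, None, layers=None,
        presence_values=np.zeros((30, 0)), absence_values=np.zeros((70, 0)),
    )
    assert np.isclose(m.coefficients["intercept"], np.log(30 / 70), atol=1e-8)


def test_glm_recovers_quadratic_logit_within_three_se(rng):
    n = 5000
    X = rng.normal(size=(n, 2))
    b = {"b0": -0.4, "x0": 1.0, "x0q": -0.7, "x1": 0.5, "x1q": -0.3}
    eta = b["b0"] + b["x0"] * X[:, 0] + b["x0q"] * X[:, 0] ** 2 + b["x1"] * X[:, 1] + b["x1q"] * X[:, 1] ** 2
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    m = fit_occurrence_glm(None, None, layers=None, presence_values=X[y], absence_values=X[~y])
    # transform the true coefficients into the model's standardized basis
    mu, sd = m.means, m.sds
    true_std = {
        "x0": (b["x0"] + 2 * b["x0q"] * mu[0]) * sd[0],
        "x0^2": b["x0q"] * sd[0] ** 2,
        "x1": (b["x1"] + 2 * b["x1q"] * mu[1]) * sd[1],
        "x1^2": b["x1q"] * sd[1] ** 2,
    }
    for key, truth in true_std.items():
        est = m.coefficients[key]
        se = m.standard_errors[key]
        assert abs(est - truth) < 3 * se, key


def test_glm_predictions_lie_in_unit_interval(rng):
    X = rng.normal(size=(200, 2))
    y = rng.random(200) < 0.4
    if y.all() or not y.any():
        y[0] = ~y[0]
    m = fit_occurrence_glm(None, None, layers=None, presence_values=X[y], absence_values=X[~y])
    p = m.predict_values(rng.normal(scale=10, size=(500, 2)))
    assert np.all((p >= 0) & (p <= 1))


def _toy_sdm(rng, n=24):
    arrs = [rng.normal(size=(n, n)) for _ in range(5)]
    layers = layerset_from(arrs)
    pres = draw_pseudoabsences(np.ones((n, n), bool), 25, seed=1)
    absn = draw_pseudoabsences(np.ones((n, n), bool), 60, seed=2)
    model = fit_occurrence_glm(pres, absn, layers)
    return layers, model


def test_augmentation_adds_exactly_one_presence_per_area(rng):
    layers, model = _toy_sdm(rng)
    n = layers.bio1.values.shape[0]
    refugia = [np.zeros((n, n), bool) for _ in range(3)]
    refugia[0][2:5, 2:5] = True
    refugia[1][10:14, 10:12] = True
    refugia[2][20:22, 5:9] = True
    hist = layerset_from([layers.bio1.values - 4.0] + [g.values for g in list(layers.layers().values())[1:]])
    out = augment_with_refugia(model, refugia, hist, layers, seed=5, n_per_source=50)
    assert out.n_presences == model.n_presences + 3


def test_augmentation_uses_the_single_shared_refugial_climate(rng):
    layers, model = _toy_sdm(rng)
    n = layers.bio1.values.shape[0]
    mask = np.zeros((n, n), bool)
    mask[4:8, 4:8] = True
    uniform_vals = [np.where(mask, 1.7 * (k + 1), g.values) for k, g in enumerate(layers.layers().values())]
    hist = layerset_from(uniform_vals)
    out = augment_with_refugia(model, [mask], hist, layers, seed=6, n_per_source=50)
    added = out.presence_X[-1]
    np.testing.assert_allclose(added, [1.7 * (k + 1) for k in range(5)])
    assert out.n_presences == model.n_presences + 1


def test_augmentation_does_not_depress_refugial_suitability(rng):
    # against a control refit on the identical regenerated absences, adding
    # the refugial presence must not lower its own predicted suitability
    layers, model = _toy_sdm(rng)
    n = layers.bio1.values.shape[0]
    mask = np.zeros((n, n), bool)
    mask[6:10, 6:10] = True
    out = augment_with_refugia(model, [mask], layers, layers, seed=7, n_per_source=50)
    control = fit_occurrence_glm(
        None, None, layers,
        presence_values=model.presence_X, absence_values=out.absence_X,
    )
    added = out.presence_X[-1]
    without = control.predict_values(added[None])[0]
    with_presence = out.predict_values(added[None])[0]
    assert with_presence >= without - 1e-9


def test_empty_refugium_is_an_error(rng):
    layers, model = _toy_sdm(rng)
    n = layers.bio1.values.shape[0]
    with pytest.raises(ValueError, match="empty"):
        augment_with_refugia(model, [np.zeros((n, n), bool)], layers, layers, seed=1, n_per_source=10)


# ---------------------------------------------------------------------------
# text grids and synthetic generators
# ---------------------------------------------------------------------------


def test_grid_text_roundtrip(tmp_path, rng):
    g = grid2d(rng.normal(size=(6, 8)), cellsize=0.25)
    g.values[2, 3] = np.nan
    path = tmp_path / "g.txt"
    write_grid(g, path)
    back = read_grid(path)
    assert back.cellsize == g.cellsize
    np.testing.assert_allclose(back.values, g.values, atol=1e-9, equal_nan=True)


def test_synthetic_series_shapes_and_seasonality():
    s = synthetic_monthly_series(nrows=6, ncols=7, years=(2000, 2004), kind="precip", seed=1)
    assert s.values.shape == (5, 12, 6, 7)
    assert np.nanmin(s.values) >= 0.0
    t = synthetic_monthly_series(nrows=6, ncols=7, years=(2000, 2004), kind="t_mean", seed=1)
    clim = t.values.mean(axis=0)
    monthly_range = clim.mean(axis=(1, 2)).max() - clim.mean(axis=(1, 2)).min()
    assert monthly_range > 5.0  # a real seasonal cycle


def test_synthetic_elevation_reproducible():
    a = synthetic_elevation(seed=3)
    b = synthetic_elevation(seed=3)
    assert np.array_equal(a.values, b.values)
    assert a.values.std() > 50.0
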