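"""Response-surface OLS: exact interpolation, factorial effects, scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sfekin as sk
from sfekin.doe import DesignError, full_quadratic_terms


def _bbd_table(factors, responses):
    """Build a 3-factor Box-Behnken table (12 edge midpoints + 3 centers)."""
    names = [f.name for f in factors]
    rows = []
    for (i, j) in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1, 1), repeat=2):
            coded = [0, 0, 0]
            coded[i], coded[j] = si, sj
            rows.append(coded)
    rows += [[0, 0, 0]] * 3
    data = pd.DataFrame(
        [[f.decode(c) for f, c in zip(factors, row)] for row in rows],
        columns=names,
        index=pd.RangeIndex(1, len(rows) + 1, name="run"),
    )
    for name, vals in responses.items():
        data[name] = vals
    return sk.DesignTable(factors, data, response_scale={k: "percent" for k in responses})


@pytest.fixture(scope="module")
def bbd_factors():
    return [
        sk.Factor("P", 200.0, 250.0, 300.0, unit="bar"),
        sk.Factor("T", 40.0, 50.0, 60.0, unit="degC"),
        sk.Factor("G", 42.0, 60.0, 150.0, unit="mesh"),
    ]


def test_selectivity_surface_r_squared(selectivity_fit):
    # the published coefficient of determination of the Box-Behnken refit
    assert selectivity_fit.rsquared == pytest.approx(0.9125, abs=5e-4)


def test_noise_free_quadratic_recovered_exactly(bbd_factors):
    truth = sk.QuadraticSurface(
        factor_names=["P", "T", "G"],
        coefficients={
            "const": 3.0, "P": 0.02, "T": -0.05, "G": 0.01,
            "P*P": -1e-4, "T*T": -2e-3, "G*G": -5e-5,
            "P*T": 1e-5, "P*G": -2e-5, "T*G": 3e-4,
        },
        response_name="y",
    )
    table = _bbd_table(bbd_factors, {})
    table = sk.simulate_design_response(truth, table)
    res = sk.ResponseSurfaceModel(table, "y").fit()
    for term in full_quadratic_terms(["P", "T", "G"]):
        assert res.params[term] == pytest.approx(
            truth.coefficients[term], rel=1e-9, abs=1e-12
        )
    assert res.rsquared == pytest.approx(1.0, abs=1e-12)


def test_constant_response_gives_flat_surface(bbd_factors):
    table = _bbd_table(bbd_factors, {"y": [4.2] * 15})
    res = sk.ResponseSurfaceModel(table, "y").fit()
    assert res.params["const"] == pytest.approx(4.2)
    assert np.allclose(res.params.drop("const"), 0.0, atol=1e-12)


def test_too_few_runs_rejected(bbd_factors):
    table = _bbd_table(bbd_factors, {"y": np.arange(15.0)})
    short = sk.DesignTable(
        bbd_factors, table.data.iloc[:8], response_scale={"y": "percent"}
    )
    with pytest.raises(DesignError, match="runs cannot identify"):
        sk.ResponseSurfaceModel(short, "y").fit()


def test_collinear_terms_named(bbd_factors):
    # duplicating the 12 edge runs only (no centers) leaves the three
    # squares mutually confounded with the intercept
    table = _bbd_table(bbd_factors, {"y": np.arange(15.0)})
    no_center = sk.DesignTable(
        bbd_factors, table.data.iloc[:12], response_scale={"y": "percent"}
    )
    with pytest.raises(DesignError, match="collinear"):
        sk.ResponseSurfaceModel(no_center, "y").fit()


def test_two_level_factorial_corner_coefficients(table1):
    corners = sk.DesignTable(
        table1.factors, table1.data.iloc[:4], response_scale=table1.response_scale
    )
    res = sk.TwoLevelFactorialModel(corners, "global_yield").fit()
    # hand least squares on the printed corner yields 1.25/1.70/1.71/2.49
    assert res.params["const"] == pytest.approx(1.7875, abs=1e-12)
    assert res.params["P"] == pytest.approx(0.3125, abs=1e-12)
    assert res.params["M"] == pytest.approx(0.3075, abs=1e-12)
    assert res.params["P*M"] == pytest.approx(0.0825, abs=1e-12)
    assert res.rsquared == pytest.approx(1.0)
    assert res.effects["P"] == pytest.approx(0.625)


def test_two_level_factorial_curvature(table1):
    res = sk.TwoLevelFactorialModel(
        table1, "global_yield", center_point_term=True
    ).fit()
    # mean(center) - mean(corners) = 2.30 - 1.7875
    assert res.curvature == pytest.approx(0.5125, abs=1e-12)
    assert res.params["const"] == pytest.approx(1.7875, abs=1e-12)


def test_center_term_without_centers_rejected(table1):
    corners = sk.DesignTable(
        table1.factors, table1.data.iloc[:4], response_scale=table1.response_scale
    )
    with pytest.raises(DesignError, match="center"):
        sk.TwoLevelFactorialModel(corners, "global_yield", center_point_term=True).fit()


def test_all_equal_responses_give_zero_effects(table1):
    data = table1.data.copy()
    data["global_yield"] = 2.0
    t = sk.DesignTable(table1.factors, data, response_scale=table1.response_scale)
    res = sk.TwoLevelFactorialModel(t, "global_yield").fit()
    assert all(abs(e) < 1e-12 for e in res.effects.values())


def test_percent_fraction_equivariance(table3):
    """Rescaling the response multiplies every coefficient by exactly 100
    and leaves R^2 unchanged."""
    pct = sk.ResponseSurfaceModel(table3, "selectivity", scale="percent").fit()
    frac = sk.ResponseSurfaceModel(table3, "selectivity", scale="fraction").fit()
    ratio = pct.params / frac.params
    assert np.allclose(ratio, 100.0, rtol=1e-10)
    assert pct.rsquared == pytest.approx(frac.rsquared, rel=1e-10)
    surf = frac.surface.on_response_scale("percent")
    assert np.allclose(
        surf.as_series(), pct.surface.as_series(), rtol=1e-10
    )


def test_surface_evaluation_matches_published_regime(selectivity_fit):
    # interpolation at a design point reproduces the fitted value
    fitted = selectivity_fit.fittedvalues
    point = {"P": 250.0, "T": 40.0, "G": 42.0}
    val = selectivity_fit.predict(point)
    run12 = selectivity_fit.model.table.data.index.get_loc(12)
    assert val == pytest.approx(fitted[run12], rel=1e-12)


def test_prediction_warns_on_extrapolation(selectivity_fit):
    with pytest.warns(UserWarning, match="outside the experimental range"):
        selectivity_fit.predict({"P": 350.0, "T": 50.0, "G": 60.0})


def test_coefficient_error_shrinks_with_noise(bbd_factors):
    """Mean absolute coefficient error decreases monotonically as the
    response noise goes to zero (100 seeds per level)."""
    truth = sk.QuadraticSurface(
        factor_names=["P", "T", "G"],
        coefficients={
            "const": 2.0, "P": 0.01, "T": -0.02, "G": 0.005,
            "P*P": -8e-5, "T*T": -1e-3, "G*G": -3e-5,
            "P*T": 2e-5, "P*G": -1e-5, "T*G": 2e-4,
        },
        response_name="y",
    )
    base = _bbd_table(bbd_factors, {})
    errs = []
    for sigma in (1e-1, 1e-2, 1e-3):
        per_seed = []
        for seed in range(100):
            noisy = sk.simulate_design_response(
                truth, base, sk.NoiseSpec("additive-gaussian", sigma, seed)
            )
            res = sk.ResponseSurfaceModel(noisy, "y").fit()
            per_seed.append(
                np.mean(np.abs(res.params - pd.Series(truth.coefficients)))
            )
        errs.append(np.mean(per_seed))
    assert errs[0] > errs[1] > errs[2]
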