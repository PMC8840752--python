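"""ANOVA decomposition: published-table reproduction and invariants."""

import numpy as np
import pytest

import sfekin as sk


@pytest.fixture(scope="module")
def anova(table3):
    return sk.compute_anova(table3, "selectivity", order=["T", "P", "G"])


def test_degrees_of_freedom_structure(anova):
    t = anova.table
    assert t.loc["Total", "df"] == 14
    assert t.loc["Regression", "df"] + t.loc["Residual error", "df"] == 14
    assert t.loc["Lack-of-fit", "df"] == 3
    assert t.loc["Pure error", "df"] == 2


def test_published_f_statistics(anova):
    """Regression, interaction and lack-of-fit F ratios of the published
    selectivity ANOVA (printed responses are rounded to 2 decimals, so
    agreement is to ~1%)."""
    t = anova.table
    assert t.loc["Regression", "F"] == pytest.approx(5.79, abs=0.01)
    assert t.loc["P*G", "F"] == pytest.approx(12.79, rel=0.01)
    assert t.loc["T*G", "F"] == pytest.approx(7.47, rel=0.01)
    assert t.loc["Lack-of-fit", "F"] == pytest.approx(4.18, rel=0.01)
    assert t.loc["Regression", "p"] == pytest.approx(0.034, abs=2e-3)


def test_pure_error_from_center_replicates(anova):
    # center selectivities 1.83/2.11/2.17 % -> fractions .0183/.0211/.0217
    c = np.array([0.0183, 0.0211, 0.0217])
    ss = float(np.sum((c - c.mean()) ** 2))
    assert anova.table.loc["Pure error", "seq_ss"] == pytest.approx(ss, rel=1e-10)
    assert ss == pytest.approx(6.59e-6, rel=1e-3)


def test_sum_of_squares_additivity(anova):
    """Seq SS adds to the total; lack-of-fit + pure error = residual."""
    t = anova.table
    assert t.loc["Regression", "seq_ss"] + t.loc["Residual error", "seq_ss"] == (
        pytest.approx(t.loc["Total", "seq_ss"], rel=1e-10)
    )
    groups = t.loc[["Linear", "Square", "Interaction"], "seq_ss"].sum()
    assert groups == pytest.approx(t.loc["Regression", "seq_ss"], rel=1e-10)
    assert t.loc["Lack-of-fit", "seq_ss"] + t.loc["Pure error", "seq_ss"] == (
        pytest.approx(t.loc["Residual error", "seq_ss"], rel=1e-10)
    )
    assert (t["seq_ss"].dropna() >= 0).all()


def test_f_is_adj_ms_over_residual_ms(anova):
    t = anova.table
    mse = t.loc["Residual error", "adj_ms"]
    for src in ["T", "P", "G", "T*T", "P*P", "G*G", "T*P", "T*G", "P*G"]:
        assert t.loc[src, "F"] == pytest.approx(t.loc[src, "adj_ms"] / mse, rel=1e-12)


def test_seq_ss_order_sensitivity(table3):
    """Permuting the term order changes sequential SS but not adjusted SS
    or F ratios."""
    a1 = sk.compute_anova(table3, "selectivity", order=["T", "P", "G"]).table
    a2 = sk.compute_anova(table3, "selectivity", order=["G", "P", "T"]).table

    def row(t, name):  # interaction labels follow the entry order
        flipped = "*".join(reversed(name.split("*")))
        return t.loc[name] if name in t.index else t.loc[flipped]

    terms = ["T", "P", "G", "T*T", "P*P", "G*G", "T*P", "T*G", "P*G"]
    # the linear block of a Box-Behnken design is orthogonal, but the
    # square terms are not: their sequential SS shift with the entry order
    seq_shift = max(
        abs(row(a1, s)["seq_ss"] - row(a2, s)["seq_ss"]) for s in terms
    )
    assert seq_shift > 1e-7
    for src in terms:
        assert row(a1, src)["adj_ss"] == pytest.approx(
            row(a2, src)["adj_ss"], rel=1e-10
        )
        assert row(a1, src)["F"] == pytest.approx(row(a2, src)["F"], rel=1e-10)


def test_scale_invariance_of_f_and_p(table3):
    """F ratios and p-values are identical on percent and fraction scales
    while every SS scales by exactly 1e4."""
    af = sk.compute_anova(table3, "selectivity", order=["T", "P", "G"], scale="fraction").table
    ap = sk.compute_anova(table3, "selectivity", order=["T", "P", "G"], scale="percent").table
    for src in af.index:
        for col in ("F", "p"):
            x, y = af.loc[src, col], ap.loc[src, col]
            if x is None or (isinstance(x, float) and np.isnan(x)):
                continue
            assert x == pytest.approx(y, rel=1e-10)
        if not np.isnan(af.loc[src, "seq_ss"]):
            assert ap.loc[src, "seq_ss"] == pytest.approx(
                af.loc[src, "seq_ss"] * 1e4, rel=1e-10
            )


def test_no_replicates_omits_lack_of_fit(table3):
    dedup = table3.data.drop(index=[5, 14])
    t = sk.DesignTable(table3.factors, dedup, response_scale=table3.response_scale)
    with pytest.warns(UserWarning, match="no replicate"):
        a = sk.compute_anova(t, "selectivity", order=["T", "P", "G"])
    assert "Lack-of-fit" not in a.sources
    assert "Pure error" not in a.sources
    assert a.warnings


def test_ols_agrees_with_statsmodels(table3):
    """Independent cross-check: coefficients, R^2 and per-term adjusted SS
    against a statsmodels OLS on the same natural-unit basis."""
    import statsmodels.formula.api as smf

    df = table3.data.rename(columns={"selectivity": "y"}).reset_index()
    df["y"] = df["y"] / 100.0
    formula = (
        "y ~ T + P + G + I(T**2) + I(P**2) + I(G**2) + T:P + T:G + P:G"
    )
    sm_fit = smf.ols(formula, data=df).fit()
    ours = sk.ResponseSurfaceModel(table3, "selectivity", scale="fraction").fit()
    assert ours.rsquared == pytest.approx(sm_fit.rsquared, rel=1e-10)
    mapping = {  # model params follow the table's P,T,G factor order
        "const": "Intercept", "T": "T", "P": "P", "G": "G",
        "T*T": "I(T ** 2)", "P*P": "I(P ** 2)", "G*G": "I(G ** 2)",
        "P*T": "T:P", "T*G": "T:G", "P*G": "P:G",
    }
    for term, sm_term in mapping.items():
        assert ours.params[term] == pytest.approx(
            sm_fit.params[sm_term], rel=1e-8, abs=1e-14
        )
    # adjusted (Type III) single-df F equals the square of the t statistic
    a = sk.compute_anova(table3, "selectivity", order=["T", "P", "G"]).table
    for term, sm_term in mapping.items():
        if term == "const":
            continue
        flipped = "*".join(reversed(term.split("*")))
        label = term if term in a.index else flipped
        assert a.loc[label, "F"] == pytest.approx(
            sm_fit.tvalues[sm_term] ** 2, rel=1e-8
        )


def test_anova_csv_round_trip(anova, tmp_path):
    import pandas as pd

    path = tmp_path / "anova.csv"
    anova.to_csv(path)
    back = pd.read_csv(path, index_col="Source")
    assert back.loc["Regression", "DF"] == 9
    assert back.loc["Total", "SeqSS"] == pytest.approx(
        anova.table.loc["Total", "seq_ss"]
    )
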