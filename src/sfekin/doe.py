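"""Design-of-experiments: factorial / Box–Behnken tables, response-surface
OLS fits, Minitab-style ANOVA, and exact constrained maximization.

The modelling API follows the statsmodels convention: a
:class:`ResponseSurfaceModel` is built from a :class:`DesignTable` and a
response name, ``fit()`` returns a :class:`ResponseSurfaceResults` carrying
the coefficient estimates, goodness of fit, the ANOVA decomposition and the
box-constrained optimizer.

Two coefficient bases are supported.  ``scale="natural"`` (the default)
regresses on the factors in their measurement units, which is what the
source study's uncoded quadratic uses; ``scale="coded"`` first maps each
declared level onto {-1, 0, +1}.  For evenly spaced levels the two bases
span the same model; for unevenly spaced levels (such as a 42/60/150 mesh
particle-size factor) they do not, and the natural basis is the one that
reproduces the published ANOVA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignError",
    "Factor",
    "DesignTable",
    "QuadraticSurface",
    "AnovaTable",
    "OptimizationResult",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "TwoLevelFactorialModel",
    "TwoLevelFactorialResults",
    "encode_factors",
    "decode_factors",
    "optimize_quadratic_over_box",
]

_LEVEL_ATOL = 1e-9


class DesignError(ValueError):
    """Raised when a design table violates its structural requirements."""


@dataclass(frozen=True)
class Factor:
    """A three-level experimental factor.

    ``low``/``center``/``high`` are the declared levels in natural units;
    coding maps them onto -1/0/+1.  A categorical factor already expressed
    on the coded scale (e.g. a cosolvent series water / 1:1 mix / ethanol
    stored as -1/0/+1) uses ``kind="categorical-as-coded"``.
    """

    name: str
    low: float
    center: float
    high: float
    unit: str = ""
    kind: str = "continuous"  # or "categorical-as-coded"

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise DesignError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )

    @property
    def levels(self) -> tuple[float, float, float]:
        return (self.low, self.center, self.high)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.low, self.high)

    def code(self, value: float) -> float:
        """Map a declared level onto {-1, 0, +1}."""
        for coded, level in zip((-1.0, 0.0, 1.0), self.levels):
            if abs(value - level) <= _LEVEL_ATOL * max(1.0, abs(level)):
                return coded
        raise DesignError(
            f"factor {self.name!r}: {value} is not one of the declared levels "
            f"{self.levels}"
        )

    def decode(self, coded: float) -> float:
        for c, level in zip((-1.0, 0.0, 1.0), self.levels):
            if abs(coded - c) <= _LEVEL_ATOL:
                return level
        raise DesignError(f"factor {self.name!r}: {coded} is not a coded level")


@dataclass
class DesignTable:
    """Runs x factors x responses of an experimental design.

    ``data`` is indexed by run id and holds one column per factor (natural
    units unless ``coded``) and per response.  ``response_scale`` maps each
    response name to ``"percent"`` or ``"fraction"``.
    """

    factors: list[Factor]
    data: pd.DataFrame
    response_scale: dict[str, str] = field(default_factory=dict)
    coded: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        missing = [f.name for f in self.factors if f.name not in self.data.columns]
        if missing:
            raise DesignError(f"factor columns missing from data: {missing}")
        for resp in self.response_names:
            col = pd.to_numeric(self.data[resp], errors="coerce")
            dropped = self.data.index[col.isna()]
            if len(dropped):
                warnings.warn(
                    f"response {resp!r}: dropping runs with missing values: "
                    f"{list(dropped)}",
                    stacklevel=2,
                )
                self.data = self.data.drop(index=dropped)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def response_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.factor_names]

    @property
    def n_runs(self) -> int:
        return len(self.data)

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self) -> None:
        """Every run's setting must equal a declared factor level."""
        for f in self.factors:
            levels = (-1.0, 0.0, 1.0) if self.coded else f.levels
            col = self.data[f.name].to_numpy(dtype=float)
            for run_id, v in zip(self.data.index, col):
                if not any(
                    abs(v - lv) <= _LEVEL_ATOL * max(1.0, abs(lv)) for lv in levels
                ):
                    raise DesignError(
                        f"run {run_id!r}: factor {f.name!r} setting {v} is not a "
                        f"declared level {tuple(levels)}"
                    )

    def replicate_groups(self) -> list[np.ndarray]:
        """Index groups of runs with identical factor settings."""
        grouped = self.data.groupby(self.factor_names, sort=False).indices
        return [np.asarray(ix) for ix in grouped.values()]

    @property
    def pure_error_df(self) -> int:
        return sum(len(g) - 1 for g in self.replicate_groups())

    # -- scales ------------------------------------------------------------

    def response_on_scale(self, response: str, scale: str) -> np.ndarray:
        y = self.data[response].to_numpy(dtype=float)
        have = self.response_scale.get(response, "percent")
        if have == scale:
            return y
        if (have, scale) == ("percent", "fraction"):
            return y / 100.0
        if (have, scale) == ("fraction", "percent"):
            return y * 100.0
        raise ValueError(f"unknown response scale conversion {have!r} -> {scale!r}")

    def with_response_scale(self, response: str, scale: str) -> "DesignTable":
        out = replace(self, data=self.data.copy())
        out.data[response] = self.response_on_scale(response, scale)
        out.response_scale = {**self.response_scale, response: scale}
        return out


def encode_factors(table: DesignTable) -> DesignTable:
    """Map every factor setting onto the coded {-1, 0, +1} scale."""
    if table.coded:
        return table
    data = table.data.copy()
    for f in table.factors:
        data[f.name] = [f.code(v) for v in data[f.name].to_numpy(dtype=float)]
    return replace(table, data=data, coded=True)


def decode_factors(table: DesignTable) -> DesignTable:
    """Inverse of :func:`encode_factors`; exact on declared levels."""
    if not table.coded:
        return table
    data = table.data.copy()
    for f in table.factors:
        data[f.name] = [f.decode(v) for v in data[f.name].to_numpy(dtype=float)]
    return replace(table, data=data, coded=False)


# ---------------------------------------------------------------------------
# Quadratic surface
# ---------------------------------------------------------------------------


def _pair_name(a: str, b: str) -> str:
    return f"{a}*{b}"


def full_quadratic_terms(factor_names: list[str]) -> list[str]:
    """Term order: intercept, linear, squares, interactions."""
    k = factor_names
    terms = ["const"] + list(k)
    terms += [_pair_name(f, f) for f in k]
    terms += [_pair_name(a, b) for a, b in itertools.combinations(k, 2)]
    return terms


def _term_column(term: str, cols: dict[str, np.ndarray]) -> np.ndarray:
    if term == "const":
        return np.ones_like(next(iter(cols.values())))
    if "*" in term:
        a, b = term.split("*")
        return cols[a] * cols[b]
    return cols[term]


@dataclass
class QuadraticSurface:
    """Full second-order polynomial in k factors.

    Coefficients are stored as a term -> value mapping over the basis
    ``{1, x_i, x_i^2, x_i x_j}``; one value per unordered pair.
    """

    factor_names: list[str]
    coefficients: dict[str, float]
    factor_scale: str = "natural"  # or "coded"
    response_scale: str = "percent"  # or "fraction"
    response_name: str = "response"
    factors: list[Factor] | None = None  # optional box metadata

    @property
    def intercept(self) -> float:
        return self.coefficients.get("const", 0.0)

    @property
    def linear(self) -> dict[str, float]:
        return {f: self.coefficients.get(f, 0.0) for f in self.factor_names}

    @property
    def quadratic(self) -> dict[str, float]:
        return {
            f: self.coefficients.get(_pair_name(f, f), 0.0)
            for f in self.factor_names
        }

    @property
    def interaction(self) -> dict[tuple[str, str], float]:
        out = {}
        for a, b in itertools.combinations(self.factor_names, 2):
            out[(a, b)] = self.coefficients.get(_pair_name(a, b), 0.0)
        return out

    def _point_array(self, point) -> np.ndarray:
        if isinstance(point, dict):
            return np.array([point[f] for f in self.factor_names], dtype=float)
        x = np.asarray(point, dtype=float)
        if x.shape[-1] != len(self.factor_names):
            raise ValueError(
                f"point has dimension {x.shape[-1]}, surface has "
                f"{len(self.factor_names)} factors"
            )
        return x

    def __call__(self, point):
        return self.evaluate(point)

    def evaluate(self, point):
        """Evaluate the polynomial at one point or an (..., k) array."""
        x = self._point_array(point)
        val = np.full(x.shape[:-1], self.intercept, dtype=float)
        for i, f in enumerate(self.factor_names):
            xi = x[..., i]
            val += self.linear[f] * xi + self.quadratic[f] * xi * xi
        for (a, b), c in self.interaction.items():
            ia, ib = self.factor_names.index(a), self.factor_names.index(b)
            val += c * x[..., ia] * x[..., ib]
        if val.ndim == 0:
            return float(val)
        return val

    def predict(self, point, *, warn_extrapolation: bool = True):
        """Evaluate with an extrapolation warning outside the factor box."""
        if warn_extrapolation and self.factors is not None:
            x = np.atleast_2d(self._point_array(point))
            for i, f in enumerate(self.factors):
                lo, hi = (-1.0, 1.0) if self.factor_scale == "coded" else f.bounds
                if np.any(x[:, i] < lo - _LEVEL_ATOL) or np.any(
                    x[:, i] > hi + _LEVEL_ATOL
                ):
                    warnings.warn(
                        f"predicting outside the experimental range of "
                        f"{f.name!r} [{lo}, {hi}]",
                        stacklevel=2,
                    )
        return self.evaluate(point)

    def on_response_scale(self, scale: str) -> "QuadraticSurface":
        """Percent <-> fraction response rescaling (x100 exactly)."""
        if scale == self.response_scale:
            return self
        if {scale, self.response_scale} != {"percent", "fraction"}:
            raise ValueError(f"unknown response scale {scale!r}")
        fac = 100.0 if scale == "percent" else 0.01
        return replace(
            self,
            coefficients={t: c * fac for t, c in self.coefficients.items()},
            response_scale=scale,
        )

    def as_series(self) -> pd.Series:
        terms = full_quadratic_terms(self.factor_names)
        return pd.Series({t: self.coefficients.get(t, 0.0) for t in terms})


# ---------------------------------------------------------------------------
# OLS engine
# ---------------------------------------------------------------------------


def _design_matrix(
    table: DesignTable, terms: list[str]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    cols = {
        f.name: table.data[f.name].to_numpy(dtype=float) for f in table.factors
    }
    X = np.column_stack([_term_column(t, cols) for t in terms])
    return X, cols


def _ols(X: np.ndarray, y: np.ndarray, terms: list[str]) -> tuple[np.ndarray, float]:
    n, p = X.shape
    if n < p:
        raise DesignError(
            f"{n} runs cannot identify {p} parameters ({terms}); need n >= p"
        )
    # scale columns for a meaningful rank check on natural-unit bases
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0.0] = 1.0
    rank = np.linalg.matrix_rank(X / norms, tol=1e-8)
    if rank < p:
        from scipy.linalg import qr

        _, _, piv = qr(X / norms, pivoting=True)
        collinear = [terms[j] for j in sorted(piv[rank:])]
        raise DesignError(f"design matrix is rank deficient; collinear terms: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ beta) ** 2))
    return beta, sse


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Minitab-style source / df / SeqSS / AdjSS / AdjMS / F / p table."""

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def sources(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        out = self.table.rename(
            columns={
                "df": "DF",
                "seq_ss": "SeqSS",
                "adj_ss": "AdjSS",
                "adj_ms": "AdjMS",
                "F": "F",
                "p": "p",
            }
        )
        out.to_csv(path, index_label="Source")

    def __str__(self) -> str:
        with pd.option_context("display.float_format", lambda v: f"{v:.6g}"):
            return f"Analysis of Variance\n{self.table.to_string()}"


def _seq_ss(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Type I sums of squares for columns 2..p (column 1 is the intercept)."""
    n, p = X.shape
    out = np.empty(p - 1)
    prev = float(np.sum((y - y.mean()) ** 2))
    for j in range(2, p + 1):
        b, _, _, _ = np.linalg.lstsq(X[:, :j], y, rcond=None)
        sse = float(np.sum((y - X[:, :j] @ b) ** 2))
        out[j - 2] = prev - sse
        prev = sse
    return out


def _adj_ss(X: np.ndarray, y: np.ndarray, sse_full: float, drop: list[int]) -> float:
    keep = [j for j in range(X.shape[1]) if j not in drop]
    b, _, _, _ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    return float(np.sum((y - X[:, keep] @ b) ** 2)) - sse_full


def _f_p(adj_ss: float, df: int, mse: float, df_resid: int):
    if df <= 0 or mse <= 0.0:
        return None, None
    f = (adj_ss / df) / mse
    return f, float(stats.f.sf(f, df, df_resid))


def compute_anova(
    table: DesignTable,
    response: str,
    order: list[str] | None = None,
    scale: str = "fraction",
) -> AnovaTable:
    """Full-quadratic ANOVA with sequential and adjusted SS.

    ``order`` gives the linear-term entry order for the sequential SS;
    squares then pairwise interactions follow in the induced order.  SS are
    computed on the requested response scale (fraction by default, where a
    percent response's SS shrink by 1e4); F ratios and p-values are
    invariant to that choice.
    """
    if order is None:
        order = table.meta.get("anova_order") or table.factor_names
    if sorted(order) != sorted(table.factor_names):
        raise ValueError(f"order {order} must permute factors {table.factor_names}")
    lin = list(order)
    sq = [_pair_name(f, f) for f in lin]
    inter = [_pair_name(a, b) for a, b in itertools.combinations(lin, 2)]
    terms = ["const"] + lin + sq + inter

    y = table.response_on_scale(response, scale)
    X, _ = _design_matrix(table, terms)
    beta, sse = _ols(X, y, terms)
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom for ANOVA")
    mse = sse / df_resid
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = sst - sse

    seq = dict(zip(terms[1:], _seq_ss(X, y)))
    adj = {
        t: _adj_ss(X, y, sse, [terms.index(t)]) for t in terms[1:]
    }
    groups = {"Linear": lin, "Square": sq, "Interaction": inter}

    rows: list[dict] = []

    def add(source, df, seq_ss_v, adj_ss_v, with_f=True):
        adj_ms = adj_ss_v / df if df > 0 else None
        f, pv = _f_p(adj_ss_v, df, mse, df_resid) if with_f else (None, None)
        rows.append(
            dict(source=source, df=df, seq_ss=seq_ss_v, adj_ss=adj_ss_v,
                 adj_ms=adj_ms, F=f, p=pv)
        )

    add("Regression", p - 1, ssr, ssr)
    for gname, gterms in groups.items():
        g_seq = sum(seq[t] for t in gterms)
        g_adj = _adj_ss(X, y, sse, [terms.index(t) for t in gterms])
        add(gname, len(gterms), g_seq, g_adj)
        for t in gterms:
            add(t, 1, seq[t], adj[t])
    rows.append(
        dict(source="Residual error", df=df_resid, seq_ss=sse, adj_ss=sse,
             adj_ms=mse, F=None, p=None)
    )

    warn: list[str] = []
    df_pe = table.pure_error_df
    if df_pe > 0:
        ss_pe = 0.0
        for g in table.replicate_groups():
            if len(g) > 1:
                yy = y[g]
                ss_pe += float(np.sum((yy - yy.mean()) ** 2))
        ss_lof = sse - ss_pe
        df_lof = df_resid - df_pe
        if df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = None, None
        rows.append(
            dict(source="Lack-of-fit", df=df_lof, seq_ss=ss_lof, adj_ss=ss_lof,
                 adj_ms=ss_lof / df_lof if df_lof > 0 else None, F=f_lof, p=p_lof)
        )
        rows.append(
            dict(source="Pure error", df=df_pe, seq_ss=ss_pe, adj_ss=ss_pe,
                 adj_ms=ss_pe / df_pe, F=None, p=None)
        )
    else:
        warn.append("no replicate runs: lack-of-fit and pure-error rows omitted")
        warnings.warn(warn[-1], stacklevel=2)
    rows.append(
        dict(source="Total", df=n - 1, seq_ss=sst, adj_ss=None, adj_ms=None,
             F=None, p=None)
    )
    df = pd.DataFrame(rows).set_index("source")
    return AnovaTable(df, warnings=warn)


# ---------------------------------------------------------------------------
# Box-constrained maximization of a quadratic (exact face enumeration)
# ---------------------------------------------------------------------------


@dataclass
class OptimizationResult:
    argmax: dict[str, float]
    predicted_response: float
    active_bounds: dict[str, str]  # at-lower | at-upper | interior
    is_stationary_interior: bool
    candidates: list[tuple[dict[str, float], float]] = field(default_factory=list)
    ties: list[dict[str, float]] = field(default_factory=list)


def optimize_quadratic_over_box(
    surface: QuadraticSurface,
    bounds: dict[str, tuple[float, float]] | None = None,
    tie_tol: float = 1e-9,
) -> OptimizationResult:
    """Global maximum of a quadratic over a box, by exact face enumeration.

    Every face of the box restricts the quadratic to a lower-dimensional
    quadratic whose stationary point is a linear solve; comparing all such
    candidates (plus the vertices) yields the exact constrained maximum —
    no iterative search.  Ties within ``tie_tol`` (relative) are all
    reported, sorted so the lowest first-factor value comes first.
    """
    names = surface.factor_names
    k = len(names)
    if bounds is None:
        if surface.factors is None:
            raise ValueError("no bounds given and surface carries no factor box")
        bounds = {f.name: f.bounds for f in surface.factors}
    missing = [f for f in names if f not in bounds]
    if missing:
        raise ValueError(f"bounds missing for factors {missing}")
    lo = np.array([bounds[f][0] for f in names], dtype=float)
    hi = np.array([bounds[f][1] for f in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite for exact box maximization")
    if np.any(lo > hi):
        raise ValueError("lower bound exceeds upper bound")

    # gradient g and Hessian M of f(x) = c + g.x + x.(M/2).x
    g = np.array([surface.linear[f] for f in names])
    M = np.zeros((k, k))
    for i, f in enumerate(names):
        M[i, i] = 2.0 * surface.quadratic[f]
    for (a, b), c in surface.interaction.items():
        ia, ib = names.index(a), names.index(b)
        M[ia, ib] = M[ib, ia] = c

    candidates: list[tuple[np.ndarray, float, bool]] = []
    for assign in itertools.product((0, 1, 2), repeat=k):  # lo, hi, free
        free = [i for i, a in enumerate(assign) if a == 2]
        x = np.where(np.array(assign) == 0, lo, hi).astype(float)
        if free:
            F = np.array(free)
            Fx = np.array([i for i in range(k) if i not in free], dtype=int)
            rhs = -(g[F] + (M[np.ix_(F, Fx)] @ x[Fx] if len(Fx) else 0.0))
            sub = M[np.ix_(F, F)]
            try:
                xf = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                continue  # degenerate face: its max lies on an enumerated subface
            if not np.all(np.isfinite(xf)):
                continue
            if np.any(xf < lo[F]) or np.any(xf > hi[F]):
                continue
            x[F] = xf
        val = surface.evaluate(x)
        candidates.append((x, val, len(free) == k))

    best_val = max(v for _, v, _ in candidates)
    tol = tie_tol * max(1.0, abs(best_val))
    ties = [(x, v, interior) for x, v, interior in candidates if best_val - v <= tol]
    # lowest first-factor (e.g. pressure) first among ties
    ties.sort(key=lambda t: tuple(t[0]))
    # de-duplicate coincident points
    uniq: list[tuple[np.ndarray, float, bool]] = []
    for x, v, inter in ties:
        if not any(np.allclose(x, u[0], atol=1e-9) for u in uniq):
            uniq.append((x, v, inter))
    x_best, val_best, interior = uniq[0]

    active = {}
    for i, f in enumerate(names):
        if abs(x_best[i] - lo[i]) <= 1e-12 * max(1.0, abs(lo[i])):
            active[f] = "at-lower"
        elif abs(x_best[i] - hi[i]) <= 1e-12 * max(1.0, abs(hi[i])):
            active[f] = "at-upper"
        else:
            active[f] = "interior"

    return OptimizationResult(
        argmax=dict(zip(names, (float(v) for v in x_best))),
        predicted_response=float(val_best),
        active_bounds=active,
        is_stationary_interior=bool(interior),
        candidates=[(dict(zip(names, map(float, x))), float(v)) for x, v, _ in candidates],
        ties=[dict(zip(names, map(float, x))) for x, _, _ in uniq],
    )


# ---------------------------------------------------------------------------
# Models / Results
# ---------------------------------------------------------------------------


class ResponseSurfaceModel:
    """Full second-order response-surface model for a design table.

    Parameters
    ----------
    table : DesignTable
        The design with the response column to model.
    response : str
        Response name.
    scale : {"percent", "fraction"}, optional
        Response scale to fit on; defaults to the scale stored in the table.
    coded : bool
        Fit on coded {-1, 0, +1} regressors instead of natural units.
    """

    def __init__(
        self,
        table: DesignTable,
        response: str,
        scale: str | None = None,
        coded: bool = False,
    ) -> None:
        if response not in table.response_names:
            raise KeyError(f"response {response!r} not in {table.response_names}")
        self.table = encode_factors(table) if (coded and not table.coded) else table
        self.response = response
        self.scale = scale or table.response_scale.get(response, "percent")
        self.terms = full_quadratic_terms(table.factor_names)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        factors: list[Factor],
        response: str,
        response_scale: str = "percent",
        **kwargs,
    ) -> "ResponseSurfaceModel":
        table = DesignTable(factors, data, response_scale={response: response_scale})
        return cls(table, response, **kwargs)

    def fit(self) -> "ResponseSurfaceResults":
        y = self.table.response_on_scale(self.response, self.scale)
        X, _ = self._xy()
        beta, sse = _ols(X, y, self.terms)
        return ResponseSurfaceResults(self, np.asarray(beta), X, y, sse)

    def _xy(self):
        return _design_matrix(self.table, self.terms)


class ResponseSurfaceResults:
    """OLS results for a fitted quadratic response surface."""

    def __init__(self, model, beta, X, y, sse) -> None:
        self.model = model
        self.params = pd.Series(beta, index=model.terms)
        self._X = X
        self._y = y
        self.sse = sse
        self.sst = float(np.sum((y - y.mean()) ** 2))
        self.nobs = len(y)
        self.df_resid = self.nobs - len(beta)

    @property
    def rsquared(self) -> float:
        return 1.0 - self.sse / self.sst

    @property
    def rsquared_adj(self) -> float:
        n, p = self.nobs, len(self.params)
        return 1.0 - (self.sse / (n - p)) / (self.sst / (n - 1))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._X @ self.params.to_numpy()

    @property
    def resid(self) -> np.ndarray:
        return self._y - self.fittedvalues

    @property
    def surface(self) -> QuadraticSurface:
        m = self.model
        return QuadraticSurface(
            factor_names=m.table.factor_names,
            coefficients=dict(self.params),
            factor_scale="coded" if m.table.coded else "natural",
            response_scale=m.scale,
            response_name=m.response,
            factors=m.table.factors,
        )

    def predict(self, point, **kw):
        return self.surface.predict(point, **kw)

    def anova(self, order: list[str] | None = None, scale: str = "fraction") -> AnovaTable:
        return compute_anova(self.model.table, self.model.response, order, scale)

    def maximize(
        self, bounds: dict[str, tuple[float, float]] | None = None, **kw
    ) -> OptimizationResult:
        return optimize_quadratic_over_box(self.surface, bounds, **kw)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Response surface OLS: {m.response} ({m.scale} scale, "
            f"{'coded' if m.table.coded else 'natural'} units)",
            f"n runs = {self.nobs}, residual df = {self.df_resid}",
            f"R^2 = {self.rsquared:.4f}   adj R^2 = {self.rsquared_adj:.4f}",
            "",
            "coefficients:",
        ]
        for t, c in self.params.items():
            lines.append(f"  {t:>8s}  {c: .6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Two-level factorial with center points
# ---------------------------------------------------------------------------


class TwoLevelFactorialModel:
    """2^2 factorial fit on coded factors: {1, A, B, AB} plus an optional
    center-point curvature term.

    With the curvature term, the intercept stays the corner mean and the
    curvature estimate is mean(center) - mean(corners); effects are twice
    the coded coefficients.
    """

    def __init__(
        self, table: DesignTable, response: str, center_point_term: bool = False
    ) -> None:
        if response not in table.response_names:
            raise KeyError(f"response {response!r} not in {table.response_names}")
        if len(table.factors) != 2:
            raise DesignError("two-level factorial model requires exactly 2 factors")
        self.table = encode_factors(table)
        self.response = response
        self.center_point_term = center_point_term

    def fit(self) -> "TwoLevelFactorialResults":
        t = self.table
        a, b = t.factor_names
        A = t.data[a].to_numpy(dtype=float)
        B = t.data[b].to_numpy(dtype=float)
        y = t.data[self.response].to_numpy(dtype=float)
        is_center = (A == 0.0) & (B == 0.0)
        terms = ["const", a, b, _pair_name(a, b)]
        cols = [np.ones_like(A), A, B, A * B]
        if self.center_point_term:
            if not is_center.any():
                raise DesignError("center-point term requested but design has no center runs")
            terms.append("ctr")
            cols.append(is_center.astype(float))
        X = np.column_stack(cols)
        beta, sse = _ols(X, y, terms)
        return TwoLevelFactorialResults(self, dict(zip(terms, beta)), X, y, sse)


class TwoLevelFactorialResults:
    def __init__(self, model, params, X, y, sse) -> None:
        self.model = model
        self.params = pd.Series(params)
        self._y = y
        self.sse = sse
        self.sst = float(np.sum((y - y.mean()) ** 2))
        self.nobs = len(y)

    @property
    def rsquared(self) -> float:
        return 1.0 - self.sse / self.sst if self.sst > 0 else 1.0

    @property
    def curvature(self) -> float | None:
        """mean(center) - mean(corners), when the center term was fitted."""
        return float(self.params["ctr"]) if "ctr" in self.params else None

    @property
    def effects(self) -> dict[str, float]:
        """Classical factorial effects: twice the coded coefficients."""
        return {
            t: 2.0 * float(c)
            for t, c in self.params.items()
            if t not in ("const", "ctr")
        }

    @property
    def surface(self) -> QuadraticSurface:
        m = self.model
        coeffs = {t: float(c) for t, c in self.params.items() if t != "ctr"}
        return QuadraticSurface(
            factor_names=m.table.factor_names,
            coefficients=coeffs,
            factor_scale="coded",
            response_scale=m.table.response_scale.get(m.response, "percent"),
            response_name=m.response,
            factors=m.table.factors,
        )

    def summary(self) -> str:
        lines = [
            f"2-level factorial fit: {self.model.response} (coded units)",
            f"n runs = {self.nobs}, R^2 = {self.rsquared:.4f}",
            "coefficients:",
        ]
        for t, c in self.params.items():
            lines.append(f"  {t:>6s}  {c: .6g}")
        for t, e in self.effects.items():
            lines.append(f"  effect({t}) = {e:.6g}")
        if self.curvature is not None:
            lines.append(f"  curvature (center - corners) = {self.curvature:.6g}")
        return "\n".join(lines)
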