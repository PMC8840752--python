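"""Sovova's broken-and-intact-cells model of supercritical extraction.

The solid bed holds an easily accessible solute fraction (cell walls
broken by milling; extraction limited by the fluid film) and an
inaccessible fraction (intact cells; limited by diffusion in the solid).
With q the cumulative specific solvent consumption (solvent mass passed
per insoluble-solid mass) the cumulative extract per insoluble solid, e,
follows three periods:

  1. q < qm   (constant-rate, film-limited):  e = q yr [1 - exp(-Z)]
  2. qm <= q < qn (the broken-cell solute depletes from bed inlet to
     outlet):                                 e = yr [q - qm exp(zw - Z)]
  3. q >= qn  (only intact-cell solute left):
       e = x0 - (yr/W) ln{1 + [exp(W x0/yr) - 1] exp(W (qm - q)) xk/x0}

with transition points

  qm = (x0 - xk) / (yr Z)
  qn = qm + (1/W) ln[(xk + (x0 - xk) exp(W x0 / yr)) / x0]

and the moving-boundary coordinate zw given by

  zw/Z = yr/(W x0) * ln{[x0 exp(W (q - qm)) - xk] / (x0 - xk)}.

Z and W are the dimensionless fast- and slow-period parameters, each
directly proportional to the film and solid mass-transfer coefficients
(kf, ks); yr is the solubility and xk the inaccessible solute loading,
both on the same solute-per-insoluble-solid basis as x0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import BedProperties

__all__ = [
    "SovovaParameters",
    "sovova_transitions",
    "sovova_yield",
    "sovova_phase_coefficients",
    "sovova_zw",
]


@dataclass(frozen=True)
class SovovaParameters:
    """Parameters of the three-period model (all dimensionless except the
    loadings, which share the solute-per-insoluble-solid basis)."""

    x0: float  # total initial solute loading
    xk: float  # inaccessible (intact-cell) loading, 0 <= xk <= x0
    yr: float  # solubility
    Z: float  # fast-period (film) parameter
    W: float  # slow-period (solid) parameter

    def __post_init__(self) -> None:
        if not (0.0 <= self.xk <= self.x0):
            raise ValueError(f"need 0 <= xk <= x0, got xk={self.xk}, x0={self.x0}")
        if self.x0 <= 0:
            raise ValueError("x0 must be > 0")
        if self.yr <= 0 or self.Z <= 0 or self.W <= 0:
            raise ValueError("yr, Z, W must all be > 0")

    @property
    def qm(self) -> float:
        return sovova_transitions(self)[0]

    @property
    def qn(self) -> float:
        return sovova_transitions(self)[1]


def sovova_transitions(params: SovovaParameters) -> tuple[float, float]:
    """Transition points (qm, qn) of the three periods.

    Degenerate limits: xk = 0 collapses the intermediate period
    (qn = qm); xk = x0 removes the accessible solute (qm = 0).
    """
    x0, xk, yr, Z, W = params.x0, params.xk, params.yr, params.Z, params.W
    qm = (x0 - xk) / (yr * Z)
    a = W * x0 / yr
    # log(xk + (x0 - xk) e^a) in overflow-safe form
    log_num = np.logaddexp(
        np.log(xk) if xk > 0 else -np.inf, a + np.log(x0 - xk) if xk < x0 else -np.inf
    )
    qn = qm + (log_num - np.log(x0)) / W
    if qn < qm:  # cannot happen for valid parameters; guard the evaluator
        raise ValueError(f"invalid parameters: qn={qn} < qm={qm}")
    return float(qm), float(qn)


def sovova_zw(q, params: SovovaParameters):
    """Moving-boundary coordinate zw inside the second period."""
    x0, xk, yr, W = params.x0, params.xk, params.yr, params.W
    qm = params.qm
    q = np.asarray(q, dtype=float)
    b = W * (q - qm)
    # log(x0 e^b - xk) = b + log(x0 - xk e^-b), stable for the large b the
    # search can visit; the shifted argument is positive whenever q >= qm
    shifted = x0 - xk * np.exp(-b)
    if np.any(shifted <= 0):
        raise ValueError(
            "zw logarithm argument is non-positive; parameters are outside "
            "the model's validity region"
        )
    log_arg = b + np.log(shifted) - np.log(x0 - xk)
    return params.Z * (yr / (W * x0)) * log_arg


def sovova_yield(q, params: SovovaParameters):
    """Cumulative extract per insoluble solid, e(q).

    Piecewise over the three periods (left-closed intervals); continuous
    and nondecreasing in q, bounded by x0.  Vectorized over q.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    x0, xk, yr, Z, W = params.x0, params.xk, params.yr, params.Z, params.W
    qm, qn = sovova_transitions(params)

    e = np.empty_like(q)
    p1 = q < qm
    p2 = (q >= qm) & (q < qn)
    p3 = q >= qn

    e[p1] = q[p1] * yr * (1.0 - np.exp(-Z))
    if np.any(p2):
        zw = sovova_zw(q[p2], params)
        e[p2] = yr * (q[p2] - qm * np.exp(zw - Z))
    if np.any(p3):
        if xk == 0.0:
            e[p3] = x0
        else:
            # [exp(a) - 1] exp(-c) = exp(a - c) - exp(-c), with a - c bounded
            # above by log(x0/(x0-xk)) for q >= qn: overflow-safe
            a = W * x0 / yr
            c = W * (q[p3] - qm)
            term = (np.exp(a - c) - np.exp(-c)) * (xk / x0)
            e[p3] = x0 - (yr / W) * np.log1p(term)
    return float(e[0]) if scalar else e


def sovova_phase_coefficients(
    Z: float, W: float, bed: BedProperties
) -> tuple[float, float]:
    """Fluid- and solid-phase mass-transfer coefficients (kf, ks) implied
    by fitted Z and W:

        Z = kf a0 rho / (qdot (1 - eps) rho_s)   =>  kf = Z qdot (1-eps) rho_s / (a0 rho)
        W = ks a0 / (qdot (1 - eps))             =>  ks = W qdot (1-eps) / a0
    """
    bed.require(
        "specific_flow", "porosity", "solid_density", "specific_area",
        "fluid_density",
    )
    eps = bed.porosity
    kf = Z * bed.specific_flow * (1.0 - eps) * bed.solid_density / (
        bed.specific_area * bed.fluid_density
    )
    ks = W * bed.specific_flow * (1.0 - eps) / bed.specific_area
    return float(kf), float(ks)


def sovova_phase_parameters(
    kf: float, ks: float, bed: BedProperties
) -> tuple[float, float]:
    """Inverse of :func:`sovova_phase_coefficients`: (Z, W) from (kf, ks)."""
    bed.require(
        "specific_flow", "porosity", "solid_density", "specific_area",
        "fluid_density",
    )
    eps = bed.porosity
    Z = kf * bed.specific_area * bed.fluid_density / (
        bed.specific_flow * (1.0 - eps) * bed.solid_density
    )
    W = ks * bed.specific_area / (bed.specific_flow * (1.0 - eps))
    return float(Z), float(W)
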