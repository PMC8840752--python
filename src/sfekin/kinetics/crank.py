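"""Fickian diffusion out of a sphere with constant surface concentration.

The cumulative fraction extracted is the classical series

    M_t / M_inf = 1 - (6/pi^2) * sum_{n>=1} n^-2 exp(-D n^2 pi^2 t / r^2),

a function of the Fourier number Fo = D t / r^2 alone.  The series is
summed adaptively: terms are added until the next term falls below the
requested tolerance (they decrease monotonically in n for t > 0), with a
hard cap on the number of terms.  No short-time approximation is
substituted at small Fo; a warning is emitted instead because convergence
is slow there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .base import ParticleGeometry

__all__ = ["CrankParameters", "crank_extraction_fraction", "crank_profile"]

_SLOW_FO = 1e-4
_MAX_TERMS = 100_000


@dataclass(frozen=True)
class CrankParameters:
    """Sphere-diffusion parameters: internal diffusivity and geometry."""

    diffusivity: float  # D, m2/s
    geometry: ParticleGeometry
    series_tol: float = 1e-12
    max_terms: int = _MAX_TERMS

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be > 0")


def crank_extraction_fraction(
    t,
    params: CrankParameters | None = None,
    *,
    diffusivity: float | None = None,
    radius: float | None = None,
    series_tol: float = 1e-12,
    max_terms: int = _MAX_TERMS,
):
    """Normalized cumulative yield M_t/M_inf at time(s) ``t`` (seconds).

    Accepts either a :class:`CrankParameters` or explicit
    ``diffusivity``/``radius``.  Vectorized over ``t``; returns values in
    [0, 1].
    """
    if params is not None:
        D = params.diffusivity
        r = params.geometry.radius
        series_tol = params.series_tol
        max_terms = params.max_terms
    else:
        if diffusivity is None or radius is None:
            raise ValueError("give either params or diffusivity and radius")
        D, r = diffusivity, radius
    if D <= 0 or r <= 0:
        raise ValueError("diffusivity and radius must be > 0")

    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")

    fo = D * t / r**2
    pos = fo > 0
    if np.any((fo > 0) & (fo < _SLOW_FO)):
        warnings.warn(
            f"Fourier number below {_SLOW_FO:g}: the sphere-diffusion series "
            "converges slowly there",
            stacklevel=2,
        )

    out = np.zeros_like(t)
    if np.any(pos):
        x = np.pi**2 * fo[pos]  # exponent scale per term: n^2 * x
        s = np.zeros_like(x)
        active = np.ones_like(x, dtype=bool)
        for n in range(1, max_terms + 1):
            term = np.exp(-(n * n) * x[active]) / (n * n)
            s_active = s[active]
            s_active += term
            s[active] = s_active
            still = term > series_tol
            if not np.any(still):
                break
            idx = np.flatnonzero(active)
            active[idx[~still]] = False
        out[pos] = 1.0 - (6.0 / np.pi**2) * s
    return np.clip(out, 0.0, 1.0)[0] if scalar else np.clip(out, 0.0, 1.0)


def crank_profile(times, params: CrankParameters):
    """Convenience: evaluate the model on a grid, returning an array."""
    return crank_extraction_fraction(np.asarray(times, dtype=float), params)
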