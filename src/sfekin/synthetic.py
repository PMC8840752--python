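"""Synthetic extraction curves and design responses with known ground truth.

The generator emulates the features of a real supercritical-extraction
campaign that the estimation code must cope with: monotone saturating
kinetic curves on an hours time scale (an approximately linear early
period followed by diffusion-limited tailing), a few-percent
multiplicative replicate scatter, and design-table responses that are a
quadratic surface plus independent run-level noise.  Everything is
seeded and bit-reproducible, and every simulated object is returned
together with the ground truth that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .doe import DesignTable, QuadraticSurface
from .kinetics.base import BedProperties, ExtractionCurve
from .kinetics.crank import CrankParameters, crank_extraction_fraction
from .kinetics.reverchon import ReverchonParameters, reverchon_simulate
from .kinetics.sovova import SovovaParameters, sovova_yield
from .datasets import load_fixture

__all__ = [
    "NoiseSpec",
    "default_time_grid",
    "simulate_extraction_curve",
    "simulate_design_response",
    "load_fixture",
]

NOISE_KINDS = ("additive-gaussian", "multiplicative-gaussian")


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded Gaussian noise, additive or multiplicative."""

    kind: str = "multiplicative-gaussian"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Perturb ``values``.  No clipping here: physical-range handling
        (yields cannot be negative) is the curve generator's job."""
        if self.sigma == 0.0:
            return np.array(values, dtype=float)
        rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.sigma, size=np.shape(values))
        if self.kind == "multiplicative-gaussian":
            return values * (1.0 + eps)
        return values + eps


def default_time_grid(
    horizon_s: float = 6 * 3600.0,
    n: int = 24,
    bias: float = 1.8,
    t_min_s: float = 600.0,
) -> np.ndarray:
    """Sampling times over a 6-hour run: first sample at 10 minutes, then
    power-law spacing biased toward early times, the way extraction
    curves are usually sampled."""
    i = np.arange(n, dtype=float)
    return t_min_s + (horizon_s - t_min_s) * (i / (n - 1)) ** bias


def simulate_extraction_curve(
    kind: str,
    params,
    times=None,
    noise: NoiseSpec | None = None,
    bed: BedProperties | None = None,
    n_cells: int = 50,
) -> tuple[ExtractionCurve, dict]:
    """Forward-simulate a cumulative-yield curve and perturb it.

    ``kind`` is ``"crank"`` (params: :class:`CrankParameters`; abscissa
    seconds, normalized basis), ``"sovova"`` (params:
    :class:`SovovaParameters`; abscissa is the specific solvent
    consumption q, per-solid basis) or ``"reverchon"`` (params:
    :class:`ReverchonParameters`; abscissa seconds, normalized basis,
    ``bed`` defaults to :meth:`BedProperties.default`).

    Returns the noisy curve and a ground-truth record holding the clean
    values and the generating parameters.
    """
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    if kind == "crank":
        if not isinstance(params, CrankParameters):
            raise TypeError("crank simulation needs CrankParameters")
        clean = crank_extraction_fraction(times, params)
        curve = ExtractionCurve(times, clean, basis="normalized",
                                meta={"model": "crank"})
    elif kind == "sovova":
        if not isinstance(params, SovovaParameters):
            raise TypeError("sovova simulation needs SovovaParameters")
        clean = sovova_yield(times, params)
        curve = ExtractionCurve(times, clean, basis="per_solid", abscissa="q",
                                meta={"model": "sovova"})
    elif kind == "reverchon":
        if not isinstance(params, ReverchonParameters):
            raise TypeError("reverchon simulation needs ReverchonParameters")
        bed = bed if bed is not None else BedProperties.default()
        curve = reverchon_simulate(params, bed, times, n_cells=n_cells)
        clean = curve.values
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    truth = {
        "kind": kind,
        "params": params,
        "clean_values": np.array(clean),
        "noise": noise,
    }
    if noise is not None:
        # yields cannot be negative (and normalized yields cannot exceed
        # 1), so noisy values are clipped to the physical range — but
        # never monotonized
        noisy = np.clip(noise.apply(curve.values), 0.0, None)
        if curve.basis == "normalized":
            noisy = np.minimum(noisy, 1.0)
        curve = curve.with_values(noisy)
    return curve, truth


def simulate_design_response(
    surface: QuadraticSurface,
    design: DesignTable,
    noise: NoiseSpec | None = None,
    response_name: str | None = None,
) -> DesignTable:
    """Evaluate a quadratic surface on a design and add run-level noise.

    Replicated runs (e.g. center points) receive independent draws.  The
    returned table carries the response on the surface's response scale.
    """
    if sorted(surface.factor_names) != sorted(design.factor_names):
        raise ValueError(
            f"surface factors {surface.factor_names} do not match design "
            f"factors {design.factor_names}"
        )
    name = response_name or surface.response_name
    pts = design.data[surface.factor_names].to_numpy(dtype=float)
    values = surface.evaluate(pts)
    if noise is not None:
        values = noise.apply(values)
    data = design.data[design.factor_names].copy()
    data[name] = values
    return replace(
        design,
        data=data,
        response_scale={name: surface.response_scale},
    )
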