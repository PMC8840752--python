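"""Containers for extraction kinetics: the measured curve, the particle
geometry, and the packed-bed properties that convert fitted model
parameters into physical mass-transfer coefficients."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._units import DEFAULT_SIEVE_TABLE_MM, mesh_to_mm

__all__ = ["ExtractionCurve", "ParticleGeometry", "BedProperties"]

#: valid bases for a cumulative-yield curve
CURVE_BASES = (
    "per_feed",  # extract mass / feed mass (the usual "global yield" fraction)
    "per_solid",  # Sovova's e: extract mass / insoluble-solid mass
    "normalized",  # M_t / M_inf in [0, 1]
)


@dataclass
class ExtractionCurve:
    """Cumulative extraction yield versus time.

    ``times`` are in seconds and must be strictly increasing; ``values``
    are cumulative yields on the declared ``basis``.  For Sovova-model
    work the abscissa may instead be the dimensionless specific solvent
    consumption q (``abscissa="q"``).
    """

    times: np.ndarray
    values: np.ndarray
    basis: str = "per_feed"
    abscissa: str = "time_s"  # or "q"
    feed_mass_g: float | None = None
    asymptote: float | None = None
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty extraction curve")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("yields must be >= 0")
        if self.basis not in CURVE_BASES:
            raise ValueError(f"basis must be one of {CURVE_BASES}")
        if self.basis == "normalized" and np.any(self.values > 1.0 + 1e-9):
            raise ValueError("normalized yields must not exceed 1")

    def __len__(self) -> int:
        return self.times.size

    def asymptote_estimate(self) -> float:
        """Plateau estimate: declared asymptote, else median of the last
        three samples (robust to multiplicative noise on the tail)."""
        if self.asymptote is not None:
            return float(self.asymptote)
        tail = self.values[-3:] if len(self) >= 3 else self.values
        return float(np.median(tail))

    def plateau_reached(self, rise_tol: float = 0.05) -> bool:
        """False when the curve is still rising more than ``rise_tol``
        (relative) at the last step — the asymptote is then unidentifiable."""
        if len(self) < 2:
            return False
        last, prev = self.values[-1], self.values[-2]
        if last <= 0:
            return False
        return (last - prev) / last <= rise_tol

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.abscissa: self.times, "yield": self.values})

    def with_values(self, values: np.ndarray, **meta) -> "ExtractionCurve":
        return replace(self, values=np.asarray(values, dtype=float), **meta)


@dataclass(frozen=True)
class ParticleGeometry:
    """Particle size and shape for the diffusion models.

    ``mu`` is the shape constant of the internal-diffusion time relation
    (3/5 for spheres) and ``l`` the characteristic length, i.e. the
    volume-to-surface ratio (r/3 for spheres).
    """

    radius: float  # m
    mu: float = 3.0 / 5.0
    l: float | None = None  # m; defaults to radius / 3 (sphere)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be > 0")
        if self.l is None:
            object.__setattr__(self, "l", self.radius / 3.0)
        if self.l <= 0 or self.mu <= 0:
            raise ValueError("mu and l must be > 0")

    @classmethod
    def sphere(cls, radius_m: float) -> "ParticleGeometry":
        return cls(radius=radius_m)

    @classmethod
    def from_mesh(
        cls, mesh: int, sieve_table: dict[int, float] | None = None
    ) -> "ParticleGeometry":
        d_mm = mesh_to_mm(mesh, sieve_table)
        return cls.sphere(0.5 * d_mm * 1e-3)


@dataclass
class BedProperties:
    """Packed-bed and flow properties of the extractor.

    All quantities are SI.  Only the properties needed by a given
    conversion must be present; :meth:`require` reports what is missing.

    The defaults in :meth:`default` describe the 500 mL pilot extractor
    loaded with 80 g of milled plant and 800 g/h of CO2: a very porous
    flower bed (bulk 160 kg/m3 against a plant-matter density of
    1400 kg/m3 gives porosity 0.886), CO2 at roughly 900 kg/m3 under the
    optimized 279 bar / 40 degC condition, and a specific interfacial
    area taken as the sphere surface-to-volume ratio 6/d of the 0.423 mm
    (42 mesh) particles.
    """

    porosity: float | None = None  # epsilon, (0, 1)
    fluid_density: float | None = None  # rho, kg/m3
    solid_density: float | None = None  # rho_s, kg/m3
    specific_area: float | None = None  # a0, 1/m
    specific_flow: float | None = None  # qdot, 1/s  (solvent mass per N per s)
    solvent_flow: float | None = None  # Q, kg/s
    insoluble_mass: float | None = None  # N, kg
    extractor_volume: float | None = None  # V, m3
    particle_area: float | None = None  # Ap, m2 (total interfacial area)
    interstitial_velocity: float | None = None  # u, m/s
    residence_time: float | None = None  # tau, s

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v is not None and v <= 0:
                raise ValueError(f"bed property {name!r} must be > 0, got {v}")
        if self.porosity is not None and not (0 < self.porosity < 1):
            raise ValueError("porosity must lie in (0, 1)")
        # derive what follows from what was given
        if (
            self.specific_flow is None
            and self.solvent_flow is not None
            and self.insoluble_mass is not None
        ):
            self.specific_flow = self.solvent_flow / self.insoluble_mass
        if (
            self.residence_time is None
            and None not in (self.porosity, self.extractor_volume,
                             self.solvent_flow, self.fluid_density)
        ):
            vdot = self.solvent_flow / self.fluid_density
            self.residence_time = self.porosity * self.extractor_volume / vdot
        elif (
            self.residence_time is not None
            and None not in (self.porosity, self.extractor_volume,
                             self.solvent_flow, self.fluid_density)
        ):
            vdot = self.solvent_flow / self.fluid_density
            tau = self.porosity * self.extractor_volume / vdot
            if abs(tau - self.residence_time) > 1e-6 * tau:
                raise ValueError(
                    f"residence_time {self.residence_time} inconsistent with "
                    f"eps*V/Vdot = {tau}"
                )

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"bed properties missing: {missing}")

    @property
    def solid_to_fluid_holdup(self) -> float:
        """(1 - eps) * rho_s / eps: solid mass per unit fluid volume."""
        self.require("porosity", "solid_density")
        return (1.0 - self.porosity) * self.solid_density / self.porosity

    @classmethod
    def default(cls) -> "BedProperties":
        """Documented default configuration of the pilot extractor."""
        d = 0.423e-3  # 42 mesh mean particle diameter, m
        eps = 0.886
        V = 5.0e-4
        return cls(
            porosity=eps,
            fluid_density=900.0,
            solid_density=1400.0,
            specific_area=6.0 / d,
            solvent_flow=800.0 / 3600.0 * 1e-3,  # 800 g/h
            insoluble_mass=0.078,  # 80 g feed less ~3% extractables
            extractor_volume=V,
            particle_area=(6.0 / d) * (1.0 - eps) * V,
        )


def warn_if_unidentifiable(curve: ExtractionCurve) -> bool:
    """Warn (and return True) when the curve never flattens, so the
    asymptote — and any parameter tied to it — is weakly identified."""
    if not curve.plateau_reached():
        warnings.warn(
            "extraction curve is still rising at the last sample; the "
            "asymptote estimate is unreliable",
            stacklevel=2,
        )
        return True
    return False
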