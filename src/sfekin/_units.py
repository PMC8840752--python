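"""Unit conversions and the Tyler sieve table.

Internally the kinetic models work in strict SI (m, s, kg, Pa, K).
Constructors accept the bench units used in supercritical-extraction
practice (bar, °C, mesh, mm, g, min) and convert on entry.
"""

from __future__ import annotations

# Tyler mesh -> mean particle diameter in mm for the sieve classes used here.
DEFAULT_SIEVE_TABLE_MM: dict[int, float] = {42: 0.423, 60: 0.303, 150: 0.125}

BAR_TO_PA = 1.0e5
MM_TO_M = 1.0e-3
G_TO_KG = 1.0e-3
MIN_TO_S = 60.0
HOUR_TO_S = 3600.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def mesh_to_mm(mesh: int, sieve_table: dict[int, float] | None = None) -> float:
    """Mean particle diameter (mm) for a Tyler mesh class."""
    table = DEFAULT_SIEVE_TABLE_MM if sieve_table is None else sieve_table
    try:
        return table[int(mesh)]
    except KeyError:
        raise KeyError(
            f"mesh {mesh} not in sieve table {sorted(table)}; "
            "pass an explicit sieve_table entry"
        ) from None


def mesh_to_radius_m(mesh: int, sieve_table: dict[int, float] | None = None) -> float:
    """Mean particle radius (m) for a Tyler mesh class."""
    return 0.5 * mesh_to_mm(mesh, sieve_table) * MM_TO_M
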