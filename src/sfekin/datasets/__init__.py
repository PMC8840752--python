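"""Embedded experimental design tables.

Two fixtures ship with the package, checksum-pinned so tests detect any
accidental edit:

``table1``
    The Step-I 2x2 factorial on CO2 pressure (120/180/240 bar) and
    cosolvent ("modifier": water / 1:1 water-ethanol / ethanol, stored on
    the ordinal coded scale -1/0/+1), with the global extract yield
    (% w/w of feed) as response; 4 corner runs plus 3 center replicates.

``table3``
    The Step-II Box-Behnken design on pressure (200/250/300 bar),
    temperature (40/50/60 degC) and mean particle size (42/60/150 Tyler
    mesh), with the p-anisic acid selectivity (% w/w of extract) and the
    global extract yield (% w/w of feed) as responses; 12 edge-midpoint
    runs plus 3 center replicates.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from ..doe import DesignTable, Factor

__all__ = ["load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table3")

_CHECKSUMS = {
    "table1.csv": "0fa7dff55653fa25555dbe8717beec7fb88cfdc6d68c7e61df9b6ec7aea452b7",
    "table3.csv": "e1e83156fd00d613351fcef579d7f5a72fef5df439793187d90efe9b9d18ccb0",
}

_FACTORS = {
    "table1": [
        Factor("P", 120.0, 180.0, 240.0, unit="bar"),
        Factor("M", -1.0, 0.0, 1.0, unit="coded", kind="categorical-as-coded"),
    ],
    "table3": [
        Factor("P", 200.0, 250.0, 300.0, unit="bar"),
        Factor("T", 40.0, 50.0, 60.0, unit="degC"),
        Factor("G", 42.0, 60.0, 150.0, unit="mesh"),
    ],
}

_META = {
    "table1": {
        "modifier_labels": {-1: "water", 0: "water:ethanol 1:1 v/v", 1: "ethanol"},
    },
    "table3": {
        # row order of the published ANOVA: temperature enters first
        "anova_order": ["T", "P", "G"],
        "sieve_mm": {42: 0.423, 60: 0.303, 150: 0.125},
    },
}

_SCALES = {
    "table1": {"global_yield": "percent"},
    "table3": {"selectivity": "percent", "global_yield": "percent"},
}


def _read_pinned(filename: str) -> pd.DataFrame:
    raw = resources.files(__package__).joinpath(filename).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise RuntimeError(
            f"fixture {filename} checksum mismatch: {digest} != "
            f"{_CHECKSUMS[filename]}; the embedded data were modified"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), index_col="run")


def load_fixture(name: str) -> DesignTable:
    """Return one of the embedded design tables as a :class:`DesignTable`."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    data = _read_pinned(f"{name}.csv")
    return DesignTable(
        factors=list(_FACTORS[name]),
        data=data,
        response_scale=dict(_SCALES[name]),
        meta=dict(_META[name]),
    )
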