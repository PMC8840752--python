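"""File formats and the end-to-end pipeline runner.

CSV dialect is fixed: comma separator, dot decimal, UTF-8, mandatory
header.  Design tables travel with a YAML sidecar declaring factors,
levels, units and response scales; extraction curves with a sidecar
declaring basis and feed mass.  Reports are written as JSON (full
precision) plus a human-readable text rendering (6 significant digits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doe import DesignError, DesignTable, Factor, ResponseSurfaceModel
from .estimation import fit_extraction_model
from .kinetics.base import BedProperties, ExtractionCurve
from .synthetic import load_fixture

log = logging.getLogger("sfekin")

__all__ = [
    "RunConfig",
    "read_design_csv",
    "write_design_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_bed_config",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------


def _factors_from_spec(spec: list[dict]) -> list[Factor]:
    out = []
    for f in spec:
        out.append(
            Factor(
                name=f["name"],
                low=float(f["low"]),
                center=float(f["center"]),
                high=float(f["high"]),
                unit=f.get("unit", ""),
                kind=f.get("kind", "continuous"),
            )
        )
    return out


def read_design_csv(path, config) -> DesignTable:
    """Read a design table; ``config`` is a sidecar YAML path or a dict
    declaring ``factors`` (name/unit/low/center/high) and ``responses``
    (name/scale).  Structural violations are reported with the offending
    row."""
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    factors = _factors_from_spec(config["factors"])
    responses = {r["name"]: r.get("scale", "percent") for r in config["responses"]}

    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if df.empty:
        raise DesignError(f"{path}: no data rows")
    if "run" not in df.columns:
        raise DesignError(f"{path}: missing mandatory 'run' column")
    if df["run"].duplicated().any():
        dupes = df.loc[df["run"].duplicated(), "run"].tolist()
        raise DesignError(f"{path}: duplicate run ids {dupes}")
    expected = ["run"] + [f.name for f in factors] + list(responses)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DesignError(f"{path}: missing columns {missing}")
    for resp in responses:
        bad = pd.to_numeric(df[resp], errors="coerce").isna() & df[resp].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # header is line 1
            raise DesignError(f"{path}: non-numeric {resp!r} at line(s) {rows}")
    df = df.set_index("run")
    table = DesignTable(
        factors=factors,
        data=df[[f.name for f in factors] + list(responses)],
        response_scale=responses,
        meta={k: v for k, v in config.items() if k not in ("factors", "responses")},
    )
    return table


def write_design_csv(table: DesignTable, path, sidecar=None) -> None:
    table.data.to_csv(path, index_label="run", encoding="utf-8")
    if sidecar is not None:
        spec = {
            "factors": [
                dict(name=f.name, unit=f.unit, low=f.low, center=f.center,
                     high=f.high, kind=f.kind)
                for f in table.factors
            ],
            "responses": [
                dict(name=r, scale=table.response_scale.get(r, "percent"))
                for r in table.response_names
            ],
            **table.meta,
        }
        with open(sidecar, "w", encoding="utf-8") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Extraction curves
# ---------------------------------------------------------------------------


def read_curve_csv(path, sidecar=None) -> ExtractionCurve:
    """Read a ``time_s,yield`` (or ``q,yield``) curve, with optional YAML
    sidecar carrying basis and feed-mass metadata."""
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    abscissa = "q" if "q" in df.columns else "time_s"
    if abscissa not in df.columns or "yield" not in df.columns:
        raise ValueError(f"{path}: expected columns 'time_s' (or 'q') and 'yield'")
    meta: dict = {}
    if sidecar is not None and Path(sidecar).exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
    return ExtractionCurve(
        df[abscissa].to_numpy(dtype=float),
        df["yield"].to_numpy(dtype=float),
        basis=meta.get("basis", "per_feed"),
        abscissa=abscissa,
        feed_mass_g=meta.get("feed_mass_g"),
        asymptote=meta.get("asymptote"),
        meta={k: v for k, v in meta.items()
              if k not in ("basis", "feed_mass_g", "asymptote")},
    )


def write_curve_csv(curve: ExtractionCurve, path, sidecar=None) -> None:
    curve.to_frame().to_csv(path, index=False, encoding="utf-8")
    if sidecar is not None:
        meta = {"basis": curve.basis, **curve.meta}
        if curve.feed_mass_g is not None:
            meta["feed_mass_g"] = curve.feed_mass_g
        if curve.asymptote is not None:
            meta["asymptote"] = curve.asymptote
        with open(sidecar, "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def read_bed_config(spec: dict | None) -> BedProperties | None:
    if spec is None:
        return None
    if spec == "default":
        return BedProperties.default()
    allowed = set(BedProperties.__dataclass_fields__)
    unknown = set(spec) - allowed
    if unknown:
        raise ValueError(f"unknown bed properties: {sorted(unknown)}")
    return BedProperties(**{k: float(v) for k, v in spec.items()})


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

_RUNCONFIG_KEYS = {
    "seed", "output_dir", "doe", "kinetics", "sieve_table",
}
_DOE_KEYS = {"design", "design_config", "response", "scale", "anova_order",
             "optimize", "bounds"}
_KIN_KEYS = {"model", "curve", "curve_sidecar", "fixed", "n_starts", "bed",
             "report_coefficients"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    output_dir: str = "sfekin_out"
    doe: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    sieve_table: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doe = raw.get("doe") or {}
        kin = raw.get("kinetics") or {}
        for section, allowed, name in ((doe, _DOE_KEYS, "doe"),
                                       (kin, _KIN_KEYS, "kinetics")):
            bad = set(section) - allowed
            if bad:
                raise ValueError(f"unknown {name} config keys: {sorted(bad)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "sfekin_out")),
            doe=doe,
            kinetics=kin,
            sieve_table=raw.get("sieve_table") or {},
        )


def _load_design(doe_cfg: dict) -> DesignTable:
    design = doe_cfg.get("design", "table3")
    if design in ("table1", "table3"):
        return load_fixture(design)
    cfg = doe_cfg.get("design_config")
    if cfg is None:
        raise ValueError("a design CSV path needs a 'design_config' sidecar")
    return read_design_csv(design, cfg)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Fixtures -> surface fit / ANOVA / optimum -> kinetic fit -> report.

    Writes the ANOVA CSV, surface coefficients on both response scales,
    the optimizer result, the kinetic fit report and a run log into
    ``config.output_dir`` and returns the report bundle as a dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__}
    stage = "setup"
    try:
        if config.doe:
            stage = "doe"
            table = _load_design(config.doe)
            response = config.doe.get("response", table.response_names[0])
            res = ResponseSurfaceModel(table, response).fit()
            log.info("fitted %s surface: R^2 = %.4f", response, res.rsquared)
            surface_pct = res.surface.on_response_scale("percent")
            surface_frac = res.surface.on_response_scale("fraction")
            report["doe"] = {
                "response": response,
                "r_squared": res.rsquared,
                "coefficients_percent": dict(surface_pct.coefficients),
                "coefficients_fraction": dict(surface_frac.coefficients),
            }
            anova = res.anova(order=config.doe.get("anova_order"))
            anova.to_csv(out / "anova.csv")
            (out / "anova.txt").write_text(str(anova) + "\n", encoding="utf-8")
            if config.doe.get("optimize", True):
                bounds = config.doe.get("bounds")
                if bounds is not None:
                    bounds = {k: tuple(map(float, v)) for k, v in bounds.items()}
                opt = res.maximize(bounds)
                log.info(
                    "optimum: %s -> %.6g %s",
                    {k: round(v, 3) for k, v in opt.argmax.items()},
                    opt.predicted_response, res.model.scale,
                )
                report["optimum"] = {
                    "argmax": opt.argmax,
                    "predicted_response": opt.predicted_response,
                    "active_bounds": opt.active_bounds,
                }
        if config.kinetics:
            stage = "kinetics"
            kin = config.kinetics
            curve = read_curve_csv(kin["curve"], kin.get("curve_sidecar"))
            bed = read_bed_config(kin.get("bed"))
            fit = fit_extraction_model(
                curve,
                kin.get("model", "crank"),
                fixed=kin.get("fixed"),
                n_starts=kin.get("n_starts"),
                seed=config.seed,
                bed=bed,
            )
            log.info("kinetic fit:\n%s", fit.summary())
            block = {
                "model": fit.model_kind,
                "estimates": fit.estimates,
                "sse": fit.sse,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
                "n_evaluations": fit.n_evaluations,
            }
            if kin.get("report_coefficients", True):
                if fit.derived:
                    block["derived"] = fit.derived
                else:
                    block["derived"] = "unavailable (bed/particle data missing)"
            report["kinetics"] = block
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_json = _jsonable(report)
    (out / "report.json").write_text(
        json.dumps(report_json, indent=2), encoding="utf-8"
    )
    (out / "report.txt").write_text(_render_report(report_json), encoding="utf-8")
    (out / "run.log").write_text(
        f"sfekin {__version__}\nseed {config.seed}\n", encoding="utf-8"
    )
    return report


def _fmt(v):
    return f"{v:.6g}" if isinstance(v, float) else str(v)


def _render_report(report: dict, indent: int = 0) -> str:
    lines = []
    pad = "  " * indent
    for k, v in report.items():
        if isinstance(v, dict):
            lines.append(f"{pad}{k}:")
            lines.append(_render_report(v, indent + 1))
        else:
            lines.append(f"{pad}{k}: {_fmt(v)}")
    return "\n".join(lines)
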