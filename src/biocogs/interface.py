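"""Configuration loading, result serialization and the pipeline driver.

All configuration is plain YAML (JSON is valid YAML and therefore also
accepted); tables are written as CSV and summaries as JSON.  Every output
directory receives exactly one ``manifest.json`` recording the command,
config path, seed, package version and timestamp, and every stochastic
output embeds its seed so it can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, cost_engine, monte_carlo, sensitivity, surrogate
from .atps_model import ATPSSpec, RecycleSpec
from .cost_engine import CostModelConfig, calibrate_fixture
from .flowsheet import ConfigurationError, Flowsheet, UnitOperation
from .param_sampler import TriangularDist
from .sensitivity import Scenario

__all__ = [
    "RunManifest",
    "ConfigBundle",
    "load_config",
    "serialize_config",
    "run_pipeline",
    "PIPELINE_COMMANDS",
]

PIPELINE_COMMANDS = ("cog", "sensitivity", "montecarlo", "surrogate", "overlap", "all")


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_path: str
    seed: int
    package_version: str
    timestamp: str


@dataclass(frozen=True)
class ConfigBundle:
    """Validated configuration tree for the packaged uricase case study."""

    flowsheets: dict[str, Flowsheet]
    cost_configs: dict[str, CostModelConfig]
    atps_spec: ATPSSpec
    recycle_spec: RecycleSpec
    scenarios: list[Scenario]
    dists: dict[str, TriangularDist]
    mc_n_max: int
    mc_window: int
    mc_tol: float
    overlap_n: int
    raw: dict
    path: str


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"{context}: missing required field {key!r}")
    return mapping[key]


def flowsheet_from_dict(d: Mapping[str, Any]) -> Flowsheet:
    ops = tuple(
        UnitOperation(
            name=_require(op, "name", "operation"),
            category=_require(op, "category", "operation"),
            step_yield=float(op.get("step_yield", 1.0)),
            volume_factor=float(op.get("volume_factor", 1.0)),
            material_items=tuple(op.get("material_items", ())),
            consumable_items=tuple(op.get("consumable_items", ())),
        )
        for op in _require(d, "operations", "flowsheet")
    )
    return Flowsheet(
        process_id=_require(d, "process_id", "flowsheet"),
        fermenter_volume=float(_require(d, "fermenter_volume", "flowsheet")),
        titer=float(_require(d, "titer", "flowsheet")),
        operations=ops,
    )


def flowsheet_to_dict(fs: Flowsheet) -> dict:
    return {
        "process_id": fs.process_id,
        "fermenter_volume": fs.fermenter_volume,
        "titer": fs.titer,
        "operations": [
            {
                "name": op.name,
                "category": op.category,
                "step_yield": op.step_yield,
                "volume_factor": op.volume_factor,
                "material_items": list(op.material_items),
                "consumable_items": list(op.consumable_items),
            }
            for op in fs.operations
        ],
    }


def _triangular_from_dict(d: Mapping[str, Any], context: str) -> TriangularDist:
    return TriangularDist(
        low=float(_require(d, "low", context)),
        mode=float(_require(d, "mode", context)),
        high=float(_require(d, "high", context)),
    )


def default_config_path() -> Path:
    """Path of the packaged uricase case-study configuration."""
    return Path(resources.files("biocogs").joinpath("data/uricase.yaml"))


def load_config(path: str | Path | None = None) -> ConfigBundle:
    """Load and validate a configuration tree (YAML, JSON accepted).

    With ``path=None`` the packaged uricase case study is loaded.  All type
    invariants are checked on load; violations raise
    :class:`~biocogs.flowsheet.ConfigurationError` naming the offending
    field.
    """
    path = default_config_path() if path is None else Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw)}")

    flowsheets = {
        fs_dict["process_id"]: flowsheet_from_dict(fs_dict)
        for fs_dict in _require(raw, "flowsheets", "config")
    }

    recycle_raw = _require(raw, "recycle", "config")
    recycle_spec = RecycleSpec(
        r_peg=float(_require(recycle_raw, "r_peg", "recycle")),
        r_as=float(_require(recycle_raw, "r_as", "recycle")),
        r_nacl=float(_require(recycle_raw, "r_nacl", "recycle")),
        bottom_fraction_second_system=float(
            _require(recycle_raw, "bottom_fraction_second_system", "recycle")
        ),
        fresh_as_per_sample_l=float(
            _require(recycle_raw, "fresh_as_per_sample_l", "recycle")
        ),
    )

    atps_raw = _require(raw, "atps", "config")
    atps_spec = ATPSSpec(
        system_volume_multiplier=float(
            _require(atps_raw, "system_volume_multiplier", "atps")
        ),
        top_fraction=float(_require(atps_raw, "top_fraction", "atps")),
        product_destination=_require(atps_raw, "product_destination", "atps"),
        component_charge_per_sample_l=dict(
            _require(atps_raw, "component_charge_per_sample_l", "atps")
        ),
        top_split=dict(_require(atps_raw, "top_split", "atps")),
    )

    cm = _require(raw, "cost_model", "config")
    wages = {
        loc: {role: float(w) for role, w in table.items()}
        for loc, table in _require(cm, "labor_wages", "cost_model").items()
    }
    calibration = _require(cm, "calibration", "cost_model")
    cost_configs: dict[str, CostModelConfig] = {}
    for process_id in ("chromatography", "atps"):
        cal = _require(calibration, process_id, "cost_model.calibration")
        template = CostModelConfig(
            annual_fixed={"capital": 0.0, "other": 0.0},
            labor_wages=wages,
            labor_base_location=_require(cm, "labor_base_location", "cost_model"),
            labor_headcount_equivalent=1.0,
            material_lines=dict(
                _require(cm, "material_lines", "cost_model").get(process_id, {})
            ),
            consumable_lines={},
            scenario_material_items=tuple(
                _require(cm, "scenario_material_items", "cost_model")
            ),
            ufdf_filter_capacity=float(
                _require(cm, "ufdf_filter_capacity_l", "cost_model")
            ),
            ufdf_filter_cost=float(_require(cm, "ufdf_filter_cost_usd", "cost_model")),
            target_output=float(
                _require(cm, "target_output_g_per_year", "cost_model")
            ),
            batches_continuous=bool(cm.get("batches_continuous", True)),
            recycle=recycle_spec,
        )
        cost_configs[process_id] = calibrate_fixture(
            flowsheets[process_id],
            target_cog=float(_require(cal, "target_cog_usd_per_g", "calibration")),
            target_shares={
                k: float(v) for k, v in _require(cal, "shares", "calibration").items()
            },
            template=template,
        )
    # The recycle flowsheet is costed with the ATPS calibration, untouched:
    # its economics must emerge from the mass balance, not a re-tuning.
    cost_configs["atps_recycle"] = cost_configs["atps"]

    scen_raw = _require(raw, "scenarios", "config")
    scenarios = [
        Scenario(
            variable=_require(s, "variable", "scenario"),
            best_value=s["best"],
            base_value=s["base"],
            worst_value=s["worst"],
        )
        for s in scen_raw
    ]

    dists = {
        name: _triangular_from_dict(d, f"distributions.{name}")
        for name, d in _require(raw, "distributions", "config").items()
    }

    mc = raw.get("monte_carlo", {})
    ov = raw.get("overlap", {})
    return ConfigBundle(
        flowsheets=flowsheets,
        cost_configs=cost_configs,
        atps_spec=atps_spec,
        recycle_spec=recycle_spec,
        scenarios=scenarios,
        dists=dists,
        mc_n_max=int(mc.get("n_max", monte_carlo.DEFAULT_N_MAX)),
        mc_window=int(mc.get("window", monte_carlo.DEFAULT_WINDOW)),
        mc_tol=float(mc.get("tol", monte_carlo.DEFAULT_TOL)),
        overlap_n=int(ov.get("n", 100_000)),
        raw=raw,
        path=str(path),
    )


def serialize_config(bundle: ConfigBundle) -> str:
    """YAML text of the bundle's configuration tree (load/serialize/load is
    idempotent)."""
    return yaml.safe_dump(bundle.raw, sort_keys=True)


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _cog_outputs(bundle: ConfigBundle, out: Path) -> dict[str, float]:
    values = {}
    for process_id, fs in bundle.flowsheets.items():
        result = cost_engine.cog_per_gram(fs, bundle.cost_configs[process_id])
        shares = cost_engine.breakdown_shares(result)
        rows = [
            {
                "category": cat,
                "annual_cost_usd": result.category_costs[cat],
                "share": shares[cat],
            }
            for cat in cost_engine.COST_CATEGORIES
        ]
        rows.append(
            {
                "category": "total",
                "annual_cost_usd": sum(result.category_costs.values()),
                "share": 1.0,
            }
        )
        pd.DataFrame(rows).to_csv(out / f"cog_{process_id}.csv", index=False)
        _write_json(
            out / f"cog_{process_id}.json",
            {
                "process_id": process_id,
                "cog_per_gram": result.cog_per_gram,
                "annual_mass_g": result.annual_mass,
                "batches": result.batches,
                "category_costs": result.category_costs,
            },
        )
        values[process_id] = result.cog_per_gram
    return values


def _sensitivity_outputs(bundle: ConfigBundle, out: Path) -> None:
    for process_id in ("chromatography", "atps"):
        entries = sensitivity.run_scenarios(
            bundle.flowsheets[process_id],
            bundle.cost_configs[process_id],
            bundle.scenarios,
        )
        ranked = sensitivity.tornado_rank(entries)
        sensitivity.tornado_frame(ranked).to_csv(
            out / f"sensitivity_{process_id}.csv", index=False
        )


def _montecarlo_outputs(
    bundle: ConfigBundle, out: Path, seed: int, n_max: int | None
) -> dict[str, monte_carlo.MCResult]:
    results = {}
    for i, (process_id, fs) in enumerate(sorted(bundle.flowsheets.items())):
        res = monte_carlo.run_monte_carlo(
            fs,
            bundle.cost_configs[process_id],
            dists=bundle.dists,
            n_max=n_max or bundle.mc_n_max,
            seed=seed + i,
            window=bundle.mc_window,
            tol=bundle.mc_tol,
        )
        res.to_frame().to_csv(out / f"montecarlo_{process_id}.csv", index=False)
        _write_json(out / f"montecarlo_{process_id}.json", res.summary())
        results[process_id] = res
    return results


def _surrogate_outputs(
    bundle: ConfigBundle, out: Path, mc_results: dict[str, monte_carlo.MCResult]
) -> None:
    rows = []
    for process_id, res in sorted(mc_results.items()):
        frame = res.to_frame()
        fit = surrogate.fit_linear(frame[["titer", "dsp_yield_delta", "cog"]])
        rows.append(
            {
                "process_id": process_id,
                "intercept": fit.intercept,
                "beta_titer": fit.beta_titer,
                "beta_yield": fit.beta_yield,
                "p_intercept": fit.p_values["intercept"],
                "p_beta_titer": fit.p_values["beta_titer"],
                "p_beta_yield": fit.p_values["beta_yield"],
                "n_obs": fit.n_obs,
                "significant_at_0.01": fit.significant(),
            }
        )
    pd.DataFrame(rows).to_csv(out / "surrogate_coefficients.csv", index=False)


def _overlap_outputs(bundle: ConfigBundle, out: Path, seed: int) -> None:
    refs = surrogate.reference_surrogates()
    result = surrogate.overlap_analysis(
        refs["chromatography"],
        refs["atps"],
        dists=bundle.dists,
        n=bundle.overlap_n,
        seed=seed,
    )
    _write_json(out / "overlap.json", asdict(result))


def run_pipeline(
    command: str,
    config: ConfigBundle | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path = "biocogs_out",
    n: int | None = None,
) -> Path:
    """Execute a pipeline command, writing results plus a manifest.

    ``all`` runs the full analysis sequence: deterministic CoG/g for the
    three flowsheets, scenario sensitivity, Monte Carlo per flowsheet,
    surrogate fits on the Monte Carlo output, and the overlap analysis.
    """
    if command not in PIPELINE_COMMANDS:
        raise ConfigurationError(
            f"unknown command {command!r}; expected one of {PIPELINE_COMMANDS}"
        )
    bundle = config if isinstance(config, ConfigBundle) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if command in ("cog", "all"):
        _cog_outputs(bundle, out)
    if command in ("sensitivity", "all"):
        _sensitivity_outputs(bundle, out)
    mc_results = None
    if command in ("montecarlo", "surrogate", "all"):
        mc_results = _montecarlo_outputs(bundle, out, seed, n)
    if command in ("surrogate", "all"):
        assert mc_results is not None
        _surrogate_outputs(bundle, out, mc_results)
    if command in ("overlap", "all"):
        _overlap_outputs(bundle, out, seed)

    manifest = RunManifest(
        command=command,
        config_path=bundle.path,
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    _write_json(out / "manifest.json", asdict(manifest))
    return out
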