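"""Single-config orchestration of the analysis stages.

A run config (YAML or a plain dict) selects stages and carries their
parameters; :func:`run` executes the selected stages in dependency order and
returns a self-contained, JSON-serializable report that echoes the config,
so any report can be reproduced by re-running from its own echo with the
same seed.  One global seed is fanned out to the stochastic stages by fixed
offsets, which lets a stage be re-run in isolation with the same stream.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time

import yaml

from . import __version__
from .design import HeterologousSpec, predicted_rubisco_3pg_fraction, scan_knockouts
from .growth import bootstrap_effect_ci, effect_at_time, read_growth_csv
from .isotopes import (
    MixtureParams,
    compare_to_fba,
    estimate_rubisco_fraction,
    read_isotopologue_csv,
)
from .kinetics import RubiscoKinetics, rate_curve_table
from .model import apply_knockouts, load_model, set_carbon_source
from .synth import (
    GrowthSimSpec,
    LabelingSimSpec,
    ToyNetworkSpec,
    make_toy_model,
    simulate_growth_curves,
    simulate_labeling,
    toy_heterologous_spec,
)

__all__ = ["RunConfig", "run", "write_report", "load_config"]

SCHEMA_VERSION = 1

#: fixed per-stage seed offsets from the global seed
_SEED_OFFSETS = {"labeling": 1, "growth": 2}

_KNOWN_STAGES = ("design", "rates", "labeling", "growth")

log = logging.getLogger("rubiscoflux")


class ConfigError(ValueError):
    """The run config is malformed."""


class RunConfig(dict):
    """A validated run configuration (a thin dict wrapper).

    Required keys: ``seed`` (int) and ``stages`` (nonempty list drawn from
    ``design, rates, labeling, growth``).  Each selected stage may carry a
    parameter mapping under its own name; referenced input paths must exist.
    """

    @classmethod
    def validate(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        if "seed" not in raw or not isinstance(raw["seed"], int):
            raise ConfigError("config needs an integer 'seed'")
        stages = raw.get("stages")
        if not isinstance(stages, list) or not stages:
            raise ConfigError("config needs a nonempty 'stages' list")
        unknown = set(stages) - set(_KNOWN_STAGES)
        if unknown:
            raise ConfigError(
                f"unknown stages {sorted(unknown)}; known: {_KNOWN_STAGES}"
            )
        for stage in stages:
            params = raw.get(stage, {})
            if not isinstance(params, dict):
                raise ConfigError(f"stage section {stage!r} must be a mapping")
            for key in ("model", "isotopologues", "mrm", "growth_csv"):
                path = params.get(key)
                if path is not None and path != "toy" and not os.path.exists(path):
                    raise ConfigError(f"{stage}.{key}: path {path!r} does not exist")
        return cls(raw)


def load_config(source) -> RunConfig:
    """Load and validate a YAML config from a path or file object."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    return RunConfig.validate(raw)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _heterologous_from(params: dict) -> HeterologousSpec:
    het = params.get("heterologous")
    if het is None:
        return toy_heterologous_spec()
    return HeterologousSpec(**het)


def _stage_design(params: dict, seed: int) -> dict:
    model_src = params.get("model", "toy")
    if model_src == "toy":
        model = make_toy_model(ToyNetworkSpec(include_heterologous=False))
    else:
        model = load_model(model_src, format=params.get("format", "json"))
    het = _heterologous_from(params)
    sources = params.get("sources", ["EX_glyc"])
    uptake = float(params.get("uptake", 10.0))
    candidates = scan_knockouts(
        model,
        het,
        sources,
        candidate_rxns=params.get("candidates"),
        max_size=int(params.get("max_size", 2)),
        max_uptake=uptake,
    )
    rows = []
    for cand in candidates:
        for source, cs in sorted(cand.slopes.items()):
            rows.append(
                {
                    "deleted_ids": ";".join(cand.deleted),
                    "source": source,
                    "growth_without": cand.growth_without_het,
                    "growth_with": cand.growth_with_het,
                    "slope": cs.slope,
                    "intercept": cs.intercept,
                }
            )
    result: dict = {"n_candidates": len(candidates), "candidates": rows}
    if candidates and params.get("predict_fraction", True):
        best = candidates[0]
        source = sorted(best.slopes)[0]
        from .design import add_heterologous

        configured, _ = add_heterologous(model, het)
        configured = apply_knockouts(
            set_carbon_source(configured, source, uptake), best.deleted
        )
        point, rng_ = predicted_rubisco_3pg_fraction(configured, het)
        result["rubisco_3pg_fraction"] = {
            "deleted_ids": ";".join(best.deleted),
            "source": source,
            "point_percent": point,
            "fva_range_percent": list(rng_),
        }
    return result


def _stage_rates(params: dict, seed: int) -> dict:
    kin = RubiscoKinetics(
        kcat_C=float(params["kcat_c"]),
        K_C=float(params["kc"]),
        kcat_O=float(params["kcat_o"]),
        K_O=float(params["ko"]),
    )
    grid_spec = params.get("co2_grid", {"start": 1.0, "stop": 1000.0, "num": 50,
                                        "log": True})
    import numpy as np

    if grid_spec.get("log", False):
        grid = np.geomspace(grid_spec["start"], grid_spec["stop"],
                            int(grid_spec.get("num", 50)))
    else:
        grid = np.linspace(grid_spec["start"], grid_spec["stop"],
                           int(grid_spec.get("num", 50)))
    table = rate_curve_table(kin, grid, o2=float(params.get("o2", 270.0)))
    return {"o2_uM": float(params.get("o2", 270.0)),
            "table": table.to_dict(orient="records")}


def _stage_labeling(params: dict, seed: int) -> dict:
    if "isotopologues" in params:
        reps = read_isotopologue_csv(params["isotopologues"], params.get("mrm"))
        experiment = [r for r in reps if r.role == "experiment"]
        control = [r for r in reps if r.role == "control"]
        sim_echo = None
    else:
        sim_params = dict(params.get("simulate", {}))
        sim_params.setdefault("seed", seed)
        spec = LabelingSimSpec(**sim_params)
        experiment, control = simulate_labeling(spec)
        sim_echo = spec.__dict__.copy()
    mix = MixtureParams(
        c=float(params.get("c", 0.989)),
        d=float(params.get("d", 0.5)),
        mode=params.get("mode", "carboxyl_mrm"),
    )
    est = estimate_rubisco_fraction(experiment, control, mix)
    result = {
        "simulated": sim_echo,
        "mode": mix.mode,
        "background_b": est.background_b,
        "per_replicate": list(est.per_replicate),
        "mean": est.mean,
        "min": est.min,
        "clipped": list(est.clipped),
    }
    if "fba_prediction" in params:
        pred = params["fba_prediction"]
        result["vs_fba"] = compare_to_fba(
            est, (pred["point"], tuple(pred["range"]))
        )
    return result


def _stage_growth(params: dict, seed: int) -> dict:
    t_eval = float(params.get("t_eval", 80.0))
    if "growth_csv" in params:
        curves = read_growth_csv(params["growth_csv"])
        experiment = [c for c in curves if c.arm == "experiment"]
        control = [c for c in curves if c.arm == "control"]
        sim_echo = None
    else:
        sim_params = dict(params.get("simulate", {}))
        sim_params.setdefault("seed", seed)
        sim_params.setdefault("t_eval", t_eval)
        spec = GrowthSimSpec(**sim_params)
        experiment, control = simulate_growth_curves(spec)
        sim_echo = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in spec.__dict__.items()}
    ci = bootstrap_effect_ci(
        experiment,
        control,
        t_eval,
        level=float(params.get("level", 0.999)),
        n_boot=int(params.get("n_boot", 10_000)),
        seed=seed,
    )
    return {
        "simulated": sim_echo,
        "t_eval_hr": t_eval,
        "effect_od": effect_at_time(experiment, control, t_eval),
        "ci": {"level": ci.level, "lo": ci.lo, "hi": ci.hi,
               "n_boot": ci.n_boot, "seed": ci.seed},
    }


_STAGE_FNS = {
    "design": _stage_design,
    "rates": _stage_rates,
    "labeling": _stage_labeling,
    "growth": _stage_growth,
}


def run(config) -> dict:
    """Execute the selected stages and return the run report.

    Stage failures abort the run with an error naming the stage.  The report
    omits keys for stages that were not selected.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.validate(config)
    seed = cfg["seed"]
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "version": __version__,
        "seed": seed,
        "config": dict(cfg),
        "stages": {},
        "warnings": [],
    }
    for stage in _KNOWN_STAGES:
        if stage not in cfg["stages"]:
            continue
        stage_seed = seed + _SEED_OFFSETS.get(stage, 0)
        t0 = time.perf_counter()
        try:
            result = _STAGE_FNS[stage](cfg.get(stage, {}), stage_seed)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
        report["stages"][stage] = result
        if stage == "labeling" and any(result["clipped"]):
            report["warnings"].append(
                "labeling: at least one replicate estimate was clipped to [0, 1]"
            )
    return report


def write_report(report: dict, path) -> None:
    """Write a report atomically as JSON (write-then-rename)."""
    directory = os.path.dirname(os.fspath(path)) or "."
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
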