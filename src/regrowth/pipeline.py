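"""Config-driven orchestration: generate -> fit -> simulate -> screen.

A run config (dict, or path to a YAML/JSON file) names the stages to
execute with their parameter blocks plus a single global seed and an
output directory. Every stage draws its own RNG seed deterministically
from the global seed and the stage name, so stages can be re-run in
isolation; all tabular outputs are TSV, and a JSON manifest records
inputs, outputs (with content hashes), seeds, versions and wall time.

Supported stages (executed in this dependency order):
``clonogenic`` (generate + LQ fit), ``growth`` (generate + exponential
fits), ``expression`` (generate + preprocess + ANOVA/Holm screen),
``qpcr`` (generate + 2^-ddCt), ``dye`` (generate + mixture fit),
``simulate`` (cellular-automaton scenario runs).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import automaton, dye, expression, io, survival, synthetic

__all__ = ["SCHEMA_VERSION", "load_config", "validate_config", "run_pipeline"]

SCHEMA_VERSION = 1
_STAGE_ORDER = ("clonogenic", "growth", "expression", "qpcr", "dye", "simulate")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any stage executes)."""


def load_config(source) -> dict:
    """Accept a config dict or a path to a YAML/JSON file."""
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the global
    seed and the stage name (stable across runs and stage subsets)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def validate_config(config: Mapping[str, Any]) -> None:
    """Walk the config schema and fail fast on structural errors."""
    if config.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(
            f"config must declare schema_version: {SCHEMA_VERSION}"
        )
    if "seed" not in config:
        raise ConfigError("config must declare a global seed")
    stages = config.get("stages")
    if not isinstance(stages, Mapping) or not stages:
        raise ConfigError("config must declare a non-empty 'stages' mapping")
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    sim = stages.get("simulate")
    if sim:
        params = automaton.CAParameters(**sim.get("params", {}))
        scenario = sim.get("scenario", "none")
        if scenario not in ("none", "local", "global"):
            raise ConfigError(f"unknown scenario {scenario!r}")
        if scenario == "global" and params.global_pa is None:
            raise ConfigError("scenario 'global' requires params.global_pa")
        if scenario == "local" and params.inhibition_radius < 1:
            raise ConfigError("scenario 'local' requires params.inhibition_radius >= 1")
        if "dose_gy" not in sim and "surviving_fraction" not in sim:
            raise ConfigError("simulate needs dose_gy or surviving_fraction")
        if "dose_gy" in sim and "lq" not in sim:
            raise ConfigError("simulate with dose_gy needs an 'lq' {alpha, beta} block")
    clon = stages.get("clonogenic")
    if clon and "truth" not in clon:
        raise ConfigError("clonogenic stage needs a 'truth' block")
    qpcr = stages.get("qpcr")
    if qpcr and "control" not in qpcr:
        raise ConfigError("qpcr stage needs a 'control' condition")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    """Config echo for the manifest: stringify non-scalar keys, unwrap numpy."""
    if isinstance(obj, Mapping):
        return {
            (k if isinstance(k, (str, int, float, bool)) or k is None else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _run_clonogenic(block, seed, out_dir):
    truth = synthetic.CloneAssayTruth(**{**block["truth"], "seed": seed})
    table = synthetic.gen_clonogenic(truth)
    paths = [io.write_table(table, out_dir / "clonogenic.tsv")]
    fit_block = block.get("fit", {})
    records = [
        survival.ClonogenicRecord(r.dose_gy, r.cells_plated, r.colonies)
        for r in table.itertuples()
    ]
    params = survival.fit_lq(records, method=fit_block.get("method", "least_squares"))
    fit_path = out_dir / "lq_fit.json"
    fit_path.write_text(json.dumps(asdict(params), indent=2))
    paths.append(fit_path)
    return paths


def _run_growth(block, seed, out_dir):
    table = synthetic.gen_growth_trajectories(
        kind=block.get("kind", "invitro"),
        dose_specs={float(k): v for k, v in block["dose_specs"].items()},
        times=block["times"],
        n_subjects=block.get("n_subjects", 3),
        noise_sd=block.get("noise_sd", 0.0),
        seed=seed,
    )
    paths = [io.write_table(table, out_dir / "growth.tsv")]
    min_value = block.get("fit", {}).get("min_value", 0.0)
    fits = []
    for (dose, subj), g in table[~table["extinct"]].groupby(["dose_gy", "subject"]):
        try:
            fit = survival.fit_exponential_growth(
                g["time_days"], g["value"], min_value=min_value
            )
            fits.append(dict(dose_gy=dose, subject=subj, **asdict(fit)))
        except survival.InsufficientDataError:
            continue
    paths.append(io.write_table(pd.DataFrame(fits), out_dir / "growth_fits.tsv"))
    return paths


def _run_expression(block, seed, out_dir):
    de_genes = {
        g: {(float(d), float(day)): float(e) for (d, day), e in effects.items()}
        if isinstance(effects, Mapping)
        else effects
        for g, effects in block.get("de_genes", {}).items()
    }
    truth = synthetic.ExpressionTruth(
        n_genes=block.get("n_genes", 1000),
        de_genes=de_genes,
        noise_sd=block.get("noise_sd", 0.2),
        batch_shift={int(k): float(v) for k, v in block.get("batch_shift", {}).items()},
        seed=seed,
    )
    study = synthetic.gen_expression_study(truth)
    paths = list(
        io.write_expression_study(
            study, out_dir / "expression_matrix.tsv", out_dir / "expression_samples.tsv"
        )
    )
    screen_block = block.get("screen", {})
    processed = expression.preprocess(study)
    result = expression.anova_screen(
        processed,
        q=screen_block.get("q", 0.10),
        fc_threshold=screen_block.get("fc_threshold", 1.5),
    )
    paths.append(
        io.write_table(
            result.rename_axis("gene").reset_index(), out_dir / "de_screen.tsv"
        )
    )
    return paths


def _run_qpcr(block, seed, out_dir):
    table = synthetic.gen_qpcr(
        condition_dct=block["conditions"],
        sd=block.get("sd", 0.0),
        n=block.get("n", 3),
        seed=seed,
    )
    paths = [io.write_table(table, out_dir / "qpcr.tsv")]
    fc = expression.ddct_fold_change(table, block["control"])
    paths.append(
        io.write_table(fc.rename_axis("condition").reset_index(), out_dir / "qpcr_fold_change.tsv")
    )
    return paths


def _run_dye(block, seed, out_dir):
    fractions = {int(k): float(v) for k, v in block["truth"]["generation_fractions"].items()}
    truth = synthetic.DyeTruth(
        generation_fractions=fractions,
        mu0=block["truth"].get("mu0", 6.0),
        cv=block["truth"].get("cv", 0.15),
        n_cells=block["truth"].get("n_cells", 10000),
        seed=seed,
    )
    values = synthetic.gen_dye_intensities(truth)
    paths = [io.write_intensities(values, out_dir / "dye_intensities.txt")]
    fit_block = block.get("fit", {})
    profile = dye.fit_division_profile(
        values,
        reference_mu0=fit_block.get("reference_mu0", truth.mu0),
        n_generations=fit_block.get("n_generations", max(fractions) + 1),
    )
    out = {
        "fractions": profile.fractions.tolist(),
        "mu0": profile.mu0,
        "sigma": profile.sigma,
        "fl2_low": dye.fl2low_fraction(profile),
        "n_iter": profile.n_iter,
    }
    p = out_dir / "division_profile.json"
    p.write_text(json.dumps(out, indent=2))
    paths.append(p)
    return paths


def _run_simulate(block, seed, out_dir):
    params = automaton.CAParameters(**{**block.get("params", {}), "seed": seed})
    if "surviving_fraction" in block:
        s = float(block["surviving_fraction"])
    else:
        lq = survival.LQParameters(**block["lq"])
        s = float(survival.lq_surviving_fraction(lq, float(block["dose_gy"])))
    reps = int(block.get("reps", 1))
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    paths = []
    summaries = []
    for rep, s_rep in enumerate(seeds):
        res = automaton.run_scenario(
            replace(params, seed=int(s_rep)),
            n0=int(block.get("n0", 10000)),
            dose_spec=(s, params.p_s),
            scenario=block.get("scenario", "none"),
            t_max=int(block.get("t_max", 120)),
            detection_size=int(block.get("detection_size", 2000)),
        )
        paths.append(
            io.write_table(res.trajectory, out_dir / f"trajectory_rep{rep}.tsv")
        )
        hist = res.final_state.dormancy_histogram().rename_axis("dormancy_days")
        paths.append(
            io.write_table(
                hist.rename("cells").reset_index(), out_dir / f"dormancy_rep{rep}.tsv"
            )
        )
        summaries.append(
            {
                "rep": rep,
                "seed": int(s_rep),
                "extinct": res.extinct,
                "rate": res.growth_fit.rate if res.growth_fit else None,
                "r_squared": res.growth_fit.r_squared if res.growth_fit else None,
                "dormancy_ge4": automaton.dormancy_fraction(res.final_state, 4),
            }
        )
    p = out_dir / "simulation_summary.json"
    p.write_text(json.dumps(summaries, indent=2))
    paths.append(p)
    return paths


_RUNNERS = {
    "clonogenic": _run_clonogenic,
    "growth": _run_growth,
    "expression": _run_expression,
    "qpcr": _run_qpcr,
    "dye": _run_dye,
    "simulate": _run_simulate,
}


def run_pipeline(config, out_dir=None) -> dict:
    """Validate, execute the requested stages, and write a JSON manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory). Fixed config + seed reproduce byte-identical
    outputs, which the manifest's content hashes make checkable.
    """
    config = load_config(config)
    validate_config(config)
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    global_seed = int(config["seed"])
    t0 = time.time()
    outputs = {}
    seeds = {}
    for stage in _STAGE_ORDER:
        if stage not in config["stages"]:
            continue
        seed = stage_seed(global_seed, stage)
        seeds[stage] = seed
        stage_dir = out_dir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        paths = _RUNNERS[stage](config["stages"][stage], seed, stage_dir)
        outputs[stage] = {
            str(p.relative_to(out_dir)): _sha256(p) for p in paths
        }
    import regrowth

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": _jsonable(config),
        "global_seed": global_seed,
        "stage_seeds": seeds,
        "outputs": outputs,
        "versions": {
            "regrowth": regrowth.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
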