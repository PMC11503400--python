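"""End-to-end pipeline orchestration from a config file.

Stages: ``simulate`` (synthetic cohort), ``featureize`` (ROI time
series -> connectivity features), ``fit`` (design + cross-validated
penalized Poisson fits) and ``interpret`` (importance, effect tables
and curves). A run manifest is always written, even on failure,
recording how far the pipeline got; identical config + seed reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import cohort_features, read_subject_timeseries
from .cv import ALPHA_GRID, GAMMA_GRID, cv_fit, select
from .design import SplineDesign
from .interpret import baseline, deviance_r2, effect_curve, effect_table, importance
from .synthetic import (
    DEFAULT_EFFECTS,
    DEFAULT_MARGINALS,
    OUTCOME_COLUMN,
    GeneratorSpec,
    centered_log_effects,
    full_term_list,
    generate_dataset,
    write_subject_table,
)

__all__ = ["validate_config", "run_pipeline", "load_config"]

STAGES = ("simulate", "featureize", "fit", "interpret")
FAMILIES = ("lasso", "mcp", "scad")

DEFAULTS = {
    "n_subjects": 2000,
    "terms": "all",
    "families": ["lasso"],
    "alpha_grid": list(ALPHA_GRID),
    "gamma_grid": list(GAMMA_GRID),
    "k": 10,
    "rule": "1se",
    "n_lambda": 100,
    "lambda_min_ratio": 0.01,
    "basis_df": 5,
    "effects": "default",
    "fc_correlation": 0.2,
    "outcome_cap": None,
    "stages": ["simulate", "fit", "interpret"],
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _merged(config: Mapping) -> dict:
    out = dict(DEFAULTS)
    out.update(config)
    return out


def validate_config(config: Mapping) -> list[str]:
    """Structural and range checks; returns a list of problems (empty
    means valid). Never raises and never mutates."""
    problems: list[str] = []
    cfg = _merged(config)
    if "seed" not in config:
        problems.append("seed is required")
    for a in cfg.get("alpha_grid", []):
        if not (isinstance(a, (int, float)) and 0.0 <= a <= 1.0):
            problems.append(f"alpha outside [0,1]: {a}")
    fams = cfg.get("families", [])
    for fam in fams:
        if fam not in FAMILIES:
            problems.append(f"unknown family {fam!r}")
    for g in cfg.get("gamma_grid", []):
        if "mcp" in fams and not g > 2:
            problems.append(f"gamma must exceed 2 for MCP (got {g})")
        if "scad" in fams and not g > 3:
            problems.append(f"gamma must exceed 3 for SCAD (got {g})")
    if cfg.get("k", 10) < 2:
        problems.append("k must be >= 2")
    if cfg.get("rule") not in ("min", "1se"):
        problems.append(f"unknown selection rule {cfg.get('rule')!r}")
    if cfg.get("n_subjects", 1) < 1:
        problems.append("n_subjects must be >= 1")
    for st in cfg.get("stages", []):
        if st not in STAGES:
            problems.append(f"unknown stage {st!r}")
    if "featureize" in cfg.get("stages", []):
        fz = cfg.get("featureize_inputs")
        if not fz:
            problems.append("featureize stage enabled but no featureize_inputs")
        else:
            for key in ("subjects", "labels"):
                if key not in fz:
                    problems.append(f"featureize_inputs missing {key!r}")
            for sid, paths in (fz.get("subjects") or {}).items():
                for p in paths.values():
                    if not Path(p).exists():
                        problems.append(f"missing input file for {sid}: {p}")
    terms = cfg.get("terms")
    if terms != "all" and not isinstance(terms, (list, dict)):
        problems.append("terms must be 'all', a list, or a name->type mapping")
    return problems


def _stage_seed(seed: int, stage: str) -> int:
    """Fixed derivation of per-stage seeds from the global seed."""
    h = np.random.SeedSequence((int(seed), STAGES.index(stage)))
    return int(h.generate_state(1)[0] % (2**31))


def _parse_effects(spec: object) -> dict:
    if spec == "default" or spec is None:
        return dict(DEFAULT_EFFECTS)
    if not isinstance(spec, Mapping):
        raise ValueError("effects must be 'default' or a mapping")
    out: dict[str, object] = {}
    for term, eff in spec.items():
        if isinstance(eff, Mapping) and "type" in eff:
            kind = eff["type"]
            if kind == "tanh":
                s = float(eff.get("scale", 1.0))
                c = float(eff.get("center", 0.0))
                w = float(eff.get("width", 1.0))
                out[term] = (
                    lambda x, s=s, c=c, w=w: s * np.tanh((x - c) / w)
                )
            elif kind == "linear":
                b = float(eff.get("slope", 1.0))
                out[term] = lambda x, b=b: b * np.asarray(x, float)
            else:
                raise ValueError(f"unknown numeric effect type {kind!r}")
        elif isinstance(eff, Mapping):
            # per-level multiplicative effects, centered under marginals
            out[term] = centered_log_effects(eff, DEFAULT_MARGINALS[term])
        else:
            raise ValueError(f"bad effect spec for {term!r}")
    return out


def _resolve_terms(terms: object) -> dict[str, str] | list[str]:
    if terms == "all":
        return full_term_list()
    if isinstance(terms, Mapping):
        return dict(terms)
    return list(terms)


def run_pipeline(config: Mapping, out_dir: str | Path, seed: int | None = None):
    """Run the enabled stages, writing all artifacts under ``out_dir``.

    Returns the output directory. Raises on the first failing stage;
    the manifest still records how far the run got.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg = _merged(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("netpoisson")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)

    cfg_json = json.dumps(
        {k: v for k, v in cfg.items() if k != "featureize_inputs"},
        sort_keys=True, default=str,
    )
    manifest = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "netpoisson": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages_completed": [],
        "error": None,
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    stages = cfg["stages"]
    table = None
    design = None
    y = None
    selections = None
    try:
        if "simulate" in stages:
            log.info("stage simulate: n=%d", cfg["n_subjects"])
            gspec = GeneratorSpec(
                n_subjects=int(cfg["n_subjects"]),
                seed=_stage_seed(seed, "simulate"),
                effect_spec=_parse_effects(cfg["effects"]),
                fc_correlation=cfg["fc_correlation"],
                outcome_cap=cfg["outcome_cap"],
            )
            if isinstance(cfg.get("intercept"), (int, float)):
                gspec.intercept_log_scale = math.log(float(cfg["intercept"]))
            table = generate_dataset(gspec)
            write_subject_table(table, out / "subjects.csv")
            manifest["stages_completed"].append("simulate")

        if "featureize" in stages:
            fz = cfg["featureize_inputs"]
            subjects = {
                sid: read_subject_timeseries(
                    p["timeseries"], p["fd"], fz["labels"]
                )
                for sid, p in fz["subjects"].items()
            }
            feats = cohort_features(subjects, log=log.info)
            feats.to_csv(out / "features.csv", index_label="subject")
            manifest["stages_completed"].append("featureize")

        if "fit" in stages:
            if table is None:
                from .synthetic import read_subject_table

                table = read_subject_table(out / "subjects.csv")
            terms = _resolve_terms(cfg["terms"])
            design = (
                SplineDesign(terms=terms, basis_df=int(cfg["basis_df"]))
                .fit(table)
                .design(table)
            )
            y = table[OUTCOME_COLUMN].to_numpy(dtype=float)
            fold_seed = _stage_seed(seed, "fit")
            summaries = []
            selections = {}
            for fam in cfg["families"]:
                log.info("stage fit: family=%s", fam)
                cv = cv_fit(
                    design.X, y, design.group_index, family=fam,
                    alpha_grid=cfg["alpha_grid"],
                    gamma_grid=cfg["gamma_grid"], k=int(cfg["k"]),
                    seed=fold_seed, n_lambda=int(cfg["n_lambda"]),
                    lambda_min_ratio=float(cfg["lambda_min_ratio"]),
                    group_weights=design.group_weights(),
                )
                df = cv.summary_frame()
                df.insert(0, "family_run", fam)
                summaries.append(df)
                spec, path, sol = select(cv, rule=cfg["rule"])
                path.to_json(out / f"fit_{fam}.json")
                selections[fam] = (spec, sol)
            pd.concat(summaries).to_csv(out / "cv_results.csv", index=False)
            manifest["stages_completed"].append("fit")

        if "interpret" in stages:
            if selections is None:
                raise RuntimeError("interpret stage requires the fit stage")
            summary = {}
            for fam, (spec, sol) in selections.items():
                vi = importance(sol, design.X)
                vi.to_csv(out / f"importance_{fam}.csv",
                          index_label="term", header=["importance"])
                for term in sol.active_groups:
                    ttype = design.term_types[term]
                    if ttype == "numeric":
                        curve = effect_curve(sol, design, term)
                        curve.as_frame().to_csv(
                            out / f"curve_{fam}_{term}.csv", index=False
                        )
                    else:
                        eff = effect_table(sol, design, term)
                        eff.to_csv(out / f"effects_{fam}_{term}.csv",
                                   index_label="level", header=["effect"])
                summary[fam] = {
                    "family": spec.family,
                    "alpha": spec.alpha,
                    "gamma": spec.gamma,
                    "lambda": spec.lam,
                    "baseline": baseline(sol),
                    "deviance_r2_pct": deviance_r2(sol, design.X, y),
                    "active_terms": [str(t) for t in sol.active_groups],
                }
            (out / "summary.json").write_text(json.dumps(summary, indent=1))
            manifest["stages_completed"].append("interpret")
    except Exception as e:  # noqa: BLE001 - manifest must record failures
        manifest["error"] = f"{type(e).__name__}: {e}"
        log.error("pipeline failed: %s", manifest["error"])
        raise
    finally:
        _write_manifest()
        log.removeHandler(handler)
        handler.close()
    return out
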