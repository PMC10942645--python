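"""Configuration, file formats, and pipeline orchestration.

All tables are delimited text (CSV): trial schedules/records with one row
per trial, pattern sets in long format with one row per (subject, run,
condition, voxel) plus a residual-covariance sidecar.  Results are JSON.
Angles are degrees, RT in ms, run/trial indices 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_sim import BehaviorGenParams
from .neural_sim import NeuralGenParams, PatternSet

log = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "subject", "group", "mapping", "session", "run", "trial",
    "conflict_type", "congruency", "direction", "polar_angle_deg",
    "correct_response",
]
TRIAL_RESULT_COLUMNS = ["rt", "accuracy"]
PATTERN_COLUMNS = [
    "region", "subject", "run", "conflict_type", "congruency", "direction",
    "voxel", "beta",
]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {missing}")
    # derived context columns (previous-trial fields) legitimately hold NaN
    # on run-initial trials, so only the required columns must be finite
    numeric = df[required].select_dtypes(include=[np.number])
    bad = numeric.columns[~np.isfinite(numeric).all()].tolist()
    if bad:
        raise SchemaError(f"{what} has non-finite values in column(s): {bad}")


def write_trials(trials: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS + TRIAL_RESULT_COLUMNS if c in trials]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = TRIAL_COLUMNS + (
        TRIAL_RESULT_COLUMNS if "rt" in df.columns or "accuracy" in df.columns else []
    )
    _check_columns(df, required, f"trial table {path}")
    return df


def write_patterns(ps: PatternSet, path) -> None:
    """Long-format pattern table plus a `<stem>_cov.csv` covariance sidecar."""
    path = Path(path)
    flat, meta = ps.flat()
    n, v = flat.shape
    long = meta.loc[meta.index.repeat(v)].reset_index(drop=True)
    long = long[["subject", "group", "run", "conflict_type", "congruency", "direction"]]
    long.insert(0, "region", ps.region)
    long["voxel"] = np.tile(np.arange(v), n)
    long["beta"] = flat.reshape(-1)
    long.to_csv(path, index=False)
    covs = []
    for r in range(ps.residual_cov.shape[0]):
        c = pd.DataFrame(ps.residual_cov[r])
        c.insert(0, "run", r)
        covs.append(c)
    pd.concat(covs).to_csv(path.with_name(path.stem + "_cov.csv"), index=False)


def read_patterns(path) -> PatternSet:
    """Rebuild a PatternSet from the long table (requires a full crossing)."""
    from .task_design import SubjectProfile, conditions
    from .neural_sim import condition_metadata

    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, PATTERN_COLUMNS, f"pattern table {path}")
    region = df["region"].iloc[0]
    subjects = np.sort(df["subject"].unique())
    runs = np.sort(df["run"].unique())
    voxels = np.sort(df["voxel"].unique())
    conds = conditions()
    key = df["conflict_type"] + "|" + df["congruency"] + "|" + df["direction"]
    cond_key = {
        f"{c.conflict_type.name}|{c.congruency}|{c.direction}": i
        for i, c in enumerate(conds)
    }
    df["cond_index"] = key.map(cond_key)
    expected = len(subjects) * len(runs) * len(conds) * len(voxels)
    if len(df) != expected or df["cond_index"].isna().any():
        have = set(zip(df["subject"], df["run"], df["cond_index"]))
        missing = [
            (s, r, i)
            for s in subjects
            for r in runs
            for i in range(len(conds))
            if (s, r, i) not in have
        ]
        raise SchemaError(
            f"pattern table {path} has an incomplete condition crossing; "
            f"missing (subject, run, condition): {missing[:10]}"
        )
    betas = np.zeros((len(subjects), len(runs), len(conds), len(voxels)))
    sidx = {s: i for i, s in enumerate(subjects)}
    betas[
        df["subject"].map(sidx), df["run"], df["cond_index"].astype(int), df["voxel"]
    ] = df["beta"]
    cov_path = path.with_name(path.stem + "_cov.csv")
    if cov_path.exists():
        cov_df = pd.read_csv(cov_path)
        v = len(voxels)
        cov = np.stack(
            [cov_df[cov_df["run"] == r].iloc[:, 1:].to_numpy() for r in runs]
        )
    else:
        cov = np.stack([np.eye(len(voxels))] * len(runs))
    if "group" not in df:
        raise SchemaError("pattern table needs a 'group' column")
    metas = []
    for s in subjects:
        grp = df.loc[df["subject"] == s, "group"].iloc[0]
        prof = SubjectProfile(int(s), grp)
        for r in runs:
            m = condition_metadata(prof)
            m["run"] = r
            metas.append(m)
    meta = pd.concat(metas, ignore_index=True)
    meta = meta.sort_values(["subject", "run", "cond_index"]).reset_index(drop=True)
    return PatternSet(region, betas, meta, cov)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "experiment": "exp2",
    "n_subjects": 35,
    "group_split": 17,
    "seed": 0,
    "behavior": {},  # overrides for BehaviorGenParams
    "neural": {"noise_sd": 0.4},  # overrides for NeuralGenParams
    "analysis": {
        "proximity_control": False,
        "session_interaction": False,
        "congruency_split": True,
        "model_comparison_variant": "full",
        "alpha": 0.05,
    },
    # per-SD modulation of each subject's neural conflict weight by their
    # behavioral similarity slope (0 decouples brain and behavior)
    "brain_behavior_coupling": 0.6,
    "out_dir": "results",
}


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(_jsonable(obj), f, indent=2, allow_nan=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict) -> dict:
    """Simulate -> behavioral CSE -> RSA -> model comparison -> connectivity.

    Writes per-stage CSV tables, a JSON summary and a run log under
    cfg['out_dir'] and returns the summary dict.
    """
    from . import behavior_cse, behavior_sim, model_space, rep_connectivity, rsa_core
    from . import neural_sim, task_design

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("conflictspace")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary = {"version": __version__, "config": cfg}
    stage = "setup"
    try:
        log.info("pipeline start (version %s, seed %s)", __version__, cfg["seed"])
        profiles = task_design.make_profiles(cfg["n_subjects"], cfg["group_split"])
        stage = "simulate-behavior"
        sched = task_design.build_experiment(
            {"experiment": cfg["experiment"], "seed": cfg["seed"]}, profiles
        )
        bparams = BehaviorGenParams(**{"seed": cfg["seed"] + 1, **cfg["behavior"]})
        trials = behavior_sim.simulate_trials(bparams, sched)
        write_trials(trials, out_dir / "trials.csv")
        stage = "analyze-cse"
        ana = cfg["analysis"]
        cse_report = {}
        behav_slopes = None
        for measure in ("RT", "ER"):
            cells = behavior_cse.cse_cells(trials, measure)
            fit = behavior_cse.fit_one_stage(
                cells, proximity_control=ana.get("proximity_control", False)
            )
            cse_report[measure] = {
                **fit.slope,
                "bic": fit.model.bic,
                "loglik": fit.model.llf,
                "converged": fit.model.converged,
            }
            if measure == "RT":
                behav_slopes = fit.per_subject_slopes
        _, cong_group = behavior_cse.congruency_effect_summary(trials)
        summary["behavior"] = cse_report
        summary["congruency_effects"] = cong_group
        stage = "simulate-neural"
        coupling = cfg.get("brain_behavior_coupling", 0.0)
        scale = None
        if coupling and behav_slopes is not None and behav_slopes.std() > 0:
            z = (behav_slopes - behav_slopes.mean()) / behav_slopes.std()
            scale = np.clip(
                1.0 + coupling * z.reindex(sorted(z.index)).to_numpy(), 0.1, None
            )
        nparams = NeuralGenParams(
            **{
                "n_subjects": cfg["n_subjects"],
                "group_split": cfg["group_split"],
                "seed": cfg["seed"] + 2,
                "subject_conflict_scale": scale,
                **cfg["neural"],
            }
        )
        regions = neural_sim.simulate_region_cohort(nparams, profiles)
        write_patterns(next(iter(regions.values())), out_dir / "patterns_example.csv")
        stage = "run-rsa"
        region_results = {}
        designs = {}
        fits = {}
        for name, ps in regions.items():
            normed = rsa_core.normalize_patterns(ps)
            rsm = rsa_core.build_rsm(normed)
            cells = rsa_core.select_cross_subject_cells(rsm)
            design = rsa_core.build_rsa_design(cells)
            designs[name] = design
            fit = rsa_core.fit_rsa(design, region=name)
            fits[name] = fit
            rr = {
                "p1": fit.regressor("conflict_similarity")["p_one_tailed"],
                "per_subject_effect": fit.per_subject_effect,
            }
            if ana.get("congruency_split", True):
                split = rsa_core.congruency_split_rsa(design, region=name)
                rr["p_interaction"] = split.interaction["p_one_tailed"]
            region_results[name] = rr
        screen = rsa_core.screen_regions(
            region_results, behav_slopes, alpha=ana.get("alpha", 0.05)
        )
        summary["region_screen"] = screen
        stage = "compare-models"
        eff = (
            summary["congruency_effects"]
            .query("measure == 'RT'")
            .set_index("conflict_type")["group_mean"]
        )
        models = model_space.build_similarity_models(eff)
        target_region = screen.loc[screen["pass_all"], "region"]
        target_region = (
            target_region.iloc[0] if len(target_region) else "conflict_dlpfc"
        )
        cmp_res = model_space.compare_models_bic(
            designs[target_region], models,
            variant=ana.get("model_comparison_variant", "full"),
        )
        avg = model_space.average_rsm_by_conflict_type(designs[target_region])
        summary["model_comparison"] = {
            "region": target_region,
            "table": cmp_res.table,
            "winner": cmp_res.winning_model,
            "participation_ratio": model_space.participation_ratio(avg),
            "participation_ratio_clipped": model_space.participation_ratio(
                avg, clip_negative=True
            ),
        }
        stage = "connectivity"
        target_rsms = rep_connectivity.within_subject_rsm(regions[target_region])
        cand, ctrl = {}, {}
        for name, ps in regions.items():
            if name == target_region:
                continue
            res = rep_connectivity.representational_connectivity(
                target_rsms, rep_connectivity.within_subject_rsm(ps),
                target=target_region, predictor=name,
            )
            (ctrl if name.startswith("control") or name == "orient_no_boost" else cand)[
                name
            ] = res
        conn = rep_connectivity.connectivity_screen(cand, ctrl)
        summary["connectivity"] = conn
        write_json(summary, out_dir / "summary.json")
        log.info("pipeline done")
    except Exception as e:  # noqa: BLE001
        log.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary
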