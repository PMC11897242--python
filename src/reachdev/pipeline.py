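"""End-to-end pipeline: simulate -> qc -> extract -> epochs -> fits -> centiles.

A single YAML/JSON config with blocks ``{cohort, paradigm_overrides, qc,
fits, centiles}`` drives all stages from one top-level seed; rerunning
the same config reproduces every artifact byte-identically (logs carry
timestamps, data files do not).  Adults (age >= 216 months) are included
in summaries but excluded from developmental curve fits and centile
estimation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agecurves import fit_exponential, fit_inverse, fit_log, select_model
from .cohort import ADULT_AGE_MO, CohortConfig, simulate_cohort
from .epochs import epoch_means, extract_epochs
from .io import QCPolicy, apply_qc, read_sessions, write_sessions
from .kinematics import measures_table
from .lms import DEFAULT_LEVELS, fit_lms, select_family

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "task": "pushball",
    "cohort": {
        "n_participants": 50,
        "age_range_mo": [36.0, 216.0],
        "seed": 0,
    },
    "paradigm_overrides": {},
    "qc": {
        "max_session_minutes": 120.0,
        "min_median_polling_hz": 20.0,
        "completion_required": True,
    },
    "fits": [
        {"measure": "initial_angle_deg", "epoch": "end_learning", "models": ["inverse", "logarithmic"]},
        {"measure": "final_angle_deg", "epoch": "end_learning", "models": ["inverse", "logarithmic"]},
        {"measure": "compensation_angle_deg", "epoch": "end_learning", "models": ["exponential"]},
    ],
    "centiles": {
        "measure": "initial_angle_deg",
        "epoch": "end_learning",
        "families": ["NO", "BCCG"],
        "df": [1, 3, 3],
        "levels": list(DEFAULT_LEVELS),
        "exclude": [],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    """Load a YAML (or JSON) config file and merge it over the defaults."""
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


_FITTERS = {"inverse": fit_inverse, "logarithmic": fit_log, "exponential": fit_exponential}


def _fit_block(epochs_df: pd.DataFrame, fit_cfg: dict) -> dict:
    surface = epoch_means(epochs_df, fit_cfg["measure"], fit_cfg["epoch"])
    children = surface[surface["age_mo"] < ADULT_AGE_MO]
    age = children["age_mo"].to_numpy()
    y = children[fit_cfg["measure"]].to_numpy()
    fits = []
    for model in fit_cfg["models"]:
        try:
            f = _FITTERS[model](age, y)
        except (RuntimeError, ValueError) as err:
            log.warning("fit %s/%s/%s failed: %s", fit_cfg["measure"], fit_cfg["epoch"], model, err)
            continue
        fits.append(f)
    entry = {
        "measure": fit_cfg["measure"],
        "epoch": fit_cfg["epoch"],
        "n": int(age.size),
        "fits": [
            {
                "model": f.model,
                "a": f.a,
                "b": f.b,
                "ci_a": list(f.ci_a),
                "ci_b": list(f.ci_b),
                "adj_r2": f.adj_r2,
            }
            for f in fits
        ],
    }
    if len(fits) >= 2:
        entry["selected"] = select_model(fits).model
    elif fits:
        entry["selected"] = fits[0].model
    return entry


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute every stage and write the artifact directory.

    Returns a dict of artifact paths.  Any stage failure raises with the
    stage name; artifacts written before the failure are retained.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        config["cohort"]["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    task = config["task"]

    stage = "validate"
    try:
        cohort = CohortConfig(
            n_participants=int(config["cohort"]["n_participants"]),
            age_range_mo=tuple(config["cohort"].get("age_range_mo", (36.0, 216.0))),
            ages_mo=config["cohort"].get("ages_mo"),
            seed=int(config["cohort"]["seed"]),
            **{
                k: float(config["cohort"][k])
                for k in (
                    "inverse_curve_a_deg",
                    "inverse_curve_b_deg_mo",
                    "fa_curve_a_deg",
                    "fa_curve_b_deg_mo",
                    "ia_target_sd_deg",
                    "fa_target_sd_deg",
                )
                if k in config["cohort"]
            },
        )

        stage = "simulate"
        sessions = simulate_cohort(cohort, task)
        paths["sessions"] = outdir / "sessions.jsonl"
        write_sessions(sessions, paths["sessions"])
        log.info("simulate: %d sessions (%s)", len(sessions), task)

        stage = "qc"
        policy = QCPolicy(**config["qc"])
        kept, report = apply_qc(sessions, policy)
        paths["qc_report"] = outdir / "qc_report.json"
        paths["qc_report"].write_text(json.dumps(report, indent=2))
        log.info("qc: kept %d / %d", len(kept), len(sessions))

        stage = "extract"
        measures = measures_table(kept)
        paths["measures"] = outdir / "measures.csv"
        measures.to_csv(paths["measures"], index=False)
        log.info("extract: %d trial rows", len(measures))

        stage = "epochs"
        epochs_df = extract_epochs(measures)
        paths["epochs"] = outdir / "epochs.csv"
        epochs_df.to_csv(paths["epochs"], index=False)
        log.info("epochs: %d summary rows", len(epochs_df))

        stage = "fits"
        fit_report = [_fit_block(epochs_df, fc) for fc in config["fits"]]
        paths["fits"] = outdir / "fits.json"
        paths["fits"].write_text(json.dumps(fit_report, indent=2))
        log.info("fits: %d measure/epoch blocks", len(fit_report))

        stage = "centiles"
        ccfg = config["centiles"]
        surface = epoch_means(epochs_df, ccfg["measure"], ccfg["epoch"])
        surface = surface[surface["age_mo"] < ADULT_AGE_MO]
        excluded = set(ccfg.get("exclude") or [])
        if excluded:
            surface = surface[~surface["participant_id"].isin(excluded)]
        age = surface["age_mo"].to_numpy()
        y = surface[ccfg["measure"]].to_numpy()
        best, aic_report = select_family(age, y, ccfg["families"], tuple(ccfg["df"]))
        grid = np.arange(np.ceil(age.min()), np.floor(age.max()) + 1.0)
        table = best.centiles(grid, ccfg["levels"])
        paths["centiles"] = outdir / "centiles.csv"
        table.to_csv(paths["centiles"], index=False)
        moments = best.residual_moments(age, y)
        paths["lms_report"] = outdir / "lms_report.json"
        paths["lms_report"].write_text(
            json.dumps(
                {
                    "measure": ccfg["measure"],
                    "epoch": ccfg["epoch"],
                    "family": best.family_used_,
                    "n": best.n_,
                    "edf": best.edf_,
                    "aic_table": aic_report.to_dict(orient="records"),
                    "residual_moments": moments.to_dict(orient="records"),
                },
                indent=2,
            )
        )
        log.info("centiles: family %s on %d children", best.family_used_, best.n_)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {k: str(v) for k, v in paths.items()}
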