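"""End-to-end orchestration: simulate -> thin -> select -> fit -> map -> detectors.

One YAML config drives every stage; each stage reads only the previous
stages' files, writes CSV/ASCII-raster artifacts into the output directory,
and derives its own seed from the master seed and the stage name (so adding a
stage never perturbs earlier stages' randomness). Re-running with the same
config reproduces byte-identical CSV outputs and raster values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import occdata, opgd, sdm, synthland, varselect
from .grids import CovariateStack, GridSpec, read_ascii_grid, write_ascii_grid
from .learners import ROSTER
from .sdm import GateFailureError, SuitabilityMap

__all__ = ["RunConfig", "run_all", "stage_seed", "read_raster", "write_raster"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "thin", "select", "fit", "map", "opgd")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, independent across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# thin wrappers so callers go through the pipeline module for raster I/O
def read_raster(path):
    return read_ascii_grid(path)


def write_raster(values, grid: GridSpec, path):
    return write_ascii_grid(values, grid, path)


@dataclass
class RunConfig:
    """All pipeline settings; defaults follow the reference study design."""

    out_dir: str = "run"
    seed: int = 0
    # inputs (ignored when the simulate stage is enabled)
    stack_manifest: str | None = None
    occurrences: str | None = None
    # simulate stage
    simulate: dict | None = None
    # varselect
    r_threshold: float = 0.8
    vif_threshold: float = 10.0
    # sdm
    roster: tuple = ROSTER
    n_pseudoabsences: int = 1000
    k_folds: int = 10
    repetitions: int = 10
    holdout: float = 0.2
    gate_auc: float = 0.9
    gate_tss: float = 0.8
    weight_metric: str = "TSS"
    # opgd
    methods: tuple = opgd.METHODS
    k_min: int = 3
    k_max: int = 7
    alpha: float = 0.05
    min_stratum: int = 10
    opgd_sample: int | None = None
    n_response_points: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.roster = tuple(cfg.roster)
        cfg.methods = tuple(cfg.methods)
        if not (0 < cfg.holdout < 1):
            raise ValueError("holdout must be in (0,1)")
        if not (0 < cfg.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if cfg.k_min > cfg.k_max:
            raise ValueError("k_min must not exceed k_max")
        return cfg


DEFAULT_SIMULATE = {
    "n_rows": 40,
    "n_cols": 40,
    "cell_size": 2.5 / 60,  # 2.5 arc-minute cells
    "n_presence": 150,
    "variables": [
        {"name": "bio_temp", "family": "bioclim", "smoothness": 4.0},
        {"name": "bio_prec", "family": "bioclim", "smoothness": 4.0},
        # engineered collinear pair: flagged by the |r|>0.8 screen and strong
        # enough (pairwise VIF = 1/(1-rho^2) > 10) for stepwise VIF to remove
        # one member
        {"name": "bio_temp_range", "family": "bioclim", "smoothness": 4.0,
         "partner": "bio_temp", "rho": 0.96},
        {"name": "slope", "family": "topo", "smoothness": 2.0},
        {"name": "ndvi", "family": "vegetation", "smoothness": 3.0},
        {"name": "human_footprint", "family": "human", "smoothness": 3.0},
    ],
    # low prevalence (mean p ~ 0.1) and a dominant climatic driver: typical of
    # an invasive pest whose suitable range is a modest fraction of the grid
    "model": {
        "linear_coefs": {"bio_temp": 4.0, "ndvi": 0.7, "bio_prec": 0.4},
        "step_var": "slope",
        "step_breaks": [-0.5, 0.6],
        "step_levels": [-1.2, 0.0, 1.2],
        "interaction": ["bio_temp", "human_footprint", 0.5],
        "intercept": -6.0,
        "noise_sd": 0.4,
    },
}


def _simulate_stage(cfg: RunConfig, out: Path, manifest: dict):
    sim = {**DEFAULT_SIMULATE, **(cfg.simulate or {})}
    grid = GridSpec(n_rows=sim["n_rows"], n_cols=sim["n_cols"], cell_size=sim["cell_size"])
    specs = [synthland.VarSpec(**v) for v in sim["variables"]]
    seed = stage_seed(cfg.seed, "simulate")
    stack = synthland.make_stack(grid, specs, seed=seed)
    model_kwargs = dict(sim["model"])
    for key in ("step_breaks", "step_levels"):
        if key in model_kwargs:
            model_kwargs[key] = tuple(model_kwargs[key])
    if model_kwargs.get("interaction"):
        model_kwargs["interaction"] = tuple(model_kwargs["interaction"])
    model = synthland.TrueModel(**model_kwargs)
    p = synthland.true_suitability(stack, model, seed=seed + 1)
    occ = synthland.sample_occurrences(p, stack, sim["n_presence"], seed=seed + 2)
    stack_path = stack.write(out / "stack")
    occ.to_csv(out / "occurrences.csv", index=False)
    manifest["stages"]["simulate"] = {
        "seed": seed, "n_cells": int(stack.mask.sum()), "n_presence": len(occ),
    }
    return stack, stack_path, occ


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest.

    On stage failure, partial outputs are kept and a FAILED marker naming the
    stage is written before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    current = "simulate"
    try:
        # ---- simulate / load -------------------------------------------
        if config.simulate is not None or config.stack_manifest is None:
            stack, stack_path, occ_raw = _simulate_stage(config, out, manifest)
        else:
            stack = CovariateStack.read(config.stack_manifest)
            stack_path = Path(config.stack_manifest)
            occ_raw = occdata.load_occurrences(config.occurrences)
            manifest["stages"]["simulate"] = {"skipped": True}

        # ---- thin -------------------------------------------------------
        current = "thin"
        seed = stage_seed(config.seed, "thin")
        occ = occdata.filter_to_mask(occ_raw, stack)
        thinned = occdata.thin_to_grid(occ, stack.grid, seed=seed)
        thinned.to_csv(out / "thinned.csv", index=False)
        manifest["stages"]["thin"] = {
            "seed": seed, "loaded": len(occ_raw), "in_area": len(occ),
            "thinned": len(thinned),
        }
        log.info("thin: %d -> %d records", len(occ_raw), len(thinned))

        # ---- select -----------------------------------------------------
        current = "select"
        cells = stack.table()
        report = varselect.vif_stepwise(
            cells, vif_threshold=config.vif_threshold, r_threshold=config.r_threshold
        )
        report.corr_matrix.to_csv(out / "correlation_matrix.csv")
        pd.DataFrame(report.elimination_order, columns=["variable", "vif"]).to_csv(
            out / "elimination_log.csv", index=False
        )
        pd.DataFrame({"variable": report.retained}).to_csv(out / "retained.csv", index=False)
        manifest["stages"]["select"] = {
            "candidates": cells.shape[1], "retained": len(report.retained),
            "flagged_pairs": len(report.flagged_pairs),
        }
        log.info("select: %d -> %d variables", cells.shape[1], len(report.retained))

        # ---- fit --------------------------------------------------------
        current = "fit"
        seed = stage_seed(config.seed, "fit")
        pa = sdm.generate_pseudoabsences(stack, thinned, n=config.n_pseudoabsences, seed=seed)
        X, y = sdm.build_training_table(stack, thinned, pa, variables=report.retained)
        ens, cv, mean_metrics, heldout = sdm.fit_sdm(
            X, y, roster=config.roster, k=config.k_folds,
            repetitions=config.repetitions, holdout=config.holdout,
            gate=(config.gate_auc, config.gate_tss),
            weight_metric=config.weight_metric, seed=seed,
        )
        cv.to_csv(out / "evaluation.csv", index=False)
        imp = sdm.variable_importance(ens, X, n_perm=3, seed=seed)
        imp.rename("importance").rename_axis("variable").to_csv(out / "importance.csv")
        curves = []
        for var in X.columns:
            c = sdm.response_curve(ens, var, X, n_points=config.n_response_points)
            c.insert(0, "variable", var)
            curves.append(c)
        pd.concat(curves, ignore_index=True).to_csv(out / "response_curves.csv", index=False)
        manifest["stages"]["fit"] = {
            "seed": seed, "n_rows": len(X), "members": sorted(ens.weights),
            "weights": {k: round(w, 6) for k, w in ens.weights.items()},
            "heldout_auc": heldout.auc, "heldout_tss": heldout.tss,
        }
        log.info("fit: %d/%d learners passed the gate", len(ens.members), len(config.roster))

        # ---- map --------------------------------------------------------
        current = "map"
        smap = sdm.predict_map(ens, stack)
        write_ascii_grid(smap.values, stack.grid, out / "suitability.asc")
        manifest["stages"]["map"] = {
            "min": int(smap.values[smap.values >= 0].min()),
            "max": int(smap.values.max()),
            "mean": float(smap.values[smap.values >= 0].mean()),
        }

        # ---- opgd -------------------------------------------------------
        current = "opgd"
        seed = stage_seed(config.seed, "opgd")
        suit = smap.values.astype(float).ravel()[cells.index.to_numpy()] / 1000.0
        det = cells[report.retained]
        if config.opgd_sample is not None and config.opgd_sample < len(det):
            rng = np.random.default_rng(seed)
            pick = np.sort(rng.choice(len(det), size=config.opgd_sample, replace=False))
            det = det.iloc[pick]
            suit = suit[pick]
        k_range = range(config.k_min, config.k_max + 1)
        disc_rows, factor_rows, strata = [], [], {}
        for var in det.columns:
            cands = opgd.evaluate_candidates(det[var].to_numpy(), suit,
                                             methods=config.methods, k_range=k_range)
            for c in cands:
                disc_rows.append({"variable": var, "method": c.method, "n_classes": c.n_classes,
                                  "breaks": ";".join(f"{b:.6g}" for b in c.breaks),
                                  "q": c.achieved_q})
            fr = opgd.factor_detector(suit, det[var].to_numpy(), variable=var,
                                      methods=config.methods, k_range=k_range)
            factor_rows.append({"variable": var, "method": fr.scheme.method,
                                "n_classes": fr.scheme.n_classes, "q": fr.q})
            strata[var] = opgd.assign_strata(det[var].to_numpy(), fr.scheme.breaks)
        pd.DataFrame(disc_rows).to_csv(out / "opgd_discretization.csv", index=False)
        factor_df = pd.DataFrame(factor_rows).sort_values("q", ascending=False)
        factor_df.to_csv(out / "opgd_factor.csv", index=False)

        inter_rows, eco_rows = [], []
        names = list(det.columns)
        for a_i in range(len(names)):
            for b_i in range(a_i + 1, len(names)):
                a, b = names[a_i], names[b_i]
                ir = opgd.interaction_detector(suit, strata[a], strata[b], pair=(a, b),
                                               min_stratum=config.min_stratum)
                inter_rows.append({"var1": a, "var2": b, "q1": ir.q1, "q2": ir.q2,
                                   "q12": ir.q12, "type": ir.type})
                er = opgd.ecological_detector(suit, strata[a], strata[b],
                                              alpha=config.alpha, pair=(a, b))
                eco_rows.append({"var1": a, "var2": b, "F": er.F, "decision": er.decision})
        pd.DataFrame(inter_rows).to_csv(out / "opgd_interaction.csv", index=False)
        pd.DataFrame(eco_rows).to_csv(out / "opgd_ecological.csv", index=False)

        risk_rows = []
        for var in names:
            rr = opgd.risk_detector(suit, strata[var], alpha=config.alpha, variable=var)
            for lab in rr.stratum_means.index:
                risk_rows.append({"variable": var, "stratum": int(lab),
                                  "mean": rr.stratum_means[lab],
                                  "n": int(rr.stratum_counts[lab]),
                                  "level": rr.levels[lab], "trend": rr.trend})
        pd.DataFrame(risk_rows).to_csv(out / "opgd_risk.csv", index=False)
        manifest["stages"]["opgd"] = {
            "seed": seed, "n_obs": len(det), "n_variables": len(names),
            "top_variable": factor_df.iloc[0]["variable"], "top_q": float(factor_df.iloc[0]["q"]),
        }
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        (out / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed") from exc

    manifest["counts_ok"] = bool(
        manifest["stages"]["thin"]["thinned"] <= manifest["stages"]["thin"]["loaded"]
        and manifest["stages"]["select"]["retained"] <= manifest["stages"]["select"]["candidates"]
        and len(manifest["stages"]["fit"]["members"]) <= len(config.roster)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
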