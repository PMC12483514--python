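"""Named end-to-end experiment recipes.

Each recipe writes its tables (CSV) and artifacts (HDF5) into an output
directory stamped with a hash of its configuration, so re-running with a
changed configuration never overwrites earlier results.  Plots are not
produced here; every figure-level quantity is serialized as a table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, connectivity, ephys, network, perturbation, pipeline
from . import training

log = logging.getLogger("flexdec")

DEFAULTS = {
    "n_nets": 5,
    "seed": 0,
    "trials_per_condition": 40,
    "shuffle_repeats": 100,
}


def config_hash(cfg: dict) -> str:
    return hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:10]


def _prepare(name, cfg, out_root):
    cfg = {**DEFAULTS, **(cfg or {})}
    h = config_hash({"recipe": name, **cfg})
    out = Path(out_root) / f"{name}-{h}"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump({"recipe": name, "config_hash": h, **cfg}, f)
    return cfg, out


def _load_or_train(cfg, out):
    """Reuse checkpoints from a previous train_cohort run if pointed to."""
    ckpt_dir = cfg.get("checkpoints")
    if ckpt_dir:
        paths = sorted(Path(ckpt_dir).glob("net*.h5"))
        if not paths:
            raise FileNotFoundError(
                f"no checkpoints under {ckpt_dir}; run the train_cohort "
                "recipe first")
        return [network.NetworkParams.load(p) for p in paths]
    cohort = pipeline.train_cohort(cfg["n_nets"], cfg["seed"],
                                   train_cfg=_train_cfg(cfg))
    for i, (p, hist) in enumerate(cohort):
        p.save(out / f"net{i:02d}.h5")
        hist.to_frame().to_csv(out / f"net{i:02d}_history.csv", index=False)
    return [p for p, _ in cohort]


def _train_cfg(cfg):
    keys = set(training.TrainConfig.__dataclass_fields__)
    overrides = {k: v for k, v in cfg.items() if k in keys}
    return training.TrainConfig(**overrides) if overrides else None


def recipe_train_cohort(cfg, out):
    nets = _load_or_train(cfg, out)
    log.info("trained %d networks", len(nets))
    return out


def recipe_test_psychometrics(cfg, out):
    nets = _load_or_train(cfg, out)
    frames = []
    for i, p in enumerate(nets):
        _, _, btab, _ = pipeline.test_battery(
            p, seed=cfg["seed"] + i,
            trials_per_condition=cfg["trials_per_condition"])
        btab["net"] = i
        frames.append(btab)
    allb = pd.concat(frames, ignore_index=True)
    allb.to_csv(out / "behavior.csv", index=False)
    behavior.psychometric_chronometric(allb).to_csv(
        out / "psychometric.csv", index=False)
    return out


def recipe_selectivity(cfg, out):
    nets = _load_or_train(cfg, out)
    rows = []
    for i, p in enumerate(nets):
        _, _, _, rtab = pipeline.test_battery(
            p, seed=cfg["seed"] + i,
            trials_per_condition=cfg["trials_per_condition"])
        r = pipeline.ds_coherence_correlation(rtab, p)
        d, _ = pipeline.ct_it_ds_difference(rtab, p)
        rows.append({"net": i, "ds_coherence_r": r, "ct_it_ds_diff": d})
    pd.DataFrame(rows).to_csv(out / "selectivity_summary.csv", index=False)
    return out


def recipe_connectivity(cfg, out):
    nets = _load_or_train(cfg, out)
    group_frames, rows = [], []
    for i, p in enumerate(nets):
        _, _, _, rtab = pipeline.test_battery(
            p, seed=cfg["seed"] + i,
            trials_per_condition=cfg["trials_per_condition"])
        prefs, groups, r = pipeline.connectivity_summary(rtab, p)
        groups["net"] = i
        group_frames.append(groups)
        rows.append({"net": i, "match_weight_r": r})
        connectivity.edge_table(p, prefs).to_csv(
            out / f"net{i:02d}_edges.csv", index=False)
    pd.concat(group_frames, ignore_index=True).to_csv(
        out / "group_weights.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "match_correlation.csv", index=False)
    return out


def recipe_perturbation(cfg, out):
    nets = _load_or_train(cfg, out)
    rows = []
    for i, p in enumerate(nets):
        seed = cfg["seed"] + i
        _, _, bt_int, rt_int = pipeline.test_battery(
            p, seed=seed, trials_per_condition=cfg["trials_per_condition"])
        prefs, _, _ = pipeline.connectivity_summary(rt_int, p)
        variants = {
            "intact": p,
            "ablate_feedback": perturbation.ablate_feedback(p),
            "shuffle_feedback": perturbation.shuffle_feedback(
                p, np.random.default_rng(seed)),
            "ablate_specific": perturbation.ablate_group(p, "specific",
                                                         prefs),
            "ablate_nonspecific": perturbation.ablate_group(
                p, "nonspecific", prefs),
        }
        for name, q in variants.items():
            _, _, bt, rt = pipeline.test_battery(
                q, seed=seed, trials_per_condition=cfg["trials_per_condition"])
            d, _ = pipeline.ct_it_ds_difference(rt, q)
            for coh, g in bt.groupby("coherence"):
                rows.append({"net": i, "variant": name, "coherence": coh,
                             "accuracy": g["correct"].mean(),
                             "rt_mean": g["rt_ms"].mean(),
                             "n_trials": len(g), "ct_it_ds_diff": d})
    pd.DataFrame(rows).to_csv(out / "perturbation_behavior.csv", index=False)
    return out


def recipe_landscape(cfg, out):
    nets = _load_or_train(cfg, out)
    rows = []
    for i, p in enumerate(nets):
        _, _, _, rtab = pipeline.test_battery(
            p, seed=cfg["seed"] + i,
            trials_per_condition=cfg["trials_per_condition"])
        res = pipeline.landscape_summary(rtab, p, seed=cfg["seed"] + i)
        row = {"net": i, "variant": "intact", **res["metrics"]}
        rows.append(row)
        for coh, depth in res.get("depth_by_coherence", {}).items():
            rows.append({"net": i, "variant": f"coh_{coh}",
                         "depth_mean": depth})
    pd.DataFrame(rows).to_csv(out / "landscape_metrics.csv", index=False)
    return out


def recipe_ephys_synthetic(cfg, out):
    rng = np.random.default_rng(cfg["seed"])
    sim_keys = set(ephys.EphysSimConfig.__dataclass_fields__)
    sim_cfg = ephys.EphysSimConfig(**{k: v for k, v in cfg.items()
                                      if k in sim_keys})
    table = ephys.simulate_session(sim_cfg, rng)
    table.save(out / "session.h5")
    from . import selectivity as sel
    prefs = sel.preferred_direction(table)
    flags = sel.screen_units(table, mode="ephys")
    flags.to_csv(out / "screening.csv", index=False)
    mi = sel.modulation_index(table, prefs=prefs)
    mi.to_csv(out / "modulation_index.csv", index=False)
    d, pval = ephys.ct_it_test(table, prefs)
    centers, r_stim, r_dec = sel.partial_corr_series(table, prefs=prefs)
    pd.DataFrame({"time_ms": centers,
                  "r_stimulus": np.nanmean(r_stim, axis=0),
                  "r_decision": np.nanmean(r_dec, axis=0)}).to_csv(
        out / "partial_correlations.csv", index=False)
    with open(out / "ct_it_test.json", "w") as f:
        json.dump({"mean_delta_diff": d, "p": pval}, f, indent=2)
    return out


RECIPES = {
    "train_cohort": recipe_train_cohort,
    "test_psychometrics": recipe_test_psychometrics,
    "selectivity_fig4": recipe_selectivity,
    "connectivity_fig5": recipe_connectivity,
    "perturbation_fig5": recipe_perturbation,
    "landscape_fig6": recipe_landscape,
    "ephys_fig2_3_synthetic": recipe_ephys_synthetic,
}


def run_recipe(name: str, cfg: dict | None = None,
               out_root="results") -> Path:
    """Run a named recipe; returns its output directory."""
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; available: "
                       f"{sorted(RECIPES)}")
    cfg, out = _prepare(name, cfg, out_root)
    t0 = time.time()
    log.info("recipe %s -> %s", name, out)
    RECIPES[name](cfg, out)
    log.info("recipe %s finished in %.1f s", name, time.time() - t0)
    return out
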