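"""Orchestration of simulate → classify → infer runs.

Each stage is a thin wrapper that moves files and calls the masks /
observer / classify / inference operations; no statistics are computed here.
Stages write their outputs under a run directory:

    run/
      manifest.json            config echo + master seed
      logs/<participant>.csv   trial logs
      arrays/<participant>.npz/.json   classification arrays
      exclusions.csv           accuracy, binomial p, included flag
      report.json              group results (clusters, p maps, timing info)
      figures/                 publication-style plots
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_participant, exclude_guesser
from .inference import StatConfig, cluster_permutation_test, transformed_r_ci
from .io import (
    RunConfig,
    load_classification,
    make_observers,
    read_trial_log,
    save_classification,
    write_trial_log,
)
from .masks import frame_to_time
from .observer import simulate_experiment

logger = logging.getLogger("bubblerc")

__all__ = ["simulate_stage", "classify_stage", "infer_stage", "run_all"]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def simulate_stage(config: RunConfig, out_dir) -> list[Path]:
    """Simulate the configured cohort; one trial-log CSV per participant."""
    out_dir = Path(out_dir)
    logs_dir = out_dir / "logs"
    logs_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    observers = make_observers(config)
    log = simulate_experiment(
        observers,
        n_trials=config.n_trials,
        n_bubbles=config.n_bubbles,
        sigma=config.sigma,
        geometry=config.geometry,
        session_type=config.session_type,
        master_seed=config.master_seed,
        balanced_labels=config.balanced_labels,
        contact_jitter=config.contact_jitter,
    )
    paths = []
    for pid, sub in log.groupby("participant_id", sort=True):
        path = logs_dir / f"{pid}.csv"
        write_trial_log(sub, path)
        paths.append(path)
    manifest = {
        "bubblerc_version": __version__,
        "config": config.to_dict(),
        "participants": sorted(log["participant_id"].unique().tolist()),
        "per_participant_seeds": {
            pid: int(sub["seed"].iloc[0])
            for pid, sub in log.groupby("participant_id")
        },
    }
    _write_json(out_dir / "manifest.json", manifest)
    logger.info(
        "simulate: %d participants x %d trials in %.1fs",
        config.n_observers, config.n_trials, time.perf_counter() - t0,
    )
    return paths


def classify_stage(log_paths, config: RunConfig, out_dir) -> pd.DataFrame:
    """Per-participant classification arrays + chance-exclusion report."""
    out_dir = Path(out_dir)
    arrays_dir = out_dir / "arrays"
    arrays_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    rows = []
    ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(1000,))
    for path, child in zip(sorted(map(Path, log_paths)), ss.spawn(len(log_paths))):
        log = read_trial_log(path)
        pid = str(log["participant_id"].iloc[0])
        n_correct = int(log["correct"].sum())
        n_trials = len(log)
        excluded, binom_p = exclude_guesser(
            n_correct, n_trials, config.accuracy_threshold
        )
        seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        arr = classify_participant(
            log,
            config.geometry,
            n_permutations=config.n_permutations_within,
            seed=seed,
        )
        save_classification(arr, arrays_dir / pid)
        rows.append(
            {
                "participant_id": pid,
                "n_trials": n_trials,
                "n_correct": n_correct,
                "accuracy": n_correct / n_trials,
                "binomial_p": binom_p,
                "included": not excluded,
            }
        )
        logger.debug("classified %s (accuracy %.3f)", pid, n_correct / n_trials)
    table = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
    table.to_csv(out_dir / "exclusions.csv", index=False)
    logger.info(
        "classify: %d participants (%d included) in %.1fs",
        len(table), int(table["included"].sum()), time.perf_counter() - t0,
    )
    return table


def _cluster_report(result, config: RunConfig) -> list[dict]:
    out = []
    temporal = config.session_type == "temporal"
    geometry = config.geometry
    for c in result.clusters:
        d = c.to_dict()
        if temporal:
            (lo, hi), = d["bounds"]
            d["frames"] = [lo + 1, hi + 1]  # 1-based frame indices
            d["time_before_contact_s"] = [
                frame_to_time(hi + 1, geometry),
                frame_to_time(lo + 1, geometry),
            ]
        out.append(d)
    return out


def infer_stage(array_paths, exclusion_table, config: RunConfig, out_dir) -> dict:
    """Group t- and r-based permutation analyses; JSON report + figures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    arrays = {p.stem: load_classification(p.with_suffix("")) for p in
              sorted(Path(q) for q in array_paths)}
    table = exclusion_table.set_index("participant_id")

    included = [pid for pid in arrays if table.loc[pid, "included"]]
    if len(included) < 2:
        raise ValueError(
            f"t analysis needs >= 2 included participants, have {len(included)}"
        )
    Z_inc = np.stack([arrays[p].z for p in included])
    exclude_pts = np.any([arrays[p].degenerate for p in included], axis=0)
    t_cfg = StatConfig(
        statistic="t",
        cluster_metric=config.cluster_metric,
        cluster_forming_threshold=config.cluster_forming_threshold,
        n_permutations=config.n_permutations_group,
        connectivity=config.connectivity,
        alpha=config.alpha,
        seed=int(
            np.random.SeedSequence(
                entropy=config.master_seed, spawn_key=(2000,)
            ).generate_state(1, dtype=np.uint32)[0] % (2**31)
        ),
    )
    t_result = cluster_permutation_test(Z_inc, t_cfg, exclude=exclude_pts)

    # r analysis uses the entire cohort (variation in ability is the signal)
    all_pids = sorted(arrays)
    perf = np.array([table.loc[p, "accuracy"] for p in all_pids])
    r_report = None
    r_result = None
    if len(all_pids) >= 3 and np.std(perf) > 0:
        Z_all = np.stack([arrays[p].z for p in all_pids])
        r_cfg = StatConfig(
            statistic="r",
            cluster_metric=config.cluster_metric,
            n_permutations=config.n_permutations_group,
            connectivity=config.connectivity,
            alpha=config.alpha,
            tail="one",
            seed=int(
                np.random.SeedSequence(
                    entropy=config.master_seed, spawn_key=(2001,)
                ).generate_state(1, dtype=np.uint32)[0] % (2**31)
            ),
        )
        r_result = cluster_permutation_test(
            Z_all, r_cfg, performance=perf,
            exclude=np.any([arrays[p].degenerate for p in all_pids], axis=0),
        )
        center, halfwidth, _ = transformed_r_ci(r_result.stat_map, len(all_pids))
        r_report = {
            "n_participants": len(all_pids),
            "forming_threshold": r_result.threshold,
            "method": r_result.method,
            "clusters": _cluster_report(r_result, config),
            "min_pointwise_max_p": float(r_result.pointwise_max_p.min()),
            "fisher_z_ci_halfwidth": halfwidth,
            "transform": "fisher-z",
        }
        np.savez(
            out_dir / "r_maps.npz",
            r=r_result.stat_map,
            normalized=r_result.normalized_map,
            pointwise_max_p=r_result.pointwise_max_p,
            fisher_z=center,
        )

    np.savez(
        out_dir / "t_maps.npz",
        t=t_result.stat_map,
        normalized=t_result.normalized_map,
        pointwise_max_p=t_result.pointwise_max_p,
        mean_z=Z_inc.mean(axis=0),
    )
    report = {
        "session_type": config.session_type,
        "n_participants_total": len(all_pids),
        "n_participants_included": len(included),
        "participants": json.loads(
            exclusion_table.to_json(orient="records")
        ),
        "t_analysis": {
            "n_participants": len(included),
            "forming_threshold": t_result.threshold,
            "method": t_result.method,
            "clusters": _cluster_report(t_result, config),
            "min_pointwise_max_p": float(t_result.pointwise_max_p.min()),
        },
        "r_analysis": r_report,
    }
    _write_json(out_dir / "report.json", report)

    try:
        from . import plots

        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        if config.session_type == "temporal":
            plots.plot_sequence(
                Z_inc, t_result, config.geometry, fig_dir / "t_sequence.png"
            )
            if r_result is not None:
                plots.plot_sequence(
                    None, r_result, config.geometry,
                    fig_dir / "r_sequence.png", n_for_ci=len(all_pids),
                )
        else:
            plots.plot_map(t_result, fig_dir / "t_map.png")
            if r_result is not None:
                plots.plot_map(r_result, fig_dir / "r_map.png")
    except Exception as exc:  # figures are best-effort, never fail a run
        logger.warning("figure generation failed: %s", exc)

    logger.info("infer: done in %.1fs", time.perf_counter() - t0)
    return report


def run_all(config: RunConfig, out_dir) -> dict:
    """simulate → classify → infer under one run directory."""
    out_dir = Path(out_dir)
    log_paths = simulate_stage(config, out_dir)
    table = classify_stage(log_paths, config, out_dir)
    array_paths = sorted((out_dir / "arrays").glob("*.npz"))
    return infer_stage(array_paths, table, config, out_dir)
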