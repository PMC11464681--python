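"""End-to-end orchestration: simulate → fit behavior → cluster → associate.

``run_full`` executes the whole chain from a YAML/dict config into a run
directory, writing a manifest that hashes every output so a rerun with the
same seed is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .association import (
    bootstrap_ci,
    build_association_dataset,
    simple_slopes,
    step_up_select,
)
from .lmm import fit_mixed_model
from .mixture import compare_tasks, fit_subjects, ks_uniform_screen
from .network import (
    HybridNetworkClustering,
    fnc_cluster_tests,
    group_mean_fc,
    network_fc_feature_table,
)
from .rois import synthetic_roi_table
from .synthesize import (
    gen_behavioral_trials,
    gen_fc_matrices,
    gen_linked_dataset,
    default_fc_condition,
    linked_condition,
    location_condition,
    orientation_condition,
    with_seed,
)

__all__ = ["run_full", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger("vwm_errnet")

DEFAULT_CONFIG = {
    "seed": 0,
    "behavior": {"n_subjects": 24, "n_trials": 120, "em_restarts": 4},
    "fc": {"n_subjects": 24, "n_timepoints": 300,
           "within_corr": 0.5, "between_corr": 0.1},
    "clustering": {"r": 0.95, "n_clusters": None},
    "association": {"responses": ["sigma_vm"], "n_bootstrap": 200,
                    "candidates": ["fc_w_N6", "fc_b_N3_N5"]},
    "linked_demo": {"response": "sigma_vm", "enabled": True},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        cfg = dict(path_or_dict)
    merged = {}
    for key, val in DEFAULT_CONFIG.items():
        merged[key] = dict(val, **cfg.get(key, {})) if isinstance(val, dict) \
            else cfg.get(key, val)
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config, out_dir) -> Path:
    """Run every stage on synthetic data; returns the run directory.

    The manifest (``manifest.json``) records, per stage, the seed, wall
    time and a content hash of every file written.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(root_seed).spawn(8)]
    manifest = {"seed": root_seed, "stages": []}

    def record(stage, t0, files, seed):
        manifest["stages"].append({
            "stage": stage, "seed": seed,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
        })
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

    # 1 -- behavioral simulation (both tasks, same subjects)
    t0 = time.time()
    b = cfg["behavior"]
    ori = gen_behavioral_trials(with_seed(
        orientation_condition(b["n_subjects"], b["n_trials"]), seeds[0]))
    loc = gen_behavioral_trials(with_seed(
        location_condition(b["n_subjects"], b["n_trials"]), seeds[1]))
    trials = pd.concat([ori, loc], ignore_index=True)
    f_trials = vio.write_trials(trials, out / "trials.tsv")
    record("simulate-behavior", t0, [f_trials], seeds[0])

    # 2 -- screen + mixture fits + task comparison
    t0 = time.time()
    prepared = vio.prepare_trials(vio.read_trials(f_trials))
    screen = ks_uniform_screen(prepared)
    kept = prepared[prepared["subject"].isin(screen.loc[screen["keep"], "subject"])]
    fits = fit_subjects(kept, n_restarts=b["em_restarts"], random_state=seeds[2])
    comparison = compare_tasks(fits)
    f_screen = out / "screen.tsv"
    screen.to_csv(f_screen, sep="\t", index=False)
    f_fits = out / "behavior_fits.tsv"
    fits.to_csv(f_fits, sep="\t", index=False, float_format="%.6f")
    f_cmp = out / "task_comparison.tsv"
    comparison.to_csv(f_cmp, sep="\t", index=False, float_format="%.6g")
    record("fit-behavior", t0, [f_screen, f_fits, f_cmp], seeds[2])

    # 3 -- connectivity simulation
    t0 = time.time()
    fc_cfg = cfg["fc"]
    fc_spec = default_fc_condition(
        n_subjects=fc_cfg["n_subjects"], n_timepoints=fc_cfg["n_timepoints"],
        within_corr=fc_cfg["within_corr"], between_corr=fc_cfg["between_corr"],
        seed=seeds[3])
    mats = gen_fc_matrices(fc_spec)
    fc_dir = out / "fc"
    files = [vio.write_fc_matrix(m, fc_dir / f"sub-{i + 1:03d}_fc.tsv")
             for i, m in enumerate(mats)]
    rois = synthetic_roi_table()
    f_rois = vio.write_roi_table(rois, out / "rois.tsv")
    record("simulate-fc", t0, files + [f_rois], seeds[3])

    # 4 -- clustering, cluster tests, features
    t0 = time.time()
    group = group_mean_fc(mats)
    cl = HybridNetworkClustering(
        r=cfg["clustering"]["r"], n_clusters=cfg["clustering"]["n_clusters"],
        n_clusters_fallback=6)
    cl.fit(group, centroids=np.asarray(rois[["x_mm", "y_mm", "z_mm"]], float))
    f_part = out / "partition.tsv"
    cl.partition_frame().to_csv(f_part, sep="\t", index=False)
    f_link = out / "linkage.tsv"
    pd.DataFrame(cl.linkage_, columns=["a", "b", "height", "count"]).to_csv(
        f_link, sep="\t", index=False, float_format="%.8f")
    tests = fnc_cluster_tests(mats, cl.labels_, random_state=seeds[4])
    f_tests = vio.write_json(tests.to_dict(orient="records"),
                             out / "fnc_tests.json")
    features = network_fc_feature_table(
        mats, cl.labels_, subjects=[f"sub-{i + 1:03d}" for i in range(len(mats))])
    f_feat = out / "network_features.tsv"
    features.to_csv(f_feat, sep="\t", index=False, float_format="%.6f")
    record("cluster", t0, [f_part, f_link, f_tests, f_feat], seeds[4])

    # 5 -- association on the joined tables (features vs fitted behavior)
    t0 = time.time()
    assoc_files = []
    a_cfg = cfg["association"]
    for response in a_cfg["responses"]:
        common = set(fits["subject"]) & set(features["subject"])
        if len(common) >= 10:
            data = build_association_dataset(
                fits[fits["subject"].isin(common)],
                features[features["subject"].isin(common)], response)
            sel = step_up_select(data, response,
                                 candidates=a_cfg.get("candidates"))
            report = {
                "response": response,
                "selected_terms": sel.selected_terms_,
                "inference": sel.fit_.inference_table().to_dict(orient="records"),
                "trace": [vars(t) for t in sel.trace_],
            }
            ci = bootstrap_ci(sel.fit_, n_sim=a_cfg["n_bootstrap"],
                              seed=seeds[5])
            report["bootstrap_ci"] = ci.to_dict(orient="records")
            assoc_files.append(vio.write_json(
                report, out / f"association_{response}.json"))
    record("associate", t0, assoc_files, seeds[5])

    # 6 -- linked-generator demo: recover planted slopes on coupled data
    if cfg["linked_demo"]["enabled"]:
        t0 = time.time()
        spec = linked_condition(cfg["linked_demo"]["response"], seed=seeds[6])
        data = gen_linked_dataset(spec)
        terms = ["intercept", "task"] + [t for t in spec.fixed_effects
                                         if t not in ("intercept", "task")]
        fit = fit_mixed_model(data, spec.response, terms)
        focal = next(t[5:] for t in terms if t.startswith("task:"))
        ss = simple_slopes(fit, focal)
        f_demo = vio.write_json({
            "response": spec.response,
            "generating_effects": spec.fixed_effects,
            "estimates": fit.params.to_dict(),
            "simple_slopes": ss.slopes.to_dict(orient="records"),
        }, out / "linked_demo.json")
        record("linked-demo", t0, [f_demo], seeds[6])

    f_manifest = vio.write_json(manifest, out / "manifest.json")
    log.info("run complete: %s", f_manifest)
    return out
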