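"""End-to-end orchestration: synthesis -> classification -> ERP/ERSP ->
cluster statistics, with a reproducibility manifest.

A run is a pure function of ``(config, seed)``: the global seed is fanned
out deterministically to the behavioral simulation, the dataset generator
and every permutation test. The report directory contains trial counts per
category (TSV), component peaks (TSV), cluster test results (JSON), the
grand-average ERPs (HDF5) and a manifest with the config hash and digests
of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .channels import subset_layout
from .classify import ClassificationParams, classify_events
from .clusterstats import (
    ClusterConfig,
    actvsbl_subject_maps,
    build_adjacency,
    dependent_t,
    equalize_trials,
    permutation_test,
)
from .config import merge_config, validate_config
from .erp import BASELINE_WINDOWS, COMPONENT_WINDOWS, average_erp, baseline_correct, component_peak
from .stimulus import ISIScheduleConfig, build_isi_schedule, logistic_observer
from .synth import CONDITIONS, default_ground_truth, simulate_dataset, simulate_observer_session

__all__ = ["run_pipeline"]

#: ERP contrasts reported by the pipeline: (name, condition A, condition B).
CONTRASTS = (
    ("hit_vs_miss", "hit_stim", "miss"),
    ("fa_vs_cr", "fa", "cr"),
    ("fa_vs_bp", "fa", "bp"),
    ("hit_vs_fa", "hit_resp", "fa"),
)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _erp_window(alignment: str) -> tuple[float, float]:
    # activation windows for the activation-vs-baseline tests
    return (0.0, 1.8) if alignment == "stimulus" else (-1.5, 0.5)


def run_pipeline(config: dict | None = None, seed: int | None = None) -> dict:
    """Run all stages on synthetic data; returns the manifest dict."""
    cfg = merge_config(config)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    if seed is not None:
        cfg["seed"] = seed
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    root = np.random.default_rng(cfg["seed"])
    stage_seed = {
        name: int(root.integers(2**31 - 1))
        for name in ("behavior", "dataset", "stats")
    }
    artifacts: dict[str, str] = {}

    # ------------------------------------------------------------------ 1
    # behavioral simulation and classification
    sc = cfg["stimulus"]
    schedule = build_isi_schedule(
        ISIScheduleConfig(isi_min=sc["isi_range"][0], isi_max=sc["isi_range"][1]),
        seed=stage_seed["behavior"],
    )
    observer = logistic_observer(midpoint_db=0.0, slope_per_db=1.0, fa_rate=0.01)
    stream, _truth = simulate_observer_session(
        observer, schedule, levels=0.7, seed=stage_seed["behavior"]
    )
    cl = cfg["classify"]
    params = ClassificationParams(
        hit_window=tuple(cl["hit_window"]),
        miss_horizon=cl["miss_horizon"],
        fa_lockout=cl["fa_lockout"],
        rt_bin=cl["rt_bin"],
        smooth_window=cl["smooth_window"],
    )
    labels = classify_events(stream, params, epoch_halfwidth=2.0)
    counts = labels.counts()
    counts_path = out_dir / "trial_counts.tsv"
    pd.DataFrame([counts]).to_csv(counts_path, sep="\t", index=False)
    artifacts["trial_counts.tsv"] = _digest(counts_path)

    # ------------------------------------------------------------------ 2
    # synthetic EEG dataset
    sy = cfg["synth"]
    labels64, positions = subset_layout(sy["n_channels"])
    gt = default_ground_truth(labels=labels64)
    dataset = simulate_dataset(
        gt, n_subjects=sy["n_subjects"], n_trials=sy["n_trials"],
        seed=stage_seed["dataset"],
    )

    # ------------------------------------------------------------------ 3
    # ERPs: grand averages, baselines, component peaks
    peaks = []
    for cond in CONDITIONS:
        grand = average_erp(
            _concat_epochs([sub[cond] for sub in dataset])
        )
        align = dataset[0][cond].alignment
        if align in BASELINE_WINDOWS:
            grand = baseline_correct(grand, BASELINE_WINDOWS[align])
        erp_path = out_dir / f"erp_{cond}.h5"
        _io.save_erp(erp_path, grand)
        artifacts[erp_path.name] = _digest(erp_path)
        for comp in ("EN", "LP"):
            key = (align if align in ("stimulus", "response") else "response", comp)
            if key in COMPONENT_WINDOWS:
                if COMPONENT_WINDOWS[key].channel not in grand.channel_labels:
                    continue  # peak channel not in the recorded subset
                lat, amp = component_peak(grand, COMPONENT_WINDOWS[key])
                peaks.append(
                    {"condition": cond, "component": comp,
                     "latency_s": lat, "amplitude_uv": amp}
                )
    peaks_path = out_dir / "component_peaks.tsv"
    pd.DataFrame(peaks).to_csv(peaks_path, sep="\t", index=False)
    artifacts[peaks_path.name] = _digest(peaks_path)

    # ------------------------------------------------------------------ 4
    # cluster permutation tests
    cs = cfg["clusterstats"]
    adjacency = build_adjacency(positions, cs["adjacency_threshold"])
    ccfg = ClusterConfig(
        cluster_quantiles=tuple(cs["cluster_quantiles"]),
        n_permutations=cs["n_permutations"],
        final_alpha=cs["final_alpha"],
        seed=stage_seed["stats"],
    )
    results = {}
    for cond in CONDITIONS:
        eps = [sub[cond] for sub in dataset]
        align = eps[0].alignment
        activation = _erp_window(align if align != "none" else "response")
        baseline = BASELINE_WINDOWS.get(align, BASELINE_WINDOWS["response"])
        maps = actvsbl_subject_maps(eps, activation, baseline)
        res = permutation_test(maps, adjacency, ccfg)
        results[f"actvsbl_{cond}"] = _summarize(res)
    for name, ca, cb in CONTRASTS:
        diffs = []
        for sub in dataset:
            a, b = equalize_trials(sub[ca], sub[cb], seed=stage_seed["stats"])
            diffs.append(a.data.mean(axis=0) - b.data.mean(axis=0))
        res = permutation_test(np.stack(diffs), adjacency, ccfg)
        results[name] = _summarize(res)
    stats_path = out_dir / "cluster_results.json"
    stats_path.write_text(json.dumps(results, indent=2))
    artifacts[stats_path.name] = _digest(stats_path)

    # ------------------------------------------------------------------ 5
    # slow-wave (SCP) ERSP report traces for the response-aligned conditions
    from .ersp import WaveletBank, band_trace, ersp as _ersp, relative_baseline, tfr_transform

    er = cfg["ersp"]
    lo, hi = er["report_band"]
    bank = WaveletBank(
        freqs=np.arange(lo, hi + 1e-9, er["report_freq_step"]),
        rate=dataset[0]["hit_resp"].rate,
        time_step=er["time_step"],
    )
    for cond in ("hit_resp", "fa"):
        traces = []
        for sub in dataset:
            coeffs, tmpl = tfr_transform(sub[cond], bank)
            rel = relative_baseline(
                _ersp(coeffs, tmpl),
                baseline=(sub[cond].times[0], -1.0),
                activation_start=-1.0,
            )
            ch = (
                list(tmpl.channel_labels).index("Pz")
                if "Pz" in tmpl.channel_labels
                else 0
            )
            traces.append(band_trace(rel, (lo, hi))[ch])
        trace_path = out_dir / f"scp_trace_{cond}.tsv"
        pd.DataFrame(
            {"time_s": rel.times, "relative_power": np.mean(traces, axis=0)}
        ).to_csv(trace_path, sep="\t", index=False)
        artifacts[trace_path.name] = _digest(trace_path)

    # ------------------------------------------------------------------ 6
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": cfg["seed"],
        "stage_seeds": stage_seed,
        "version": _version(),
        "artifacts": artifacts,
        "elapsed_s": round(time.time() - t0, 2),
        "counts": counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _version() -> str:
    from . import __version__

    return __version__


def _concat_epochs(epoch_sets):
    from dataclasses import replace

    data = np.concatenate([e.data for e in epoch_sets], axis=0)
    return replace(epoch_sets[0], data=data)


def _summarize(res) -> dict:
    return {
        "n_clusters": len(res.clusters),
        "clusters": [
            {"sign": c.sign, "t_sum": c.t_sum, "p": c.p_value, "size": int(c.members.size)}
            for c in res.clusters[:10]
        ],
        "significant": len(res.significant),
        "seed": res.config.seed,
    }
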