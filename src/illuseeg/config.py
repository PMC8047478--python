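"""Pipeline configuration: named defaults and schema validation.

Every timing and threshold constant of the analysis lives here as a named
default so that a run is fully described by one (YAML/JSON-compatible)
mapping. ``validate_config`` rejects unknown keys and inconsistent values.
"""

from __future__ import annotations

import copy

__all__ = ["DEFAULT_CONFIG", "validate_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "illuseeg_out",
    "classify": {
        "hit_window": [0.3, 1.8],  # s post stimulus onset
        "miss_horizon": 3.6,  # s
        "fa_lockout": 3.6,  # s pre response
        "rt_bin": 0.042,  # s
        "smooth_window": 0.420,  # s
    },
    "preprocess": {
        "target_rate": 200.0,  # Hz
        "highpass": {"cutoff": 0.3, "transition": 0.6, "order": 1100},
        "lowpass_tfa": {"cutoff": 45.0, "transition": 8.0, "order": 84},
        "lowpass_erp": {"cutoff": 30.0, "transition": 7.5, "order": 88},
        "epoch_response": [-4.6, 1.9],  # s
        "epoch_stimulus": [-2.8, 3.7],  # s
        "reject_threshold": 300.0,  # µV, post-cleaning screen
        "precleaning_threshold": 400.0,  # µV, frontal channels excluded
    },
    "erp": {
        "baseline_stimulus": [-0.2, 0.0],  # s
        "baseline_response": [-3.1, -2.9],  # s
    },
    "ersp": {
        "fmin": 1.0,
        "fmax": 45.0,
        "freq_step": 0.2,  # Hz
        "time_step": 0.010,  # s
        "cycles": [3.0, 10.0],
        "bands": {"scp": [1.0, 4.0], "alpha": [8.0, 12.0], "beta": [15.0, 25.0]},
        # band + grid used for the pipeline's slow-wave report trace; the
        # full fmin-fmax grid at freq_step stays available via the library
        "report_band": [1.0, 4.0],
        "report_freq_step": 0.5,
    },
    "clusterstats": {
        "n_permutations": 1000,
        "final_alpha": 0.05,
        "cluster_quantiles": [2.5, 97.5],
        "adjacency_threshold": 0.55,  # unit-head chord distance
    },
    "synth": {
        "n_subjects": 16,
        # None selects the per-condition study trial counts
        # (hits 108, FAs 67, misses 57, CRs/BPs 60)
        "n_trials": None,
        "n_channels": 64,
        "noise_sigma": 20.0,  # µV
        "noise_exponent": 1.0,
        "spatial_mix": 0.5,
        "fa_scale": 0.6,
    },
    "stimulus": {
        "rate": 50000.0,  # Hz
        "isi_range": [3.0, 19.0],  # s
        "n_stimuli": 180,
        "staircase": {
            "step_initial": 1.0,
            "step_reduced": 0.5,
            "reversals_to_reduce": 4,
            "reversals_to_stop": 9,
            "reversals_averaged": 5,
        },
        "ihl": {"burst_ms": 400.0, "step_db": 2.0, "drop_db": 10.0, "repeats": 3},
    },
}


def _check(cond: bool, path: str, msg: str, errors: list[str]):
    if not cond:
        errors.append(f"{path}: {msg}")


def validate_config(config: dict) -> list[str]:
    """Return a list of schema errors (empty when the config is valid)."""
    errors: list[str] = []
    _walk_unknown(config, DEFAULT_CONFIG, "", errors)
    c = merge_config(config)
    hw = c["classify"]["hit_window"]
    _check(0 < hw[0] < hw[1], "classify.hit_window", "must be increasing and positive", errors)
    _check(hw[1] <= c["classify"]["miss_horizon"], "classify.miss_horizon",
           "must cover the hit window", errors)
    _check(c["classify"]["fa_lockout"] >= hw[1], "classify.fa_lockout",
           "must cover the hit window", errors)
    _check(c["clusterstats"]["n_permutations"] >= 1, "clusterstats.n_permutations",
           "must be >= 1", errors)
    _check(0 < c["clusterstats"]["final_alpha"] < 1, "clusterstats.final_alpha",
           "must be in (0, 1)", errors)
    q = c["clusterstats"]["cluster_quantiles"]
    _check(0 < q[0] < q[1] < 100, "clusterstats.cluster_quantiles",
           "must be increasing within (0, 100)", errors)
    _check(c["ersp"]["fmin"] < c["ersp"]["fmax"], "ersp", "fmin must be < fmax", errors)
    ep = c["preprocess"]["epoch_response"]
    _check(ep[0] < 0 < ep[1], "preprocess.epoch_response", "must straddle the anchor", errors)
    _check(c["synth"]["n_subjects"] >= 2, "synth.n_subjects", "need >= 2 subjects", errors)
    return errors


def _walk_unknown(config, defaults, prefix, errors):
    for key, val in config.items():
        path = f"{prefix}.{key}" if prefix else str(key)
        if key not in defaults:
            errors.append(f"{path}: unknown key")
        elif isinstance(val, dict) and isinstance(defaults[key], dict):
            _walk_unknown(val, defaults[key], path, errors)


def merge_config(overrides: dict | None = None) -> dict:
    """Deep-merge ``overrides`` onto the defaults."""
    def _merge(base, over):
        out = copy.deepcopy(base)
        for k, v in (over or {}).items():
            if k in out and isinstance(out[k], dict) and isinstance(v, dict):
                out[k] = _merge(out[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    return _merge(DEFAULT_CONFIG, overrides or {})
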