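"""Event-related potentials: averaging, baselines, peaks, topographies.

An ERP is the trial average of an :class:`~illuseeg.preprocess.EpochSet`;
its per-sample standard error quantifies across-trial variability. The
module also extracts component peaks (the early negativity and the late
centro-parietal positivity analysed in this task), builds scalp
topographies as time-averages over an interval, and compares topographies
across alignments or conditions by Pearson correlation over channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import pearsonr

from .preprocess import EpochSet

__all__ = [
    "ERP",
    "ComponentWindow",
    "Topography",
    "COMPONENT_WINDOWS",
    "average_erp",
    "baseline_correct",
    "component_peak",
    "component_topography",
    "spatial_correlation",
]


@dataclass(frozen=True)
class ERP:
    mean: np.ndarray  # channels x time, microvolts
    sem: np.ndarray  # channels x time
    times: np.ndarray  # s
    n_trials: int
    rate: float
    channel_labels: tuple[str, ...] = ()
    baseline_window: tuple[float, float] | None = None

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in ERP") from None


@dataclass(frozen=True)
class ComponentWindow:
    """Where to look for a component peak: channel, interval, polarity."""

    channel: str
    window: tuple[float, float]  # s
    polarity: str  # 'positive' | 'negative'

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


#: Component search windows (s) used in this analysis, per alignment.
COMPONENT_WINDOWS = {
    ("stimulus", "LP"): ComponentWindow("Pz", (0.4, 1.3), "positive"),
    ("stimulus", "EN"): ComponentWindow("Pz", (0.1, 0.6), "negative"),
    ("response", "LP"): ComponentWindow("Pz", (-0.25, 0.25), "positive"),
    ("response", "EN"): ComponentWindow("Pz", (-0.9, -0.1), "negative"),
}

#: Baseline windows (s) per alignment: 200-0 ms pre-stimulus for
#: stimulus-aligned epochs, -3.1 to -2.9 s for response-aligned epochs.
#: An alternative stimulus-aligned window of (-1.3, -1.1) s, used for some
#: displays, is provided alongside.
BASELINE_WINDOWS = {
    "stimulus": (-0.2, 0.0),
    "stimulus_early": (-1.3, -1.1),
    "response": (-3.1, -2.9),
}


@dataclass(frozen=True)
class Topography:
    values: np.ndarray  # one scalar per channel
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, float)
        if values.size != len(self.channel_labels):
            raise ValueError("one value per channel required")
        if not np.all(np.isfinite(values)):
            raise ValueError("topography values must be finite")
        object.__setattr__(self, "values", values)


def average_erp(epochs: EpochSet) -> ERP:
    """Trial mean and standard error of the mean per (channel, time)."""
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials for an SEM")
    mean = epochs.data.mean(axis=0)
    sem = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
    return ERP(
        mean=mean,
        sem=sem,
        times=epochs.times,
        n_trials=epochs.n_trials,
        rate=epochs.rate,
        channel_labels=tuple(epochs.channel_labels),
    )


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
    if not mask.any():
        raise ValueError(f"window {window} outside the epoch times")
    return mask


def baseline_correct(erp: ERP, window: tuple[float, float]) -> ERP:
    """Subtract the per-channel mean over ``window`` (idempotent)."""
    mask = _window_mask(erp.times, window)
    base = erp.mean[:, mask].mean(axis=1, keepdims=True)
    return replace(erp, mean=erp.mean - base, baseline_window=tuple(window))


def component_peak(erp: ERP, cw: ComponentWindow) -> tuple[float, float]:
    """Latency (s) and amplitude (µV) of the raw extremum in the window.

    Ties are broken to the earliest sample; no interpolation is applied.
    """
    ch = erp.channel_index(cw.channel)
    mask = _window_mask(erp.times, cw.window)
    trace = erp.mean[ch, mask]
    idx = int(np.argmax(trace)) if cw.polarity == "positive" else int(np.argmin(trace))
    times = erp.times[mask]
    return float(times[idx]), float(trace[idx])


def component_topography(erp: ERP, interval) -> Topography:
    """Per-channel time average over ``interval`` (or the single latency)."""
    if np.isscalar(interval):
        interval = (float(interval), float(interval))
    mask = _window_mask(erp.times, interval)
    return Topography(erp.mean[:, mask].mean(axis=1), erp.channel_labels)


def spatial_correlation(a: Topography, b: Topography) -> float:
    """Pearson correlation of two topographies over channels."""
    if a.channel_labels != b.channel_labels:
        raise ValueError("topographies must share the channel set")
    if len(a.channel_labels) < 3:
        raise ValueError("need at least 3 channels")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("zero-variance topography")
    return float(pearsonr(a.values, b.values).statistic)
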