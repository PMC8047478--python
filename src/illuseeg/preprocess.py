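"""FIR filtering, resampling, epoching and amplitude-based trial rejection.

The chain mirrors a standard EEG pipeline for a 1-kHz recording analysed at
200 Hz: one-pass zero-phase Hamming-windowed sinc FIR filters (a single
forward convolution compensated by the group delay of ``order/2`` samples),
integer-factor downsampling behind an anti-alias lowpass, event-anchored
epoching with both window endpoints included, and strict peak-to-peak
rejection. Independent component analysis is exposed only as an optional
hook (``ica_hook``) taking and returning a :class:`Recording`; by default it
is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import fftconvolve, firwin

__all__ = [
    "Recording",
    "FilterSpec",
    "EpochSet",
    "design_windowed_sinc",
    "filter_zero_phase",
    "downsample",
    "epoch",
    "reject_peak_to_peak",
    "HIGHPASS_TF",
    "LOWPASS_TF_TFA",
    "LOWPASS_TF_ERP",
]


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG in microvolts."""

    data: np.ndarray  # channels x samples
    rate: float
    channel_labels: tuple[str, ...]
    channel_positions: np.ndarray | None = None  # n_channels x 3, unit norm

    def __post_init__(self):
        data = np.atleast_2d(np.asarray(self.data, float))
        if len(self.channel_labels) != data.shape[0]:
            raise ValueError("channel label count must match data rows")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Windowed-sinc FIR specification (order = taps - 1, must be even)."""

    kind: str  # 'highpass' | 'lowpass'
    cutoff: float  # Hz, band edge at the center of the transition
    transition: float  # Hz
    order: int
    rate: float

    def __post_init__(self):
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError("kind must be 'highpass' or 'lowpass'")
        if self.order % 2:
            raise ValueError("order must be even for a type-I linear-phase FIR")
        if self.cutoff <= 0 or self.cutoff + self.transition / 2 >= self.rate / 2:
            raise ValueError("cutoff (+ half transition) must lie below Nyquist")


# Filter settings used for this analysis, at the 200 Hz working rate.
HIGHPASS_TF = FilterSpec("highpass", cutoff=0.3, transition=0.6, order=1100, rate=200.0)
LOWPASS_TF_TFA = FilterSpec("lowpass", cutoff=45.0, transition=8.0, order=84, rate=200.0)
LOWPASS_TF_ERP = FilterSpec("lowpass", cutoff=30.0, transition=7.5, order=88, rate=200.0)


def design_windowed_sinc(spec: FilterSpec) -> np.ndarray:
    """Hamming-windowed sinc taps with exact DC behaviour.

    Lowpass taps sum to one (unit DC gain); the highpass is the spectral
    inversion of the complementary lowpass, so its taps sum to exactly zero.
    """
    taps = firwin(
        spec.order + 1,
        spec.cutoff,
        window="hamming",
        pass_zero=True,
        fs=spec.rate,
    )
    if spec.kind == "highpass":
        taps = -taps
        taps[spec.order // 2] += 1.0
    return taps


def filter_zero_phase(rec: Recording, taps: np.ndarray) -> Recording:
    """One-pass zero-phase FIR filtering.

    A single forward convolution with symmetric (linear-phase) taps,
    shifted back by the group delay of ``(len(taps) - 1) / 2`` samples, so
    an impulse maps onto the taps centered at the impulse sample.
    """
    taps = np.asarray(taps, float)
    if rec.n_samples < taps.size:
        raise ValueError("recording shorter than the filter")
    delay = (taps.size - 1) // 2
    full = fftconvolve(rec.data, taps[None, :], mode="full")
    out = full[:, delay : delay + rec.n_samples]
    return replace(rec, data=out)


def downsample(rec: Recording, target: float = 200.0, antialias: bool = True) -> Recording:
    """Integer-factor decimation to ``target`` Hz behind an anti-alias lowpass.

    The anti-alias filter is a windowed-sinc lowpass at 0.8x the target
    Nyquist; the time base is preserved (sample k of the output is sample
    ``k * rate/target`` of the input).
    """
    if target > rec.rate:
        raise ValueError("target rate exceeds the recording rate")
    factor = rec.rate / target
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("rate must be an integer multiple of the target")
    factor = int(round(factor))
    if factor == 1:
        return rec
    out = rec
    if antialias:
        aa_cut = 0.8 * (target / 2.0)
        aa = FilterSpec("lowpass", cutoff=aa_cut, transition=0.2 * (target / 2.0),
                        order=200, rate=rec.rate)
        out = filter_zero_phase(out, design_windowed_sinc(aa))
    return replace(out, data=out.data[:, ::factor], rate=target)


@dataclass(frozen=True)
class EpochSet:
    """Trials x channels x time, with the anchor at t = 0.

    Both window endpoints are included at uniform ``1/rate`` spacing, so a
    ``[-pre, post]`` window at rate ``r`` yields ``(pre + post) * r + 1``
    samples.
    """

    data: np.ndarray  # trials x channels x time, microvolts
    times: np.ndarray  # s relative to the anchor
    rate: float
    alignment: str = "stimulus"  # 'stimulus' | 'response' | 'none'
    condition: str = ""
    channel_labels: tuple[str, ...] = ()
    channel_positions: np.ndarray | None = None
    dropped_anchors: tuple[float, ...] = ()

    def __post_init__(self):
        data = np.asarray(self.data, float)
        if data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        times = np.asarray(self.times, float)
        if times.size != data.shape[2]:
            raise ValueError("times length must match the time axis")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def epoch(
    rec: Recording,
    anchors: Sequence[float],
    window: tuple[float, float],
    alignment: str = "stimulus",
    condition: str = "",
) -> EpochSet:
    """Cut fixed windows around anchor times.

    ``window = (pre, post)`` with ``pre < 0 < post`` in seconds; anchors too
    close to the record edges are dropped and reported in
    ``EpochSet.dropped_anchors``.
    """
    pre, post = window
    if pre >= post:
        raise ValueError("window must satisfy pre < post")
    n_pre = int(round(-pre * rec.rate))
    n_post = int(round(post * rec.rate))
    times = np.arange(-n_pre, n_post + 1) / rec.rate
    trials, dropped = [], []
    for a in anchors:
        i = int(round(a * rec.rate))
        if i - n_pre < 0 or i + n_post >= rec.n_samples:
            dropped.append(float(a))
            continue
        trials.append(rec.data[:, i - n_pre : i + n_post + 1])
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.data.shape[0], times.size))
    )
    return EpochSet(
        data=data,
        times=times,
        rate=rec.rate,
        alignment=alignment,
        condition=condition,
        channel_labels=rec.channel_labels,
        channel_positions=rec.channel_positions,
        dropped_anchors=tuple(dropped),
    )


def reject_peak_to_peak(
    epochs: EpochSet,
    threshold: float = 300.0,
    exclude_channels: Sequence[str] = (),
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose peak-to-peak amplitude exceeds ``threshold`` (µV).

    A trial is kept iff ``max - min`` over every non-excluded channel is at
    most the threshold ("higher than" is strict, so exactly-threshold
    trials survive). Returns the kept epochs and the boolean keep-mask.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep_ch = np.array([lab not in set(exclude_channels) for lab in epochs.channel_labels])
    if epochs.channel_labels and not keep_ch.any():
        raise ValueError("all channels excluded from the rejection screen")
    data = epochs.data[:, keep_ch, :] if epochs.channel_labels else epochs.data
    p2p = data.max(axis=2) - data.min(axis=2)  # trials x channels
    mask = ~(p2p > threshold).any(axis=1)
    return replace(epochs, data=epochs.data[mask]), mask


def ica_hook(rec: Recording, hook: Callable[[Recording], Recording] | None = None) -> Recording:
    """Optional artifact-removal stage; identity unless a hook is supplied."""
    return rec if hook is None else hook(rec)
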