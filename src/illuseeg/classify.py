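"""Trial categorisation for a continuous signal-detection design.

The experiment has no discrete trials: stimuli and button presses share one
timeline, so hits, misses, false alarms (FAs) and correct rejections (CRs)
must be carved out of the continuous record. The criteria follow the
response-time distribution of the task:

* **hit** — a response occurs 300-1800 ms after a stimulus onset,
* **miss** — no response within 3600 ms of a stimulus onset,
* **FA** — a response with no stimulus onset in the preceding 3600 ms,
* **margin** — everything in between (deliberately discarded: a late
  response is neither confidently a hit nor confidently an FA),
* **CR** — stretches of the record free of stimuli and responses.

All times are in seconds and stay continuous; sample quantisation happens
only at epoching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import gaussian

__all__ = [
    "EventStream",
    "ClassificationParams",
    "TrialLabels",
    "smoothed_rt_histogram",
    "link_responses_to_stimuli",
    "classify_events",
    "extract_cr_anchors",
]


@dataclass(frozen=True)
class EventStream:
    """Stimulus onsets and response times for one session."""

    stim_onsets: np.ndarray  # s, strictly ascending
    responses: np.ndarray  # s, strictly ascending
    duration: float

    def __post_init__(self):
        stims = np.asarray(self.stim_onsets, float)
        resps = np.asarray(self.responses, float)
        for name, arr in (("stim_onsets", stims), ("responses", resps)):
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"{name} must be strictly ascending")
            if arr.size and (arr[0] < 0 or arr[-1] > self.duration):
                raise ValueError(f"{name} outside [0, duration]")
        object.__setattr__(self, "stim_onsets", stims)
        object.__setattr__(self, "responses", resps)


@dataclass(frozen=True)
class ClassificationParams:
    """Timing criteria, in seconds."""

    hit_window: tuple[float, float] = (0.3, 1.8)
    miss_horizon: float = 3.6
    fa_lockout: float = 3.6
    rt_bin: float = 0.042
    smooth_window: float = 0.420

    def __post_init__(self):
        lo, hi = self.hit_window
        if not 0 < lo < hi <= self.miss_horizon:
            raise ValueError("need 0 < hit_window.lo < hit_window.hi <= miss_horizon")
        if self.fa_lockout < hi:
            raise ValueError("fa_lockout must cover the hit window")


@dataclass
class TrialLabels:
    """Per-event labels plus correct-rejection anchors."""

    stim_labels: list[str]  # 'hit' | 'miss' | 'margin'
    resp_labels: list[str]  # 'hit_response' | 'fa' | 'margin'
    hit_pairs: list[tuple[int, int]]  # (stimulus index, response index)
    cr_anchors: np.ndarray = field(default_factory=lambda: np.empty(0))

    def counts(self) -> dict[str, int]:
        return {
            "hit": self.stim_labels.count("hit"),
            "miss": self.stim_labels.count("miss"),
            "fa": self.resp_labels.count("fa"),
            "cr": int(np.size(self.cr_anchors)),
            "stim_margin": self.stim_labels.count("margin"),
            "resp_margin": self.resp_labels.count("margin"),
        }


def smoothed_rt_histogram(
    rts, params: ClassificationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed response-time histogram as a probability density.

    Response times are binned at ``rt_bin`` (42 ms), smoothed with a
    Gaussian-weighted moving average of length ``smooth_window`` (420 ms),
    and rescaled so the trapezoidal integral over the bin centers is one.
    """
    params = params or ClassificationParams()
    rts = np.asarray(rts, float)
    if rts.size == 0:
        raise ValueError("no response times given")
    nbins = max(int(np.ceil((rts.max() - rts.min()) / params.rt_bin)), 1) + 2
    edges = rts.min() - params.rt_bin + np.arange(nbins + 1) * params.rt_bin
    counts, _ = np.histogram(rts, bins=edges)
    density = counts / (rts.size * params.rt_bin)
    nwin = max(int(round(params.smooth_window / params.rt_bin)), 1)
    # MATLAB-style Gaussian moving average: window of nwin bins, alpha=2.5
    kernel = gaussian(nwin, std=(nwin - 1) / 5.0 if nwin > 1 else 1.0)
    kernel /= kernel.sum()
    full = np.convolve(density, kernel, mode="full")
    start = (kernel.size - 1) // 2
    density = full[start : start + density.size]
    centers = (edges[:-1] + edges[1:]) / 2.0
    integral = np.trapezoid(density, centers)
    if integral > 0:
        density = density / integral
    return centers, density


def link_responses_to_stimuli(
    stream: EventStream, params: ClassificationParams | None = None
) -> dict[int, int]:
    """Assign responses to the stimuli they plausibly answer.

    A response is linked to the most recent stimulus whose onset lies in
    ``[response - hit_window.hi, response - hit_window.lo]``; the first such
    response wins per stimulus, so the mapping is injective on hits.
    Returns ``{stimulus index: response index}``.
    """
    params = params or ClassificationParams()
    lo, hi = params.hit_window
    mapping: dict[int, int] = {}
    for ri, r in enumerate(stream.responses):
        candidates = np.nonzero(
            (stream.stim_onsets >= r - hi) & (stream.stim_onsets <= r - lo)
        )[0]
        if candidates.size == 0:
            continue
        si = int(candidates[-1])  # the later (closer) stimulus
        if si not in mapping:
            mapping[si] = ri
    return mapping


def classify_events(
    stream: EventStream,
    params: ClassificationParams | None = None,
    epoch_halfwidth: float | None = None,
    cr_guard: float = 1.0,
) -> TrialLabels:
    """Label every stimulus and response in the stream.

    Stimuli become hits (a linked response in the 300-1800 ms window),
    misses (no response within the 3600 ms horizon) or margin trials;
    responses become hit responses, FAs (no stimulus in the 3600 ms
    lockout) or margin. If ``epoch_halfwidth`` is given, correct-rejection
    anchors are tiled into the event-free parts of the record.
    """
    params = params or ClassificationParams()
    mapping = link_responses_to_stimuli(stream, params)
    linked_responses = set(mapping.values())

    stim_labels = []
    for si, onset in enumerate(stream.stim_onsets):
        if si in mapping:
            stim_labels.append("hit")
        elif not np.any(
            (stream.responses >= onset) & (stream.responses <= onset + params.miss_horizon)
        ):
            stim_labels.append("miss")
        else:
            stim_labels.append("margin")

    resp_labels = []
    for ri, r in enumerate(stream.responses):
        if ri in linked_responses:
            resp_labels.append("hit_response")
        elif not np.any(
            (stream.stim_onsets >= r - params.fa_lockout) & (stream.stim_onsets <= r)
        ):
            resp_labels.append("fa")
        else:
            resp_labels.append("margin")

    labels = TrialLabels(
        stim_labels=stim_labels,
        resp_labels=resp_labels,
        hit_pairs=sorted((si, ri) for si, ri in mapping.items()),
    )
    if epoch_halfwidth is not None:
        labels.cr_anchors = extract_cr_anchors(stream, epoch_halfwidth, cr_guard)
    return labels


def extract_cr_anchors(
    stream: EventStream, epoch_halfwidth: float, guard: float = 1.0
) -> np.ndarray:
    """Tile correct-rejection anchors into event-free stretches.

    An anchor at time ``a`` requires that
    ``[a - halfwidth - guard, a + halfwidth + guard]`` contains no stimulus
    onset and no response; anchors are packed greedily left-to-right with
    non-overlapping epochs.
    """
    margin = epoch_halfwidth + guard
    events = np.sort(np.concatenate([stream.stim_onsets, stream.responses]))
    # event-free open intervals, clipped to the record
    bounds = np.concatenate([[0.0], events, [stream.duration]])
    anchors: list[float] = []
    for left, right in zip(bounds[:-1], bounds[1:]):
        # record edges need the epoch to fit but no event guard
        lo = left + margin if left > 0.0 else epoch_halfwidth
        hi = (right - margin) if right < stream.duration else stream.duration - epoch_halfwidth
        a = lo
        while a <= hi + 1e-12:
            anchors.append(a)
            a += 2.0 * epoch_halfwidth
    return np.asarray(anchors)
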