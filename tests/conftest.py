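import numpy as np
import pytest

from illuseeg.channels import subset_layout
from illuseeg.preprocess import EpochSet

RECOVERY_LABELS = subset_layout(19)[0]  # classic 10-20 set, includes Pz
RECOVERY_WINDOW = (-6.0, 6.0)  # long epochs so the 0.3 Hz highpass fits
RECOVERY_RATE = 200.0


def _erp_chain_filter(data):
    """The ERP analysis filters: 0.3 Hz highpass + 30 Hz lowpass."""
    from illuseeg.preprocess import (
        HIGHPASS_TF,
        LOWPASS_TF_ERP,
        Recording,
        design_windowed_sinc,
        filter_zero_phase,
    )

    rec = Recording(data, RECOVERY_RATE, tuple(str(i) for i in range(data.shape[0])))
    rec = filter_zero_phase(rec, design_windowed_sinc(HIGHPASS_TF))
    rec = filter_zero_phase(rec, design_windowed_sinc(LOWPASS_TF_ERP))
    return rec.data


def filtered_component_reference(spec, crop=(-1.5, 0.5)):
    """The noiseless planted component after the ERP filtering chain.

    The 0.3-30 Hz chain attenuates slow deflections (about 20% for the
    planted widths), so recovered amplitudes must be compared with the
    filtered waveform, not the raw planted amplitude.
    """
    n_t = int(round((RECOVERY_WINDOW[1] - RECOVERY_WINDOW[0]) * RECOVERY_RATE)) + 1
    times = RECOVERY_WINDOW[0] + np.arange(n_t) / RECOVERY_RATE
    bump = spec.amplitude * np.exp(
        -((times - spec.latency) ** 2) / (2 * spec.width**2)
    )
    clean = spec.topography[:, None] * bump[None, :]
    filt = _erp_chain_filter(clean)
    keep = (times >= crop[0]) & (times <= crop[1])
    return times[keep], filt[:, keep]


def filtered_grand_average(spec, seed, n_subjects=16, n_trials=100, crop=(-1.5, 0.5)):
    """Grand-average ERP of filtered subject averages with one planted
    component, mirroring the analysis chain (filter, average, baseline-free
    because the highpass removes the offset)."""
    from illuseeg import synth
    from illuseeg.erp import ERP

    gt = synth.GroundTruth(
        effects={"hit_resp": (spec,)},
        noise=synth.NoiseModel(),
        channel_labels=RECOVERY_LABELS,
        rate=RECOVERY_RATE,
        window=RECOVERY_WINDOW,
    )
    subs = []
    for k in range(n_subjects):
        ep = synth.simulate_subject(
            gt, n_trials={"hit_resp": n_trials}, seed=seed + k,
            conditions=("hit_resp",),
        )["hit_resp"]
        subs.append(_erp_chain_filter(ep.data.mean(axis=0)))
        times = ep.times
    sub = np.stack(subs)
    keep = (times >= crop[0]) & (times <= crop[1])
    return ERP(
        mean=sub[:, :, keep].mean(axis=0),
        sem=sub[:, :, keep].std(axis=0, ddof=1) / np.sqrt(n_subjects),
        times=times[keep],
        n_trials=n_subjects,
        rate=RECOVERY_RATE,
        channel_labels=RECOVERY_LABELS,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_layout():
    """10-channel scalp subset with unit-head positions."""
    return subset_layout(10)


def make_epochs(data, rate=200.0, t0=None, labels=None, **kw):
    """EpochSet from a (trials, channels, time) array with anchor at 0."""
    data = np.asarray(data, float)
    n_t = data.shape[2]
    t0 = -(n_t // 2) / rate if t0 is None else t0
    times = t0 + np.arange(n_t) / rate
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, times=times, rate=rate, channel_labels=labels, **kw)


@pytest.fixture
def epochs_factory():
    return make_epochs
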