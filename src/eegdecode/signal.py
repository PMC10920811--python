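"""Epoch extraction, artifact rejection and spectral feature extraction.

Covers the preprocessing front of the pipeline: cutting non-overlapping
fixed-length epochs out of continuous recordings (starting well after
task onset so stimulus-driven visual activity is excluded), peak-to-peak
amplitude rejection, the seven-band Butterworth filter bank feeding the
covariance pipelines, and multitaper band power feeding the handcrafted
relative-power pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal
from scipy.signal.windows import dpss

from .containers import BandDefinition, BandEpochs, EpochSet, FeatureMatrix, PSDSet, default_bands


def extract_epochs(
    continuous: np.ndarray,
    fs: float,
    onsets,
    *,
    trial_ends=None,
    start_offset: float = 5.0,
    length: float = 2.0,
    subject: str = "S01",
    group: str = "M",
    tasks=None,
    ch_names=None,
    ch_pos=None,
) -> EpochSet:
    """Cut consecutive non-overlapping epochs from each trial.

    For each trial onset, epoching starts ``start_offset`` seconds later
    and proceeds in back-to-back windows of ``length`` seconds until the
    trial ends (next onset, the supplied end/response time, or the end of
    the recording). Onsets whose first epoch would not fit are skipped
    with a warning. Labels are inherited from the parent trial.
    """
    continuous = np.asarray(continuous, float)
    if continuous.ndim != 2:
        raise ValueError("continuous must be (channels, samples)")
    n_ch, n_samp = continuous.shape
    duration = n_samp / fs
    onsets = list(np.atleast_1d(np.asarray(onsets, float)))
    if trial_ends is None:
        trial_ends = [onsets[i + 1] if i + 1 < len(onsets) else duration for i in range(len(onsets))]
    trial_ends = list(np.atleast_1d(np.asarray(trial_ends, float)))
    if tasks is None:
        tasks = ["verb"] * len(onsets)
    elif isinstance(tasks, str):
        tasks = [tasks] * len(onsets)
    n_per = int(round(length * fs))

    segs, task_l = [], []
    for onset, end, task in zip(onsets, trial_ends, tasks):
        t0 = onset + start_offset
        end = min(end, duration)
        if t0 + length > end + 1e-9:
            warnings.warn(f"trial at {onset:.3f}s too short after offset; skipped")
            continue
        n_ep = int(np.floor((end - t0) / length + 1e-9))
        start = int(round(t0 * fs))
        for k in range(n_ep):
            a = start + k * n_per
            if a + n_per > n_samp:
                break
            segs.append(continuous[:, a : a + n_per])
            task_l.append(task)

    data = np.stack(segs) if segs else np.empty((0, n_ch, n_per))
    n = len(segs)
    if ch_names is None:
        ch_names = [f"E{i + 1:03d}" for i in range(n_ch)]
    if ch_pos is None:
        ch_pos = np.zeros((n_ch, 3))
        ch_pos[:, 2] = 1.0
    return EpochSet(
        data=data,
        fs=fs,
        ch_names=list(ch_names),
        ch_pos=ch_pos,
        subject=[subject] * n,
        group=[group] * n,
        task=task_l,
    )


def reject_epochs(
    epochs: EpochSet, ptp_min: float = 1e-6, ptp_max: float = 150e-6
) -> tuple[EpochSet, np.ndarray]:
    """Peak-to-peak amplitude rejection.

    An epoch is kept iff every channel's peak-to-peak amplitude lies in
    ``[ptp_min, ptp_max]``: the lower bound catches flat/disconnected
    channels, the upper bound large transients. Returns the kept subset
    and the boolean keep-mask over the input epochs.
    """
    if not ptp_min < ptp_max:
        raise ValueError("need ptp_min < ptp_max")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (epochs, channels)
    mask = np.all((ptp >= ptp_min) & (ptp <= ptp_max), axis=1)
    if epochs.n_epochs and not mask.any():
        raise ValueError("peak-to-peak rejection removed every epoch")
    return epochs.select(mask), mask


def apply_filter_bank(
    epochs: EpochSet, bands: list[BandDefinition] | None = None, order: int = 4
) -> BandEpochs:
    """Zero-phase Butterworth band-pass decomposition into the analysis bands.

    Each band is filtered forward-backward (``sosfiltfilt``), so the
    output is phase-aligned with the input and the effective magnitude
    response is the squared Butterworth response.
    """
    bands = default_bands() if bands is None else bands
    for b in bands:
        b.validate_for_fs(epochs.fs)
    out = np.empty((len(bands),) + epochs.data.shape)
    for k, b in enumerate(bands):
        sos = sp_signal.butter(order, [b.low, b.high], btype="bandpass", fs=epochs.fs, output="sos")
        out[k] = sp_signal.sosfiltfilt(sos, epochs.data, axis=-1) if epochs.n_epochs else 0.0
    return BandEpochs(data=out, bands=list(bands), source=epochs)


def multitaper_band_power(
    epochs: EpochSet,
    bands: list[BandDefinition] | None = None,
    half_bandwidth: float = 1.0,
    n_tapers: int = 3,
) -> PSDSet:
    """Band-integrated multitaper power per epoch and channel.

    The PSD is the average of per-taper periodograms over ``n_tapers``
    DPSS tapers with spectral half-bandwidth ``half_bandwidth`` (Hz); it
    is then integrated over each band's frequency range, so the values
    are in signal-variance units (V^2) and the full-spectrum integral
    equals the epoch variance up to taper bias. The defaults (1 Hz
    half-bandwidth on 2-s epochs, i.e. NW=2, with the 2NW-1=3 well-
    concentrated tapers) keep the smoothing window narrower than the
    2-Hz analysis bands so band-specific effects stay in their band.
    """
    bands = default_bands() if bands is None else bands
    T = epochs.n_samples / epochs.fs
    min_bw = min(b.high - b.low for b in bands)
    if T < 2.0 / min_bw:
        raise ValueError(
            f"epoch length {T:.3f}s too short to resolve a {min_bw:.1f} Hz band"
        )
    nw = half_bandwidth * T  # time-half-bandwidth product
    tapers = dpss(epochs.n_samples, nw, Kmax=n_tapers)  # unit-energy rows
    freqs = np.fft.rfftfreq(epochs.n_samples, 1.0 / epochs.fs)
    df = epochs.fs / epochs.n_samples

    # (epochs, channels, tapers, freqs) is small at desk scale; stay vectorized
    x = epochs.data[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(x, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=2) * (2.0 / epochs.fs)
    # one-sided doubling does not apply to DC / Nyquist
    psd[..., 0] /= 2.0
    if epochs.n_samples % 2 == 0:
        psd[..., -1] /= 2.0

    power = np.empty((epochs.n_epochs, epochs.n_channels, len(bands)))
    for k, b in enumerate(bands):
        sel = (freqs >= b.low) & (freqs < b.high)
        power[:, :, k] = psd[:, :, sel].sum(axis=-1) * df
    return PSDSet(power=power, bands=list(bands), source=epochs)


def relative_power(psd: PSDSet, total_power: np.ndarray | None = None) -> FeatureMatrix:
    """Relative band power features, one value per (channel, band).

    By default each band's power is divided by the summed power over the
    seven analysis bands, so the seven values per channel partition to 1
    exactly. Passing ``total_power`` (epochs x channels, e.g. broadband
    variance) switches the denominator to that full-spectrum total.
    Channels with zero total power get the uninformative uniform value
    1/K with a warning.
    """
    K = len(psd.bands)
    denom = psd.power.sum(axis=2) if total_power is None else np.asarray(total_power, float)
    zero = denom <= 0
    rel = np.empty_like(psd.power)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} (epoch, channel) cells with zero total power")
    safe = np.where(zero, 1.0, denom)
    rel = psd.power / safe[:, :, None]
    rel[zero] = 1.0 / K
    names = [f"{ch}_{b.name}" for ch in psd.source.ch_names for b in psd.bands]
    values = rel.reshape(psd.power.shape[0], -1)
    return FeatureMatrix(values=values, feature_names=names, pipeline="handcrafted")


def read_continuous_edf(path, resample_to: float | None = None):
    """Read a continuous EDF/BDF recording via MNE.

    Returns ``(data, fs, ch_names)`` with data in volts. If
    ``resample_to`` is given the signal is polyphase-resampled.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    if resample_to is not None and resample_to != fs:
        from fractions import Fraction

        frac = Fraction(resample_to / fs).limit_denominator(1000)
        data = sp_signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        fs = resample_to
    return data, fs, list(raw.ch_names)
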