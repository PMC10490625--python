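"""EEG cleaning: mains notch, ICA artifact removal, epoching, SNR rejection.

The stage order is fixed — band-stop (60 Hz) -> ICA component removal ->
segmentation -> SNR-based epoch rejection -> 0.5-44 Hz band-pass — and is
logged by :func:`preprocess_recording`. All filtering is zero-phase
(forward-backward IIR), so epoch timing is preserved.

SNR is defined per epoch as ``10*log10(P_in / P_out)`` with ``P_in`` the mean
per-channel power in 0.5-44 Hz and ``P_out`` the mean per-channel power from
44 Hz to Nyquist, both from a Welch estimate of the pre-band-pass signal.
Epochs below the threshold (default 25 dB) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .simulate import EEG_CHANNELS, RawRecording

logger = logging.getLogger(__name__)

DEFAULT_SNR_THRESHOLD_DB = 25.0
IN_BAND = (0.5, 44.0)


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "band_stop" | "band_pass"
    f_low: float
    f_high: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"need 0 < f_low < f_high, got {self.f_low}, {self.f_high}")
        if self.f_high >= nyq:
            raise ValueError(
                f"f_high={self.f_high} Hz at or above Nyquist ({nyq} Hz)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.kind not in ("band_stop", "band_pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")

    def sos(self, sampling_rate_hz: float) -> np.ndarray:
        btype = "bandstop" if self.kind == "band_stop" else "bandpass"
        return signal.butter(
            self.order, [self.f_low, self.f_high], btype=btype,
            fs=sampling_rate_hz, output="sos",
        )


def notch_spec(freq: float = 60.0, half_width: float = 2.0, order: int = 4) -> FilterSpec:
    return FilterSpec("band_stop", freq - half_width, freq + half_width, order)


def bandpass_spec(f_low: float = 0.5, f_high: float = 44.0, order: int = 4) -> FilterSpec:
    return FilterSpec("band_pass", f_low, f_high, order)


@dataclass
class EpochSet:
    """Fixed-length labeled epochs: ``epochs`` is (n_epochs, channels, samples)."""

    epochs: np.ndarray
    labels: list[str]
    starts_s: list[float]
    channel_labels: list[str]
    sampling_rate_hz: float
    epoch_length_s: float
    snr_db: np.ndarray | None = None
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.kept is None:
            self.kept = np.ones(len(self.labels), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_only(self) -> "EpochSet":
        m = self.kept
        return EpochSet(
            epochs=self.epochs[m],
            labels=[l for l, k in zip(self.labels, m) if k],
            starts_s=[s for s, k in zip(self.starts_s, m) if k],
            channel_labels=list(self.channel_labels),
            sampling_rate_hz=self.sampling_rate_hz,
            epoch_length_s=self.epoch_length_s,
            snr_db=None if self.snr_db is None else self.snr_db[m],
            kept=np.ones(int(m.sum()), dtype=bool),
        )


def apply_filter(recording: RawRecording, spec: FilterSpec) -> RawRecording:
    """Zero-phase filter all channels; shape and annotations unchanged."""
    spec.validate(recording.sampling_rate_hz)
    sos = spec.sos(recording.sampling_rate_hz)
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.samples, axis=-1)
    else:
        filtered = signal.sosfilt(sos, recording.samples, axis=-1)
    return recording.copy_with(filtered)


def remove_artifact_components(
    recording: RawRecording,
    reference_labels: list[str],
    correlation_threshold: float = 0.7,
    max_iter: int = 500,
    seed: int = 0,
) -> RawRecording:
    """FastICA-based artifact removal guided by reference channels.

    The non-reference (EEG) channels are unmixed into independent components;
    any component whose absolute Pearson correlation with a reference channel
    (e.g. EOG, EMG) exceeds ``correlation_threshold`` is zeroed before
    remixing. With no reference channels the input is returned unchanged.
    """
    if not reference_labels:
        logger.warning("no reference channels given; skipping ICA artifact removal")
        return recording.copy_with(recording.samples.copy())
    missing = [r for r in reference_labels if r not in recording.channel_labels]
    if missing:
        raise ValueError(f"reference channels not in recording: {missing}")
    eeg_idx = [i for i, ch in enumerate(recording.channel_labels) if ch not in reference_labels]
    if len(eeg_idx) < 2:
        raise ValueError("need at least two EEG channels for ICA")
    X = recording.samples[eeg_idx].T  # time x channels
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer samples than channels; cannot decompose")

    ica = FastICA(
        n_components=len(eeg_idx), whiten="unit-variance",
        max_iter=max_iter, random_state=seed,
    )
    sources = ica.fit_transform(X)  # time x components
    refs = recording.samples[[recording.channel_labels.index(r) for r in reference_labels]]

    removed = []
    for c in range(sources.shape[1]):
        s = sources[:, c]
        if s.std() == 0:
            continue
        for ri, r in enumerate(refs):
            denom = s.std() * r.std()
            if denom == 0:
                continue
            corr = abs(np.mean((s - s.mean()) * (r - r.mean())) / denom)
            if corr > correlation_threshold:
                removed.append((c, reference_labels[ri], corr))
                sources[:, c] = 0.0
                break
    cleaned = ica.inverse_transform(sources).T
    out = recording.samples.copy()
    out[eeg_idx] = cleaned
    logger.info(
        "ICA removed %d/%d components: %s", len(removed), len(eeg_idx),
        [(c, ref, round(r, 3)) for c, ref, r in removed],
    )
    return recording.copy_with(out)


def segment_epochs(recording: RawRecording, epoch_length_s: float = 10.0) -> EpochSet:
    """Cut each annotated interval into consecutive non-overlapping epochs.

    A trailing remainder shorter than ``epoch_length_s`` is dropped, not
    padded. Each epoch carries its interval's activity label.
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    fs = recording.sampling_rate_hz
    n_samp = int(round(epoch_length_s * fs))
    epochs, labels, starts = [], [], []
    if not recording.annotations:
        logger.warning("recording has no annotations; empty epoch set")
    for start_s, end_s, label in sorted(recording.annotations):
        n_full = int(np.floor((end_s - start_s) / epoch_length_s + 1e-9))
        for k in range(n_full):
            i0 = int(round((start_s + k * epoch_length_s) * fs))
            if i0 + n_samp > recording.n_times:
                break
            epochs.append(recording.samples[:, i0 : i0 + n_samp])
            labels.append(label)
            starts.append(start_s + k * epoch_length_s)
    arr = np.stack(epochs) if epochs else np.empty((0, recording.n_channels, n_samp))
    return EpochSet(
        epochs=arr, labels=labels, starts_s=starts,
        channel_labels=list(recording.channel_labels),
        sampling_rate_hz=fs, epoch_length_s=epoch_length_s,
    )


def epoch_snr_db(
    epochs: EpochSet, in_band: tuple[float, float] = IN_BAND,
    channels: tuple[str, ...] = EEG_CHANNELS,
) -> np.ndarray:
    """Per-epoch in-band/out-of-band power ratio in dB (Welch estimate)."""
    fs = epochs.sampling_rate_hz
    ch_idx = [epochs.channel_labels.index(c) for c in channels if c in epochs.channel_labels]
    data = epochs.epochs[:, ch_idx, :]
    nper = min(int(2 * fs), data.shape[-1])
    f, psd = signal.welch(
        data, fs=fs, window="hamming", nperseg=nper,
        noverlap=int(0.1 * nper), axis=-1,
    )
    lo, hi = in_band
    m_in = (f >= lo) & (f <= hi)
    m_out = f > hi
    p_in = np.trapezoid(psd[..., m_in], f[m_in], axis=-1).mean(axis=-1)
    p_out = np.trapezoid(psd[..., m_out], f[m_out], axis=-1).mean(axis=-1)
    with np.errstate(divide="ignore"):
        return np.where(p_out > 0, 10 * np.log10(np.maximum(p_in, 1e-300) / p_out), np.inf)


def estimate_snr_and_reject(
    epochs: EpochSet, threshold_db: float = DEFAULT_SNR_THRESHOLD_DB
) -> EpochSet:
    """Flag epochs whose SNR falls below ``threshold_db`` (kept iff >= threshold).

    Zero out-of-band power gives SNR +inf and the epoch is kept. Operates on
    the pre-band-pass signal path.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    if not np.isfinite(threshold_db):
        raise ValueError("threshold_db must be finite")
    snr = epoch_snr_db(epochs)
    kept = snr >= threshold_db
    logger.info(
        "SNR rejection at %.1f dB: kept %d / %d epochs",
        threshold_db, int(kept.sum()), epochs.n_epochs,
    )
    return replace_epochs(epochs, snr_db=snr, kept=kept)


def replace_epochs(epoch_set: EpochSet, **kw) -> EpochSet:
    epochs = epoch_set
    base = dict(
        epochs=epochs.epochs, labels=list(epochs.labels), starts_s=list(epochs.starts_s),
        channel_labels=list(epochs.channel_labels),
        sampling_rate_hz=epochs.sampling_rate_hz, epoch_length_s=epochs.epoch_length_s,
        snr_db=epochs.snr_db, kept=epochs.kept,
    )
    base.update(kw)
    return EpochSet(**base)


def bandpass_epochs(epochs: EpochSet, spec: FilterSpec | None = None) -> EpochSet:
    """Zero-phase band-pass each epoch independently (default 0.5-44 Hz)."""
    spec = spec or bandpass_spec()
    spec.validate(epochs.sampling_rate_hz)
    if epochs.n_epochs == 0:
        return epochs
    sos = spec.sos(epochs.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, epochs.epochs, axis=-1)
    return replace_epochs(epochs, epochs=filtered)


def preprocess_recording(
    recording: RawRecording,
    notch_freq: float = 60.0,
    band_pass: tuple[float, float] = IN_BAND,
    snr_threshold_db: float = DEFAULT_SNR_THRESHOLD_DB,
    epoch_length_s: float = 10.0,
    reference_labels: list[str] | None = None,
    correlation_threshold: float = 0.7,
    filter_order: int = 4,
    ica_seed: int = 0,
) -> EpochSet:
    """Run the full cleaning chain in its fixed order and return all epochs
    (rejected ones flagged, not removed)."""
    if reference_labels is None:
        reference_labels = [c for c in ("EOG", "EMG") if c in recording.channel_labels]
    logger.info(
        "preprocessing order: band-stop %.0f Hz -> ICA -> SNR >= %.0f dB -> band-pass %s Hz",
        notch_freq, snr_threshold_db, band_pass,
    )
    rec = apply_filter(recording, notch_spec(notch_freq, order=filter_order))
    rec = remove_artifact_components(rec, reference_labels, correlation_threshold, seed=ica_seed)
    epochs = segment_epochs(rec, epoch_length_s)
    epochs = estimate_snr_and_reject(epochs, snr_threshold_db)
    epochs = bandpass_epochs(epochs, bandpass_spec(*band_pass, order=filter_order))
    return epochs
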