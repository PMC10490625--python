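"""Per-epoch EEG spectral features.

For every kept 10-s epoch this module computes, from a Welch PSD per channel:

* relative band power ``RP_<Band>_<Region>`` — a band's integrated power
  divided by the total 0.5-44 Hz power of that region, for the five
  canonical bands (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30,
  gamma 30-44 Hz) and regions F (Fz), C (mean of C1/C2), T (mean of T7/T8),
  O (Oz) and G (mean of all six channels);
* the pairwise-derived brain symmetry index ``pdBSI`` — the mean over
  homologous left/right pairs and frequency bins of
  ``|R - L| / (R + L)``, ranging from 0 (symmetric) to 1 (one side silent),
  per band and broadband, for the central (C2 vs C1) and temporal
  (T8 vs T7) pairs;
* the power ratios DAR = delta/alpha, DTR = delta/theta and
  DTABR = (delta+theta)/(alpha+beta) per region F/C/T/O.

Channel averaging happens in the power domain after integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochSet
from .simulate import BANDS, EEG_CHANNELS

logger = logging.getLogger(__name__)

BAND_NAMES = tuple(BANDS)  # delta, theta, alpha, beta, gamma
RP_REGIONS = ("F", "C", "T", "O", "G")
RATIO_REGIONS = ("F", "C", "T", "O")
HOMOLOGOUS_PAIRS = {"C": ("C2", "C1"), "T": ("T8", "T7")}

REGION_CHANNELS = {
    "F": ("Fz",),
    "C": ("C1", "C2"),
    "T": ("T7", "T8"),
    "O": ("Oz",),
    "G": EEG_CHANNELS,
}


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float


DEFAULT_BANDS = [BandDefinition(n, lo, hi) for n, (lo, hi) in BANDS.items()]


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator settings: Hamming taper, default 2-s segments
    (0.5 Hz resolution, resolving the 0.5 Hz delta edge) with 10% overlap."""

    segment_length_s: float = 2.0
    overlap_fraction: float = 0.1
    window: str = "hamming"


@dataclass
class SpectrumEstimate:
    frequencies: np.ndarray
    psd: np.ndarray  # channels x frequencies, uV^2/Hz
    channel_labels: list[str]
    epoch_index: int = 0
    welch_params: WelchParams = WelchParams()


def welch_psd(
    epoch: np.ndarray,
    sampling_rate_hz: float,
    params: WelchParams = WelchParams(),
    channel_labels: list[str] | None = None,
    epoch_index: int = 0,
) -> SpectrumEstimate:
    """Averaged-periodogram PSD of one epoch (channels x samples).

    Density scaling: the integral of the PSD over frequency equals the
    signal variance up to taper-correction tolerance (Parseval).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nper = int(round(params.segment_length_s * sampling_rate_hz))
    if nper > epoch.shape[-1]:
        raise ValueError(
            f"Welch segment ({nper} samples) longer than epoch ({epoch.shape[-1]})"
        )
    f, psd = signal.welch(
        epoch, fs=sampling_rate_hz, window=params.window, nperseg=nper,
        noverlap=int(params.overlap_fraction * nper), axis=-1, scaling="density",
    )
    labels = channel_labels or [f"ch{i}" for i in range(epoch.shape[0])]
    return SpectrumEstimate(f, psd, list(labels), epoch_index, params)


def _band_edges_ok(bands: list[BandDefinition], frequencies: np.ndarray) -> None:
    fmax = frequencies.max()
    for b in bands:
        if b.f_low < frequencies.min() - 1e-9 or b.f_high > fmax + 1e-9:
            raise ValueError(
                f"band {b.name} [{b.f_low}, {b.f_high}] outside frequency grid "
                f"[{frequencies.min()}, {fmax}]"
            )


def integrate_band(
    frequencies: np.ndarray, psd: np.ndarray, f_low: float, f_high: float
) -> np.ndarray:
    """Trapezoid integral of the PSD over [f_low, f_high] along the last axis.

    Band edges are inserted by linear interpolation so adjacent bands tile
    the axis exactly (each trapezoid panel is counted once).
    """
    inner = (frequencies > f_low) & (frequencies < f_high)
    grid = np.concatenate(([f_low], frequencies[inner], [f_high]))
    if psd.ndim == 1:
        interp = np.interp(grid, frequencies, psd)
        return np.trapezoid(interp, grid)
    # vectorized endpoint interpolation for nd psd
    lo_val = _interp_nd(frequencies, psd, f_low)
    hi_val = _interp_nd(frequencies, psd, f_high)
    interp = np.concatenate(
        [lo_val[..., None], psd[..., inner], hi_val[..., None]], axis=-1
    )
    return np.trapezoid(interp, grid, axis=-1)


def _interp_nd(x: np.ndarray, y: np.ndarray, x0: float) -> np.ndarray:
    i = np.searchsorted(x, x0)
    if i == 0:
        return y[..., 0]
    if i >= len(x):
        return y[..., -1]
    if x[i] == x0:
        return y[..., i]
    w = (x0 - x[i - 1]) / (x[i] - x[i - 1])
    return (1 - w) * y[..., i - 1] + w * y[..., i]


@dataclass
class BandPowerSet:
    """Integrated band powers per channel and per region (uV^2)."""

    power: dict[tuple[str, str], float]  # (channel, band) -> power
    region_power: dict[tuple[str, str], float]  # (region, band) -> power


def band_powers(
    spectrum: SpectrumEstimate, bands: list[BandDefinition] | None = None
) -> BandPowerSet:
    bands = bands or DEFAULT_BANDS
    _band_edges_ok(bands, spectrum.frequencies)
    power: dict[tuple[str, str], float] = {}
    for ci, ch in enumerate(spectrum.channel_labels):
        for b in bands:
            power[(ch, b.name)] = float(
                integrate_band(spectrum.frequencies, spectrum.psd[ci], b.f_low, b.f_high)
            )
    region_power: dict[tuple[str, str], float] = {}
    for region, chans in REGION_CHANNELS.items():
        present = [c for c in chans if c in spectrum.channel_labels]
        if not present:
            continue
        for b in bands:
            region_power[(region, b.name)] = float(
                np.mean([power[(c, b.name)] for c in present])
            )
    return BandPowerSet(power=power, region_power=region_power)


def relative_power(bp: BandPowerSet) -> dict[tuple[str, str], float]:
    """Relative band power per region: each band's power over the region's
    total across the five bands. Regions with zero total give NaN (flagged)."""
    out: dict[tuple[str, str], float] = {}
    regions = sorted({r for r, _ in bp.region_power})
    for region in regions:
        total = sum(bp.region_power[(region, b)] for b in BAND_NAMES)
        for b in BAND_NAMES:
            out[(region, b)] = (
                bp.region_power[(region, b)] / total if total > 0 else np.nan
            )
        if total <= 0:
            logger.warning("region %s has zero total power; RP undefined", region)
    return out


def pdbsi(rt: np.ndarray, lt: np.ndarray) -> float:
    """Pairwise-derived brain symmetry index of right/left PSD arrays.

    ``rt`` and ``lt`` are (pairs x bins) or (bins,) nonnegative PSD values;
    returns ``mean(|R - L| / (R + L))`` over all pair/bin cells, skipping
    cells with ``R + L = 0``. NaN if every cell is zero.
    """
    rt = np.atleast_2d(np.asarray(rt, dtype=float))
    lt = np.atleast_2d(np.asarray(lt, dtype=float))
    if rt.shape != lt.shape:
        raise ValueError(f"shape mismatch: {rt.shape} vs {lt.shape}")
    if (rt < 0).any() or (lt < 0).any():
        raise ValueError("PSD values must be nonnegative")
    s = rt + lt
    mask = s > 0
    if not mask.any():
        return float("nan")
    return float(np.mean(np.abs(rt - lt)[mask] / s[mask]))


def band_bin_mask(
    frequencies: np.ndarray, f_low: float, f_high: float, last_band: bool = False
) -> np.ndarray:
    """Bins belonging to a band: half-open [f_low, f_high), shared edges going
    to the upper band; the uppermost band includes its upper edge."""
    m = (frequencies >= f_low) & (frequencies < f_high)
    if last_band:
        m |= np.isclose(frequencies, f_high)
    return m


def spectral_ratios(bp: BandPowerSet, region: str) -> tuple[float, float, float]:
    """(DAR, DTR, DTABR) for a region; zero denominators give NaN."""
    p = {b: bp.region_power[(region, b)] for b in BAND_NAMES}
    dar = p["delta"] / p["alpha"] if p["alpha"] > 0 else np.nan
    dtr = p["delta"] / p["theta"] if p["theta"] > 0 else np.nan
    ab = p["alpha"] + p["beta"]
    dtabr = (p["delta"] + p["theta"]) / ab if ab > 0 else np.nan
    return dar, dtr, dtabr


def feature_columns() -> list[str]:
    """The fixed, documented column order of the feature table."""
    cols = [f"RP_{b.capitalize()}_{r}" for b in BAND_NAMES for r in RP_REGIONS]
    cols += [f"pdBSI_{b.capitalize()}_{p}" for b in BAND_NAMES for p in ("C", "T")]
    cols += ["pdBSI_C", "pdBSI_T"]
    for ratio in ("DAR", "DTR", "DTABR"):
        cols += [f"{ratio}_{r}" for r in RATIO_REGIONS]
    return cols


def build_feature_table(
    epochs: EpochSet,
    bands: list[BandDefinition] | None = None,
    welch_params: WelchParams = WelchParams(),
) -> pd.DataFrame:
    """One row per kept epoch with all named spectral features plus ``label``.

    Rows with any undefined mandatory feature (zero-power region, zero ratio
    denominator, all-zero homologous spectra) are dropped with a logged count.
    """
    bands = bands or DEFAULT_BANDS
    kept = epochs.kept_only()
    cols = feature_columns()
    if kept.n_epochs == 0:
        return pd.DataFrame(columns=cols + ["label"])

    eeg_idx = [kept.channel_labels.index(c) for c in EEG_CHANNELS]
    data = kept.epochs[:, eeg_idx, :]
    fs = kept.sampling_rate_hz
    nper = int(round(welch_params.segment_length_s * fs))
    if nper > data.shape[-1]:
        raise ValueError("Welch segment longer than epoch")
    freqs, psd = signal.welch(
        data, fs=fs, window=welch_params.window, nperseg=nper,
        noverlap=int(welch_params.overlap_fraction * nper), axis=-1,
    )  # psd: (epochs, channels, freqs)

    # integrated band power per epoch/channel/band
    bp = {
        b.name: integrate_band(freqs, psd, b.f_low, b.f_high) for b in bands
    }  # each (epochs, channels)
    ch_pos = {c: i for i, c in enumerate(EEG_CHANNELS)}

    def region_pow(band: str, region: str) -> np.ndarray:
        idx = [ch_pos[c] for c in REGION_CHANNELS[region]]
        return bp[band][:, idx].mean(axis=1)

    out: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for region in RP_REGIONS:
            total = sum(region_pow(b, region) for b in BAND_NAMES)
            for b in BAND_NAMES:
                out[f"RP_{b.capitalize()}_{region}"] = np.where(
                    total > 0, region_pow(b, region) / np.where(total > 0, total, 1.0), np.nan
                )
        for ratio_region in RATIO_REGIONS:
            p = {b: region_pow(b, ratio_region) for b in BAND_NAMES}
            out[f"DAR_{ratio_region}"] = np.where(p["alpha"] > 0, p["delta"] / np.where(p["alpha"] > 0, p["alpha"], 1.0), np.nan)
            out[f"DTR_{ratio_region}"] = np.where(p["theta"] > 0, p["delta"] / np.where(p["theta"] > 0, p["theta"], 1.0), np.nan)
            ab = p["alpha"] + p["beta"]
            out[f"DTABR_{ratio_region}"] = np.where(ab > 0, (p["delta"] + p["theta"]) / np.where(ab > 0, ab, 1.0), np.nan)

    # pdBSI per pair, per band and broadband
    last = max(bands, key=lambda b: b.f_high)
    for pair_name, (right, left) in HOMOLOGOUS_PAIRS.items():
        r_psd = psd[:, ch_pos[right], :]
        l_psd = psd[:, ch_pos[left], :]
        for b in bands:
            m = band_bin_mask(freqs, b.f_low, b.f_high, last_band=b is last)
            out[f"pdBSI_{b.name.capitalize()}_{pair_name}"] = _pdbsi_rows(
                r_psd[:, m], l_psd[:, m]
            )
        m = (freqs >= min(b.f_low for b in bands)) & (freqs <= last.f_high)
        out[f"pdBSI_{pair_name}"] = _pdbsi_rows(r_psd[:, m], l_psd[:, m])

    table = pd.DataFrame({c: out[c] for c in cols})
    table["label"] = kept.labels
    n_before = len(table)
    table = table.dropna()
    dropped = n_before - len(table)
    if dropped:
        logger.info("dropped %d epochs with undefined features", dropped)
    return table.reset_index(drop=True)


def _pdbsi_rows(r: np.ndarray, l: np.ndarray) -> np.ndarray:
    s = r + l
    d = np.abs(r - l)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s > 0, d / np.where(s > 0, s, 1.0), np.nan)
    counts = (s > 0).sum(axis=1)
    vals = np.nansum(frac, axis=1) / np.where(counts > 0, counts, 1)
    return np.where(counts > 0, vals, np.nan)
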