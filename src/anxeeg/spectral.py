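"""Welch power spectra and the MP / RASM / AI feature table.

Within each 1-s epoch (128 samples at 128 Hz) the Welch estimate uses 64-sample
segments with 50% overlap under a Hamming taper: three segments and 2 Hz
frequency resolution. With 2 Hz bins and inclusive band edges, theta (5-7 Hz)
is represented by the single 6 Hz bin; this is a direct consequence of the
epoch length and is documented rather than smoothed over.

Features per epoch:

* ``MP_<ch>_<band>``      mean PSD (uV^2/Hz) over the band's bins;
* ``RASM_<L>-<R>_<band>`` left/right band-power ratio for a homologous pair;
* ``AI_<L>-<R>_<band>``   normalized difference (L-R)/(L+R) in [-1, 1]
  (a log-ratio variant is available via ``ai_mode="log"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import EpochMatrix
from .synth import BANDS

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")

#: Homologous left/right channel pairs, left first.
PAIRS: tuple[tuple[str, str], ...] = (("AF3", "AF4"), ("FC5", "FC6"), ("P7", "P8"))


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float

    def validate(self) -> None:
        if self.low >= self.high:
            raise ValueError("band low edge must be below high edge")


@dataclass
class PsdVector:
    """A single channel's PSD estimate."""

    freqs: np.ndarray      # bin centers, Hz
    values: np.ndarray     # uV^2/Hz
    channel: str | None = None

    def validate(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("PSD values must be non-negative")
        d = np.diff(self.freqs)
        if np.any(d <= 0) or not np.allclose(d, d[0]):
            raise ValueError("freqs must be strictly increasing and uniform")


def welch_psd_array(x: np.ndarray, fs: float, seg_len: int = 64,
                    overlap: float = 0.5, taper: str = "hamming"):
    """Welch PSD along the last axis of an arbitrary-dimensional array.

    Returns ``(freqs, pxx)`` with ``pxx`` in density scaling, so
    ``pxx.sum(-1) * df`` approximates the mean-square signal power.
    """
    if seg_len > x.shape[-1]:
        raise ValueError(
            f"seg_len {seg_len} exceeds signal length {x.shape[-1]}")
    noverlap = int(round(seg_len * overlap))
    freqs, pxx = sps.welch(x, fs=fs, window=taper, nperseg=seg_len,
                           noverlap=noverlap, detrend=False, axis=-1)
    return freqs, pxx


def welch_psd(x: np.ndarray, fs: float, seg_len: int = 64, overlap: float = 0.5,
              taper: str = "hamming", channel: str | None = None) -> PsdVector:
    """Welch PSD of one channel's samples."""
    freqs, pxx = welch_psd_array(np.asarray(x, dtype=float), fs,
                                 seg_len=seg_len, overlap=overlap, taper=taper)
    return PsdVector(freqs=freqs, values=pxx, channel=channel)


def normalize_psd(values: np.ndarray) -> np.ndarray:
    """Min-max normalization onto [0, 14] (one unit per headset channel):
    ``(x - min) / (max - min) * 14``."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant PSD (max == min)")
    return (values - lo) / (hi - lo) * 14.0


def band_power(psd: PsdVector, band: BandDefinition | str) -> float:
    """Mean PSD over bins with center frequency inside [low, high] inclusive."""
    if isinstance(band, str):
        lo, hi = BANDS[band]
        band = BandDefinition(band, lo, hi)
    band.validate()
    mask = (psd.freqs >= band.low) & (psd.freqs <= band.high)
    if not mask.any():
        raise ValueError(
            f"no PSD bins inside band {band.name} [{band.low}, {band.high}] Hz")
    return float(psd.values[mask].mean())


def compute_rasm(p_left: float, p_right: float) -> float:
    """Rational asymmetry: left/right band-power ratio."""
    if p_right <= 0:
        raise ValueError("right-hemisphere power must be positive")
    return p_left / p_right


def compute_ai(p_left: float, p_right: float, mode: str = "normalized") -> float:
    """Asymmetry index. ``normalized``: (L-R)/(L+R); ``log``: ln(L) - ln(R)."""
    if mode == "normalized":
        s = p_left + p_right
        if s <= 0:
            raise ValueError("total pair power must be positive")
        return (p_left - p_right) / s
    if mode == "log":
        if p_left <= 0 or p_right <= 0:
            raise ValueError("log asymmetry requires positive powers")
        return float(np.log(p_left) - np.log(p_right))
    raise ValueError(f"unknown AI mode {mode!r}")


def feature_columns(channels, bands, pairs) -> list[str]:
    """Column names in contract order: MP by channel x band, then RASM and AI
    by pair x band."""
    cols = [f"MP_{ch}_{b}" for ch in channels for b in bands]
    cols += [f"RASM_{l}-{r}_{b}" for l, r in pairs for b in bands]
    cols += [f"AI_{l}-{r}_{b}" for l, r in pairs for b in bands]
    return cols


def parse_feature_name(col: str) -> tuple[str, str, str]:
    """Split a feature column name into (kind, site, band)."""
    parts = col.split("_")
    if len(parts) != 3 or parts[0] not in ("MP", "RASM", "AI") \
            or parts[2] not in BANDS:
        raise ValueError(f"unparseable feature column name {col!r}")
    return parts[0], parts[1], parts[2]


def build_feature_table(epochs: EpochMatrix,
                        channels=None, bands=None, pairs=None,
                        seg_len: int = 64, overlap: float = 0.5,
                        taper: str = "hamming",
                        ai_mode: str = "normalized") -> pd.DataFrame:
    """One row per epoch of MP, RASM and AI features.

    ``channels`` defaults to all epoch channels; ``pairs`` defaults to the
    homologous pairs whose two channels are both requested. Band order follows
    the canonical delta<theta<alpha<beta<gamma ordering.
    """
    if channels is None:
        channels = list(epochs.channels)
    bands = list(bands) if bands is not None else list(BAND_ORDER)
    for b in bands:
        if b not in BANDS:
            raise ValueError(f"unknown band {b!r}")
    if pairs is None:
        pairs = [(l, r) for l, r in PAIRS if l in channels and r in channels]
    missing = [c for c in channels if c not in epochs.channels]
    missing += [c for p in pairs for c in p if c not in epochs.channels]
    if missing:
        raise ValueError(f"channels not present in epochs: {sorted(set(missing))}")

    cols = feature_columns(channels, bands, pairs)
    if epochs.n_epochs == 0:
        return pd.DataFrame(np.empty((0, len(cols))), columns=cols)

    ch_idx = {c: i for i, c in enumerate(epochs.channels)}
    freqs, pxx = welch_psd_array(epochs.epochs, epochs.fs, seg_len=seg_len,
                                 overlap=overlap, taper=taper)
    # per-band mean PSD: (n_epochs, n_channels) for each band
    band_p = {}
    for b in bands:
        lo, hi = BANDS[b]
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"no PSD bins inside band {b}")
        band_p[b] = pxx[..., mask].mean(axis=-1)

    data = {}
    for ch in channels:
        for b in bands:
            data[f"MP_{ch}_{b}"] = band_p[b][:, ch_idx[ch]]
    for l, r in pairs:
        for b in bands:
            pl = band_p[b][:, ch_idx[l]]
            pr = band_p[b][:, ch_idx[r]]
            data[f"RASM_{l}-{r}_{b}"] = pl / pr
            if ai_mode == "normalized":
                data[f"AI_{l}-{r}_{b}"] = (pl - pr) / (pl + pr)
            elif ai_mode == "log":
                data[f"AI_{l}-{r}_{b}"] = np.log(pl) - np.log(pr)
            else:
                raise ValueError(f"unknown AI mode {ai_mode!r}")
    table = pd.DataFrame(data, columns=cols)
    if table.isna().any().any() or not np.all(np.isfinite(table.to_numpy())):
        raise ValueError("feature table contains non-finite values")
    return table
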