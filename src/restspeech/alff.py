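"""Amplitude of low-frequency fluctuations (ALFF).

The linearly detrended node signal is taken to the frequency domain with an
FFT; the square root of the power spectrum (the one-sided amplitude spectrum,
``a_k = 2 |X_k| / N``) is averaged over the frequency bins falling inside the
low-frequency band, 0.008-0.09 Hz by default, both edges inclusive and the DC
bin excluded.  Per-participant summaries are the mean ALFF over the
left-language nodes and over all included nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend

from .connectome import TimeSeriesMatrix

DEFAULT_BAND = (0.008, 0.09)


class InvalidBandError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class ALFFProfile:
    participant: str
    node_alff: dict[str, float]
    language_mean: float | None
    whole_brain_mean: float
    normalized: bool = False


def band_bins(n: int, tr_seconds: float, band: tuple[float, float]) -> np.ndarray:
    """Indices k of DFT bins with low <= k/(n*tr) <= high, k >= 1."""
    low, high = band
    if not 0 <= low < high:
        raise InvalidBandError(f"invalid band {band}")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if high > nyquist + 1e-12:
        raise InvalidBandError(f"band high {high} Hz exceeds Nyquist {nyquist} Hz")
    freqs = np.arange(1, n // 2 + 1) / (n * tr_seconds)
    # closed band on both edges; epsilon guards the float grid at the edges
    eps = 1e-9
    ks = np.nonzero((freqs >= low - eps) & (freqs <= high + eps))[0] + 1
    if len(ks) == 0:
        raise InvalidBandError(
            f"no DFT bins inside {band} Hz at resolution {1.0 / (n * tr_seconds):.6g} Hz"
        )
    return ks


def node_alff(signal: np.ndarray, tr_seconds: float,
              band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Mean square-root spectral power of one detrended node signal in-band."""
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 8:
        raise ValueError("signal too short for a meaningful spectrum")
    ks = band_bins(n, tr_seconds, band)
    x = np.fft.rfft(detrend(signal, type="linear"))
    amp = 2.0 * np.abs(x) / n
    return float(amp[ks].mean())


def alff_profile(ts: TimeSeriesMatrix, atlas: pd.DataFrame,
                 band: tuple[float, float] = DEFAULT_BAND) -> ALFFProfile:
    """Node-level ALFF for every included node plus language/whole-brain means."""
    node_vals: dict[str, float] = {}
    for nid in atlas["node_id"]:
        try:
            node_vals[nid] = node_alff(ts.signal(nid), ts.tr_seconds, band)
        except (ValueError, InvalidBandError) as exc:
            raise type(exc)(f"node {nid!r}: {exc}") from exc
    lang = atlas.loc[atlas["language_side"] == "left", "node_id"].tolist()
    language_mean = float(np.mean([node_vals[n] for n in lang])) if lang else None
    whole = float(np.mean(list(node_vals.values())))
    return ALFFProfile(participant=ts.participant, node_alff=node_vals,
                       language_mean=language_mean, whole_brain_mean=whole)


def normalize_values(values: dict[str, float]) -> dict[str, float]:
    """Standardize across participants: (value - mean) / SD, n-1 denominator."""
    if len(values) < 2:
        raise NormalizationError("need at least 2 participants to standardize")
    ids = list(values)
    arr = np.array([values[i] for i in ids], dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise NormalizationError("zero SD: values cannot be standardized")
    z = (arr - arr.mean()) / sd
    return dict(zip(ids, z.tolist()))


def profiles_to_frame(profiles: list[ALFFProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for nid, v in p.node_alff.items():
            rows.append({"participant": p.participant, "node": nid, "alff": v})
    return pd.DataFrame(rows)


def summaries_to_frame(profiles: list[ALFFProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [p.participant for p in profiles],
            "language_mean": [p.language_mean for p in profiles],
            "whole_brain_mean": [p.whole_brain_mean for p in profiles],
        }
    )
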