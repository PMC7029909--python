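"""Per-window feature characteristics of the differenced magnitude signals.

Sixteen characteristics are computed per sensor modality (accelerometer
and gyroscope magnitude difference), giving a 32-dimensional vector per
7 s window:

time domain
    mean, standard deviation, minimum, maximum, skewness, kurtosis,
    interquartile range, median, zero crossings (after mean removal),
    signal area SA = Σ|x| / f_s

frequency domain (from the plain, un-tapered DFT of the window)
    spectral entropy SE = −Σ PSD_norm · ln PSD_norm,
    dominant frequency, spectral area SpA = 2 Σ_{n≥1} S(f_n)·Δf,
    2nd and 3rd harmonic frequencies (next-highest power bins),
    harmonic ratio HR = Σ even-bin amplitudes / Σ odd-bin amplitudes

Conventions for degenerate (all-zero or constant) windows and the two
documented reading ambiguities (signed vs absolute signal area; harmonic
ratio over DFT bin parity vs multiples of the dominant frequency) are
fixed by :class:`FeatureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ovinesense.preprocess import AnnotatedWindow

#: per-modality characteristic names, in table order
BASE_FEATURE_NAMES = [
    "mean",
    "std",
    "min",
    "max",
    "skewness",
    "kurtosis",
    "interquantile_range",
    "median",
    "zero_crossings",
    "signal_area",
    "spectral_entropy",
    "dominant_frequency",
    "spectral_area",
    "harmonic_freq_2",
    "harmonic_freq_3",
    "harmonic_ratio",
]

#: the full 32-entry feature-vector column order (accel block then gyro block)
FEATURE_NAMES = [f"{mod}_{name}" for mod in ("accel", "gyro") for name in BASE_FEATURE_NAMES]

META_COLUMNS = ["sheep_id", "window_index", "activity", "lame"]


@dataclass(frozen=True)
class FeatureConfig:
    """Resolves the two reading ambiguities in the characteristic table.

    ``signal_area_absolute``: SA sums |x| (default) rather than the signed
    samples — the differenced magnitude is near zero-mean, so the signed
    sum would be ≈ 0 for every window and carry no intensity information.

    ``harmonic_ratio_bins``: HR sums amplitudes over even- vs odd-indexed
    DFT bins (default, the literal index reading); the alternative sums
    over even vs odd integer multiples of the dominant-frequency bin.
    """

    signal_area_absolute: bool = True
    harmonic_ratio_bins: bool = True


@dataclass
class PowerSpectrum:
    """One-sided periodogram of a window, from the plain DFT.

    ``psd`` holds the one-sided power spectral density without interior
    doubling (S(f_n) = |X_n|² / (N·f_s)); ``psd_norm`` is S normalised to
    unit sum; ``amplitudes`` are the raw DFT magnitudes |X_n|.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    psd_norm: np.ndarray
    amplitudes: np.ndarray
    delta_f: float
    n_bins: int
    degenerate: bool = False


def time_domain_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, std, min, max, skewness, kurtosis, IQR and median.

    Moments are population (biased) estimators; kurtosis is excess
    kurtosis; a zero-variance window takes skewness = kurtosis = 0 by
    convention.  Quantiles use linear interpolation.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need >= 4 samples for the time-domain statistics")
    mean = float(np.mean(values))
    std = float(np.std(values))  # population
    centred = values - mean
    if std > 0:
        skewness = float(np.mean(centred**3) / std**3)
        kurtosis = float(np.mean(centred**4) / std**4 - 3.0)
    else:
        skewness = 0.0
        kurtosis = 0.0
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "mean": mean,
        "std": std,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "interquantile_range": float(q3 - q1),
        "median": float(np.median(values)),
    }


def zero_crossings(values: np.ndarray) -> int:
    """Sign changes of the mean-removed window.

    Exact zeros carry the previous nonzero sign; leading zeros carry no
    sign and cannot produce a crossing.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 samples to count zero crossings")
    signs = np.sign(values - np.mean(values))
    count = 0
    prev = 0.0
    for s in signs:
        if s == 0:
            continue
        if prev != 0 and s != prev:
            count += 1
        prev = s
    return count


def signal_area(
    values: np.ndarray, f_s: float, config: FeatureConfig | None = None
) -> float:
    """SA = Σ Mag · (1/f_s); by default Mag enters as |value|."""
    if f_s <= 0:
        raise ValueError("sampling rate must be positive")
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("window must be non-empty")
    if config is None or config.signal_area_absolute:
        return float(np.sum(np.abs(values)) / f_s)
    return float(np.sum(values) / f_s)


def compute_spectrum(values: np.ndarray, f_s: float) -> PowerSpectrum:
    """One-sided periodogram of the un-tapered, un-detrended window."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ValueError("need >= 8 samples for a spectrum")
    dft = np.fft.rfft(values)
    amplitudes = np.abs(dft)
    psd = amplitudes**2 / (n * f_s)
    delta_f = f_s / n
    frequencies = np.arange(len(dft)) * delta_f
    total = psd.sum()
    degenerate = bool(np.all(values == 0.0)) or total == 0.0
    psd_norm = psd / total if not degenerate else np.zeros_like(psd)
    return PowerSpectrum(
        frequencies=frequencies,
        psd=psd,
        psd_norm=psd_norm,
        amplitudes=amplitudes,
        delta_f=delta_f,
        n_bins=len(dft),
        degenerate=degenerate,
    )


def spectral_entropy(spectrum: PowerSpectrum) -> float:
    """SE = −Σ PSD_norm ln PSD_norm (natural log, 0·ln 0 = 0)."""
    if spectrum.degenerate:
        return 0.0
    p = spectrum.psd_norm[spectrum.psd_norm > 0]
    return float(-np.sum(p * np.log(p)))


def dominant_and_harmonic_frequencies(
    spectrum: PowerSpectrum,
) -> tuple[float, float, float]:
    """Frequencies of the three highest-power non-DC bins, descending.

    The DC bin is excluded (residual drift of a differenced signal is not
    rhythm); power ties break toward the lower frequency.
    """
    if spectrum.degenerate:
        return (0.0, 0.0, 0.0)
    if spectrum.n_bins < 4:
        raise ValueError("need >= 4 spectral bins")
    power = spectrum.psd[1:]
    freqs = spectrum.frequencies[1:]
    order = np.lexsort((freqs, -power))[:3]
    return tuple(float(freqs[i]) for i in order)


def spectral_area(spectrum: PowerSpectrum) -> float:
    """SpA = 2 Σ_{n=1}^{N} S(f_n)·Δf over the one-sided PSD, DC excluded."""
    if spectrum.degenerate:
        return 0.0
    return float(2.0 * spectrum.delta_f * np.sum(spectrum.psd[1:]))


def harmonic_ratio(
    spectrum: PowerSpectrum, config: FeatureConfig | None = None
) -> float:
    """HR = Σ even amplitudes / Σ odd amplitudes (0 if the denominator is 0).

    The default reads "even/odd" as DFT bin-index parity (DC excluded);
    the configurable alternative sums amplitudes at even vs odd integer
    multiples of the dominant-frequency bin.
    """
    if spectrum.degenerate:
        return 0.0
    amps = spectrum.amplitudes
    if config is None or config.harmonic_ratio_bins:
        even = float(np.sum(amps[2::2]))
        odd = float(np.sum(amps[1::2]))
    else:
        power = spectrum.psd[1:]
        k = int(np.argmax(power)) + 1  # dominant bin
        idx = np.arange(1, (len(amps) - 1) // k + 1)
        harmonics = amps[idx * k]
        even = float(np.sum(harmonics[1::2]))  # 2k, 4k, ...
        odd = float(np.sum(harmonics[0::2]))  # k, 3k, ...
    return even / odd if odd > 0 else 0.0


def _modality_features(
    values: np.ndarray, f_s: float, config: FeatureConfig
) -> dict[str, float]:
    out = time_domain_stats(values)
    out["zero_crossings"] = float(zero_crossings(values))
    out["signal_area"] = signal_area(values, f_s, config)
    spectrum = compute_spectrum(values, f_s)
    out["spectral_entropy"] = spectral_entropy(spectrum)
    dom, second, third = dominant_and_harmonic_frequencies(spectrum)
    out["dominant_frequency"] = dom
    out["harmonic_freq_2"] = second
    out["harmonic_freq_3"] = third
    out["spectral_area"] = spectral_area(spectrum)
    out["harmonic_ratio"] = harmonic_ratio(spectrum, config)
    return out


def extract_features(
    window: AnnotatedWindow, f_s: float, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All 32 characteristics of one window, keyed by ``FEATURE_NAMES``."""
    if config is None:
        config = FeatureConfig()
    out: dict[str, float] = {}
    for mod, values in (
        ("accel", window.samples_accel_diff),
        ("gyro", window.samples_gyro_diff),
    ):
        feats = _modality_features(values, f_s, config)
        out.update({f"{mod}_{name}": feats[name] for name in BASE_FEATURE_NAMES})
    return out


def feature_table(
    windows: list[AnnotatedWindow],
    f_s: float,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature matrix for a batch of windows.

    Columns: ``sheep_id, window_index, activity, lame`` followed by the 32
    feature columns in ``FEATURE_NAMES`` order.  This table is the
    contract between extraction and modelling.
    """
    records = []
    for w in windows:
        rec = {
            "sheep_id": w.sheep_id,
            "window_index": w.window_index,
            "activity": w.activity,
            "lame": bool(w.lame),
        }
        rec.update(extract_features(w, f_s, config))
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=META_COLUMNS + FEATURE_NAMES)
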