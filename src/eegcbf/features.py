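"""The 20 quantitative-EEG parameters computed per 2-s sub-epoch.

Time domain
    BSR (burst suppression ratio, %), Magnitude (max |x|, µV),
    Ratio05 (% of samples with |x| < 5 µV).
Frequency domain (half-open bands, P[a, b) in µV²)
    BetaR   = log10(P[20,47) / P[11,20))
    DeltaR  = log10(P[8,20)  / P[1,4))
    DAR     = log10(P[1,4)   / P[8,13))
    DTABR   = log10(P[1,8)   / P[8,30))
    power fractions of total 1–47 Hz power: ExtraPR [40,47), AlphaPR [8,13),
    BetaPR [13,30), DeltaPR [1,4), ThetaPR [4,8), GammaPR [30,47);
    BG_AlphaPlus = 100 * P[8,47)/P[1,47);
    BcSEF = SEF95 * (1 - BSR/100), SEF95 the lowest frequency below which
    95 % of 1–47 Hz power lies.
Bispectral
    SynchFastSlow: log10 ratio of bispectral magnitude over the full
    0.5–47 Hz triangle to the 40–47 Hz sum-frequency region.
Entropies (natural log)
    Shannon and Rényi (alpha = 0.5) of the per-sample energy distribution
    p_i = x_i^2 / sum(x^2); log-energy entropy either of the raw sample
    energies sum(log x_i^2) (default, the wavelet-toolbox convention) or of
    the normalized p_i; spectral entropy of the 1–47 Hz power distribution,
    normalized to [0, 1].

Band ratios and SynchFastSlow use log10 (the BIS-family convention);
entropies use the natural log. All logs are epsilon-floored so every feature
is finite on every input, including an all-zero window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .preprocess import PowerSpectrum, band_power, power_spectrum
from .records import SubEpoch

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "magnitude",
    "ratio05",
    "burst_suppression_ratio",
    "log_band_ratio",
    "power_fraction",
    "bcsef",
    "signal_entropy",
    "spectral_entropy",
    "synch_fast_slow",
    "extract_feature_vector",
]

#: canonical column order of the feature table
FEATURE_NAMES = (
    "BSR",
    "Magnitude",
    "SynchFastSlow",
    "BetaR",
    "DeltaR",
    "DAR",
    "DTABR",
    "BcSEF",
    "ExtraPR",
    "AlphaPR",
    "BetaPR",
    "DeltaPR",
    "ThetaPR",
    "GammaPR",
    "ShannonEntropy",
    "LogEnergyEntropy",
    "SpectralEntropy",
    "RenyiEntropy",
    "Ratio05",
    "BG_AlphaPlus",
)

EPS = 1e-12

#: classical band edges (Hz), half-open [a, b)
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 47.0),
    "extra": (40.0, 47.0),
    "total": (1.0, 47.0),
}


@dataclass
class FeatureConfig:
    """Conventions that the source definitions leave open.

    suppression_threshold_uv / suppression_min_run_s
        BSR counts contiguous runs with |x| below the threshold lasting at
        least the minimum run length (the standard burst-suppression
        convention; 5 µV matches the isoelectric limit).
    entropy_convention
        "raw_energy" computes the log-energy entropy as sum(log x_i^2) over
        raw µV samples (wavelet-toolbox convention); "probability" uses the
        normalized energy distribution, sum(log p_i^2).
    """

    suppression_threshold_uv: float = 5.0
    suppression_min_run_s: float = 0.5
    ratio05_threshold_uv: float = 5.0
    entropy_convention: str = "raw_energy"
    sef_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.entropy_convention not in ("raw_energy", "probability"):
            raise ValueError(
                f"unknown entropy convention {self.entropy_convention!r}"
            )


def _samples(subepoch: SubEpoch | np.ndarray) -> np.ndarray:
    x = subepoch.samples if isinstance(subepoch, SubEpoch) else np.asarray(subepoch, float)
    if x.size == 0:
        raise ValueError("empty sub-epoch")
    return x


def magnitude(subepoch: SubEpoch | np.ndarray) -> float:
    """Maximal absolute amplitude during the epoch (µV)."""
    return float(np.max(np.abs(_samples(subepoch))))


def ratio05(subepoch: SubEpoch | np.ndarray, threshold_uv: float = 5.0) -> float:
    """Percentage of samples with amplitude strictly under ±threshold µV."""
    x = _samples(subepoch)
    return 100.0 * float(np.count_nonzero(np.abs(x) < threshold_uv)) / x.size


def burst_suppression_ratio(
    subepoch: SubEpoch | np.ndarray,
    fs: float | None = None,
    threshold_uv: float = 5.0,
    min_run_s: float = 0.5,
) -> float:
    """Percentage of epoch time spent in suppression.

    Suppression = contiguous runs with |x| < threshold lasting at least
    ``min_run_s`` seconds.
    """
    if isinstance(subepoch, SubEpoch):
        x, fs = subepoch.samples, subepoch.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        x = np.asarray(subepoch, float)
    if x.size == 0:
        raise ValueError("empty sub-epoch")
    below = np.abs(x) < threshold_uv
    min_run = int(round(min_run_s * fs))
    # run-length encode the boolean trace
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [below.size]))
    suppressed = sum(
        e - s for s, e in zip(starts, ends) if below[s] and (e - s) >= min_run
    )
    return 100.0 * suppressed / x.size


def log_band_ratio(
    spectrum: PowerSpectrum,
    num_band: tuple[float, float],
    den_band: tuple[float, float],
) -> float:
    """log10 of the ratio of two band powers, epsilon-floored."""
    num = band_power(spectrum, *num_band)
    den = band_power(spectrum, *den_band)
    return float(np.log10(max(num, EPS) / max(den, EPS)))


def power_fraction(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Band power as a fraction of total 1–47 Hz power, in [0, 1]."""
    total = band_power(spectrum, *BANDS["total"])
    if total <= 0:
        warnings.warn("zero total 1-47 Hz power; power fraction reported as 0")
        return 0.0
    return band_power(spectrum, *band) / total


def spectral_edge_frequency(
    spectrum: PowerSpectrum, quantile: float = 0.95
) -> float:
    """Lowest frequency below which ``quantile`` of 1–47 Hz power lies."""
    mask = (spectrum.freqs >= BANDS["total"][0]) & (spectrum.freqs < BANDS["total"][1])
    power = spectrum.power[mask]
    freqs = spectrum.freqs[mask]
    total = power.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, quantile * total))
    idx = min(idx, freqs.size - 1)
    return float(freqs[idx])


def bcsef(spectrum: PowerSpectrum, bsr: float, quantile: float = 0.95) -> float:
    """Burst-suppression-compensated spectral edge frequency.

    SEF95 scaled by (1 - BSR/100): a fully suppressed epoch (BSR = 100)
    has BcSEF = 0 regardless of its spectrum.
    """
    if not 0 <= bsr <= 100:
        raise ValueError(f"BSR must be in [0, 100], got {bsr}")
    return spectral_edge_frequency(spectrum, quantile) * (1.0 - bsr / 100.0)


def amplitude_distribution(x: np.ndarray) -> np.ndarray:
    """Per-sample energy distribution p_i = x_i^2 / sum(x^2).

    Falls back to the uniform distribution for an all-zero window so the
    entropies stay finite.
    """
    energy = np.square(np.asarray(x, float))
    total = energy.sum()
    if total <= 0:
        return np.full(energy.size, 1.0 / energy.size)
    return energy / total


def signal_entropy(
    subepoch: SubEpoch | np.ndarray,
    kind: str,
    entropy_convention: str = "raw_energy",
) -> float:
    """Shannon, log-energy or Rényi (alpha = 0.5) entropy of the epoch.

    Natural log throughout; probabilities are epsilon-floored inside logs.
    """
    x = _samples(subepoch)
    p = amplitude_distribution(x)
    if kind == "shannon":
        return float(-np.sum(p * np.log(np.maximum(p, EPS))))
    if kind == "renyi":
        # 1/(1-alpha) * log(sum p^alpha) at alpha = 0.5
        return float(2.0 * np.log(max(np.sum(np.sqrt(p)), EPS)))
    if kind == "log_energy":
        if entropy_convention == "raw_energy":
            return float(np.sum(np.log(np.maximum(np.square(x), EPS))))
        return float(np.sum(np.log(np.maximum(p, EPS) ** 2)))
    raise ValueError(f"unknown entropy kind {kind!r}")


def spectral_entropy(spectrum: PowerSpectrum) -> float:
    """Normalized Shannon entropy of the 1–47 Hz power distribution.

    Division by log(n_bins) maps the value to [0, 1]: a flat spectrum gives
    1, a single occupied bin gives 0. Zero total power gives 0.
    """
    mask = (spectrum.freqs >= BANDS["total"][0]) & (spectrum.freqs < BANDS["total"][1])
    power = spectrum.power[mask]
    total = power.sum()
    if total <= 0:
        return 0.0
    q = power / total
    h = -np.sum(q * np.log(np.maximum(q, EPS)))
    return float(h / np.log(q.size))


@lru_cache(maxsize=8)
def _bispectrum_regions(n: int, fs: float) -> tuple[np.ndarray, ...]:
    """Index triples (i, j, i+j) for the bispectral triangle at this n, fs."""
    df = fs / n
    n_bins = n // 2 + 1
    lo = int(np.ceil(0.5 / df))  # lowest in-band bin (0.5 Hz)
    hi = int(np.floor(47.0 / df))  # highest sum-frequency bin (47 Hz)
    i, j = np.meshgrid(np.arange(lo, hi + 1), np.arange(lo, hi + 1), indexing="ij")
    tri = (j <= i) & (i + j <= hi) & (i + j < n_bins)
    ii, jj = i[tri], j[tri]
    fsum = (ii + jj) * df
    fast = fsum >= 40.0
    return ii, jj, ii + jj, fast


def synch_fast_slow(subepoch: SubEpoch | np.ndarray, fs: float | None = None) -> float:
    """Relative bispectral synchrony of fast and slow waves.

    log10 of the bispectral magnitude summed over the full 0.5–47 Hz
    triangle divided by the sum over the region whose sum frequency falls
    in 40–47 Hz. Both sums are epsilon-floored, so an all-zero window maps
    to 0.
    """
    if isinstance(subepoch, SubEpoch):
        x, fs = subepoch.samples, subepoch.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        x = np.asarray(subepoch, float)
    if x.size == 0:
        raise ValueError("empty sub-epoch")
    x = x - x.mean()
    spec = np.fft.rfft(x)
    ii, jj, kk, fast = _bispectrum_regions(x.size, float(fs))
    b = np.abs(spec[ii] * spec[jj] * np.conj(spec[kk]))
    num = b.sum()
    den = b[fast].sum()
    return float(np.log10(max(num, EPS) / max(den, EPS)))


def extract_feature_vector(
    subepoch: SubEpoch, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All 20 parameters for one sub-epoch, keyed by FEATURE_NAMES."""
    cfg = config or FeatureConfig()
    x = subepoch.samples
    spec = power_spectrum(subepoch)
    bsr = burst_suppression_ratio(
        subepoch,
        threshold_uv=cfg.suppression_threshold_uv,
        min_run_s=cfg.suppression_min_run_s,
    )
    values = {
        "BSR": bsr,
        "Magnitude": magnitude(x),
        "SynchFastSlow": synch_fast_slow(subepoch),
        "BetaR": log_band_ratio(spec, (20.0, 47.0), (11.0, 20.0)),
        "DeltaR": log_band_ratio(spec, (8.0, 20.0), BANDS["delta"]),
        "DAR": log_band_ratio(spec, BANDS["delta"], BANDS["alpha"]),
        "DTABR": log_band_ratio(spec, (1.0, 8.0), (8.0, 30.0)),
        "BcSEF": bcsef(spec, bsr, cfg.sef_quantile),
        "ExtraPR": power_fraction(spec, BANDS["extra"]),
        "AlphaPR": power_fraction(spec, BANDS["alpha"]),
        "BetaPR": power_fraction(spec, BANDS["beta"]),
        "DeltaPR": power_fraction(spec, BANDS["delta"]),
        "ThetaPR": power_fraction(spec, BANDS["theta"]),
        "GammaPR": power_fraction(spec, BANDS["gamma"]),
        "ShannonEntropy": signal_entropy(x, "shannon"),
        "LogEnergyEntropy": signal_entropy(x, "log_energy", cfg.entropy_convention),
        "SpectralEntropy": spectral_entropy(spec),
        "RenyiEntropy": signal_entropy(x, "renyi"),
        "Ratio05": ratio05(x, cfg.ratio05_threshold_uv),
        "BG_AlphaPlus": 100.0 * power_fraction(spec, (8.0, 47.0)),
    }
    return {name: values[name] for name in FEATURE_NAMES}
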