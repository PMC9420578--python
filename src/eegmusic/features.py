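"""Rhythm band-energy-ratio and sliding sample-entropy features.

Two feature families are computed per epoch and concatenated into a
50-column row:

* columns 0–24: sliding-average sample entropy — the epoch is split into 25
  half-overlapping windows spanning its full length, sample entropy (SampEn,
  the Richman–Moorman statistic) is computed per window, and each output is
  the running mean of the current and previous window;
* columns 25–49: frequency band energy ratios (FBER) — the epoch is split
  into 5 equal windows; in each, the harmonic-wavelet-packet energy of the
  five rhythms is expressed as a percentage of the total (5 windows x 5
  bands, window-major order).

The harmonic wavelet packet transform (HWPT) is realized in the Newland
construction: harmonic wavelets are ideal boxcar filters in the frequency
domain, so the transform is an exact FFT-bin partition and Parseval's
identity holds to machine precision.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bands import RHYTHM_BANDS, RHYTHM_NAMES, ConfigurationError, validate_bands
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

REMAINDER_BAND = "_rest"


@dataclass
class HWPTCoefficients:
    """Complex per-band coefficient sequences from the boxcar FFT partition.

    ``coeffs[band][k]`` is the band-limited component at time index k; the
    bands (including the remainder band covering everything outside the five
    rhythms) partition all FFT bins, so summed squared magnitudes equal the
    time-domain energy exactly.
    """

    coeffs: "OrderedDict[str, np.ndarray]"
    fs: float
    band_edges_hz: "OrderedDict[str, tuple[float, float]]"

    def total_energy(self) -> float:
        return float(sum(np.sum(np.abs(c) ** 2) for c in self.coeffs.values()))


def harmonic_wavelet_packet(signal: np.ndarray, fs: float,
                            bands=RHYTHM_BANDS) -> HWPTCoefficients:
    """Partition the signal's FFT bins into rhythm bands and invert each.

    Each FFT bin is assigned to the band whose [low, high) interval contains
    its absolute frequency (bins outside every rhythm go to a remainder
    band); the inverse FFT of each masked spectrum gives that band's complex
    coefficient sequence.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    validate_bands(bands)
    if max(hi for _, hi in bands.values()) > fs / 2:
        raise ConfigurationError("band edge above Nyquist frequency")
    n = x.size
    X = np.fft.fft(x)
    freqs = np.abs(np.fft.fftfreq(n, 1.0 / fs))

    assigned = np.zeros(n, dtype=bool)
    coeffs: "OrderedDict[str, np.ndarray]" = OrderedDict()
    edges: "OrderedDict[str, tuple[float, float]]" = OrderedDict()
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi) & ~assigned
        assigned |= mask
        coeffs[name] = np.fft.ifft(np.where(mask, X, 0.0))
        edges[name] = (lo, hi)
    coeffs[REMAINDER_BAND] = np.fft.ifft(np.where(~assigned, X, 0.0))
    edges[REMAINDER_BAND] = (0.0, fs / 2)
    return HWPTCoefficients(coeffs=coeffs, fs=fs, band_edges_hz=edges)


def band_energy(coeffs: HWPTCoefficients, p: str):
    """Per-time energy trace and total energy of rhythm ``p``.

    Returns ``(energy_k, E_p)`` where ``energy_k[k]`` is the squared
    coefficient magnitude at time index k and ``E_p`` is its sum.
    """
    if p not in coeffs.coeffs:
        raise KeyError(f"unknown rhythm {p!r}")
    energy_k = np.abs(coeffs.coeffs[p]) ** 2
    return energy_k, float(energy_k.sum())


def fber(epoch: np.ndarray, fs: float, bands=RHYTHM_BANDS) -> np.ndarray:
    """Five-band energy percentages; entries sum to exactly 100."""
    coeffs = harmonic_wavelet_packet(epoch, fs, bands)
    energies = np.array([band_energy(coeffs, name)[1] for name in bands])
    total = energies.sum()
    if total <= 0:
        raise ValueError("zero total energy in epoch")
    return energies / total * 100.0


def sample_entropy_counts(signal: np.ndarray, m: int = 2,
                          r: float = 0.2) -> tuple:
    """Template-match pair counts ``(A, B)`` underlying SampEn(m, r).

    Both counts run over the ``N - m`` templates that admit a length-(m+1)
    extension, Chebyshev distance, tolerance ``r * SD``, self-matches
    excluded (Richman–Moorman convention).
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"signal too short for SampEn (need >= {m + 2})")
    sd = float(x.std())
    if sd == 0:
        raise ValueError("zero variance")
    tol = r * sd

    emb = sliding_window_view(x, m + 1)          # [n - m, m + 1]
    diff = np.abs(emb[:, None, :] - emb[None, :, :])
    d_m = diff[:, :, :m].max(axis=2)
    d_m1 = diff.max(axis=2)
    iu = np.triu_indices(emb.shape[0], k=1)
    B = int(np.count_nonzero(d_m[iu] <= tol))
    A = int(np.count_nonzero(d_m1[iu] <= tol))
    return A, B


def sample_entropy(signal: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with r as a fraction of the signal SD.

    ``-ln(A/B)`` where B counts template pairs of length m within Chebyshev
    distance ``r * SD`` and A the same for length m+1; self-matches excluded.
    Returns ``inf`` when no length-(m+1) pairs match.
    """
    A, B = sample_entropy_counts(signal, m=m, r=r)
    if A == 0 or B == 0:
        return float("inf")
    return float(-np.log(A / B))


def sliding_sample_entropy(epoch: np.ndarray, n_windows: int = 25,
                           m: int = 2, r: float = 0.2) -> np.ndarray:
    """Sliding-average SampEn over half-overlapping windows of an epoch.

    The epoch is covered by ``n_windows`` windows of equal length with 50%
    overlap; each output value is the mean of the current and previous
    window's SampEn (the first window passes through unchanged).
    """
    x = np.asarray(epoch, dtype=float)
    L = x.size
    min_len = n_windows * (m + 2)
    if L < min_len:
        raise ValueError(
            f"epoch too short for {n_windows} entropy windows: "
            f"need >= {min_len} samples, got {L}")
    w = int(2 * L // (n_windows + 1))
    stride = w // 2
    vals = np.empty(n_windows)
    for i in range(n_windows):
        start = i * stride
        window = x[start:start + w]
        try:
            vals[i] = sample_entropy(window, m=m, r=r)
        except ValueError as exc:
            raise ValueError(f"window {i}: {exc}") from exc
    out = vals.copy()
    out[1:] = 0.5 * (vals[1:] + vals[:-1])
    return out


def sliding_fber(epoch: np.ndarray, fs: float, bands=RHYTHM_BANDS,
                 n_windows: int = 5) -> np.ndarray:
    """FBER over equal non-overlapping windows, window-major concatenation.

    With the default 5 windows and 5 rhythms the output has 25 entries:
    ``[w0:delta..gamma, w1:delta..gamma, ...]``; each window's five entries
    sum to 100.
    """
    x = np.asarray(epoch, dtype=float)
    w = x.size // n_windows
    if w < 2:
        raise ValueError("epoch too short for the requested FBER windows")
    out = np.empty(n_windows * len(bands))
    for i in range(n_windows):
        out[i * len(bands):(i + 1) * len(bands)] = fber(
            x[i * w:(i + 1) * w], fs, bands)
    return out


@dataclass
class FeatureMatrix:
    """Epoch-by-feature matrix with aligned labels and subject ids.

    Columns 0–24 hold sliding SampEn values, 25–49 the FBER percentages
    (before any standardization).
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    column_names: list
    standardized: bool = False

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]


def feature_column_names(n_entropy: int = 25, n_fber_windows: int = 5) -> list:
    names = [f"sampen_{i:02d}" for i in range(n_entropy)]
    for w in range(n_fber_windows):
        names.extend(f"fber_w{w}_{band}" for band in RHYTHM_NAMES)
    return names


def build_feature_matrix(epochs: EpochSet, m: int = 2, r: float = 0.2,
                         bands=RHYTHM_BANDS, n_entropy_windows: int = 25,
                         n_fber_windows: int = 5,
                         train_mask: np.ndarray | None = None) -> FeatureMatrix:
    """Assemble the 50-column feature matrix from an epoch set.

    Per-channel feature vectors are averaged across channels into one row per
    epoch.  When ``train_mask`` is supplied the columns are z-scored using
    statistics of the training rows only (so no information leaks from the
    test rows); without a mask the matrix is left on its natural scale.
    Epochs on which a feature operation fails are dropped with a logged
    reason.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    rows, kept = [], []
    for i in range(epochs.n_epochs):
        try:
            per_channel = []
            for ch in range(epochs.epochs.shape[1]):
                sig = epochs.epochs[i, ch]
                se = sliding_sample_entropy(sig, n_windows=n_entropy_windows,
                                            m=m, r=r)
                fb = sliding_fber(sig, epochs.fs, bands,
                                  n_windows=n_fber_windows)
                per_channel.append(np.concatenate([se, fb]))
            row = np.mean(per_channel, axis=0)
            if not np.all(np.isfinite(row)):
                raise ValueError("non-finite feature value")
        except ValueError as exc:
            logger.warning("dropping epoch %d: %s", i, exc)
            continue
        rows.append(row)
        kept.append(i)
    if not rows:
        raise ValueError("all epochs failed feature extraction")
    kept = np.asarray(kept)
    X = np.vstack(rows)
    y = epochs.labels[kept]
    subjects = epochs.subject_ids[kept]

    standardized = False
    if train_mask is not None:
        mask = np.asarray(train_mask, bool)[kept]
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        standardized = True
    return FeatureMatrix(X=X, y=y, subject_ids=subjects,
                         column_names=feature_column_names(
                             n_entropy_windows,
                             n_fber_windows),
                         standardized=standardized)


def standardize_features(fm: FeatureMatrix,
                         train_mask: np.ndarray) -> FeatureMatrix:
    """Z-score the columns of an assembled matrix on training-row statistics."""
    mask = np.asarray(train_mask, bool)
    if mask.shape[0] != fm.n_epochs:
        raise ValueError("train_mask length must match the number of rows")
    mu = fm.X[mask].mean(axis=0)
    sd = fm.X[mask].std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureMatrix(X=(fm.X - mu) / sd, y=fm.y.copy(),
                         subject_ids=fm.subject_ids.copy(),
                         column_names=list(fm.column_names),
                         standardized=True)
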