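"""Denoising by Hilbert–Huang decomposition plus FastICA, and epoch cutting.

The pipeline applied by :func:`denoise`:

1. per channel, empirical mode decomposition (EMD); intrinsic mode functions
   (IMFs) whose median instantaneous frequency falls outside the 0.5–45 Hz
   rhythm range are dropped before reconstruction (this removes mains
   interference and slow drift);
2. FastICA across channels; components flagged as artifact-like (excess
   kurtosis outlier or mains-band concentration) are zeroed and the rest
   back-projected.

EMD follows the classic sifting construction: cubic-spline envelopes through
the signal extrema (mirror-extended at the ends to curb edge effects), with
the Cauchy standard-deviation stopping rule.  FastICA is the symmetric
fixed-point iteration with the tanh (log-cosh) contrast after eigenvalue
whitening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert as _hilbert
from scipy.stats import kurtosis as _kurtosis

from .bands import MAX_BAND_EDGE_HZ, MIN_BAND_EDGE_HZ, ConfigurationError
from .synthetic import EEGRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------

@dataclass
class IMFDecomposition:
    """EMD result: ``sum(imfs) + residue`` reconstructs the input exactly."""

    imfs: list  # list of arrays [n_samples]
    residue: np.ndarray
    source_channel: int = 0

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateau midpoints)."""
    d = np.diff(x)
    # collapse flat runs by treating zero slopes as carrying the previous sign
    s = np.sign(d)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    ds = np.diff(s)
    maxima = np.nonzero(ds < 0)[0] + 1
    minima = np.nonzero(ds > 0)[0] + 1
    return maxima, minima


def _mirrored_envelope(idx: np.ndarray, x: np.ndarray, n: int,
                       n_mirror: int = 3) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extending the ends."""
    t = idx.astype(float)
    v = x[idx]
    k = min(n_mirror, idx.size)
    # reflect extrema across the first/last sample
    t_pre = 2 * 0.0 - t[:k][::-1] - 1.0
    v_pre = v[:k][::-1]
    t_post = 2 * (n - 1.0) - t[-k:][::-1] + 1.0
    v_post = v[-k:][::-1]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    tt, uniq = np.unique(tt, return_index=True)
    vv = vv[uniq]
    if tt.size < 2:
        return np.full(n, vv[0] if vv.size else 0.0)
    spline = CubicSpline(tt, vv)
    return spline(np.arange(n))


def emd(signal: np.ndarray, max_imfs: int = 10,
        sd_stop: float = 0.2, max_sift: int = 50,
        source_channel: int = 0) -> IMFDecomposition:
    """Decompose a signal into intrinsic mode functions by sifting.

    Sifting of each mode stops when the Cauchy criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below ``sd_stop`` or the
    candidate runs out of extrema; decomposition stops when the residue has
    fewer than 3 extrema or ``max_imfs`` is reached.  A constant signal
    yields zero IMFs and ``residue == signal``.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 16:
        raise ValueError("signal too short for EMD (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n = x.size
    residue = x.copy()
    imfs: list = []
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residue)
        if maxima.size + minima.size < 3:
            break
        h = residue.copy()
        for _ in range(max_sift):
            hmax, hmin = _local_extrema(h)
            if hmax.size < 2 or hmin.size < 2:
                break
            upper = _mirrored_envelope(hmax, h, n)
            lower = _mirrored_envelope(hmin, h, n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / (denom + 1e-300)
            h = h_new
            if sd < sd_stop:
                break
        imfs.append(h)
        residue = residue - h
    return IMFDecomposition(imfs=imfs, residue=residue,
                            source_channel=source_channel)


def hilbert_instantaneous(imf: np.ndarray, fs: float):
    """Instantaneous amplitude and frequency of one mode.

    Returns ``(amplitude, frequency_hz)``: modulus of the analytic signal and
    the unwrapped-phase derivative over 2*pi, clipped to [0, fs/2].
    """
    x = np.asarray(imf, dtype=float)
    if x.size < 16:
        raise ValueError("imf too short (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("imf contains non-finite values")
    analytic = _hilbert(x)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase) * fs / (2 * np.pi)
    return amplitude, np.clip(freq, 0.0, fs / 2)


# ---------------------------------------------------------------------------
# FastICA
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """FastICA result in the original channel space.

    ``mixing @ sources + mean`` reconstructs the input (up to any rank
    reduction applied during whitening).  ``unmixing_white`` has orthonormal
    rows (unit norm in whitened space).
    """

    unmixing: np.ndarray       # [n_components x n_channels]
    mixing: np.ndarray         # [n_channels x n_components]
    sources: np.ndarray        # [n_components x n_samples]
    mean: np.ndarray           # [n_channels]
    unmixing_white: np.ndarray  # rotation in whitened space
    component_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    def reconstruct(self, zero_flagged: bool = False) -> np.ndarray:
        S = self.sources.copy()
        if zero_flagged and self.component_flags.size:
            S[self.component_flags] = 0.0
        return self.mixing @ S + self.mean[:, None]


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^(-1/2) W
    vals, vecs = np.linalg.eigh(W @ W.T)
    vals = np.clip(vals, 1e-12, None)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T @ W


def fastica(X: np.ndarray, n_components: int | None = None,
            tol: float = 1e-5, max_iter: int = 500,
            seed: int = 0) -> ICADecomposition:
    """Symmetric FastICA with the tanh contrast.

    Centering, eigen-whitening (reducing to the effective rank with a warning
    if the covariance is rank-deficient), then the fixed-point iteration with
    symmetric decorrelation until the rotation update stabilizes below
    ``tol``.  Components are ordered by explained channel-space variance and
    sign-fixed so each column's largest-magnitude mixing weight is positive.
    """
    X = np.asarray(X, dtype=float)
    n_ch, n_samp = X.shape
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed n_channels")
    if n_samp <= 10 * n_ch:
        raise ValueError("need n_samples > 10 * n_channels")

    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    eff_rank = int(np.sum(evals > max(evals.max(), 0) * 1e-10))
    if eff_rank < n_components:
        warnings.warn(
            f"rank-deficient covariance: reducing components "
            f"{n_components} -> {eff_rank}", RuntimeWarning)
        n_components = eff_rank
    evals = evals[:n_components]
    evecs = evecs[:, :n_components]
    K = (evecs / np.sqrt(evals)).T          # [n_comp x n_ch] whitening
    Z = K @ Xc                              # whitened data

    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((n_components, n_components)))
    converged = False
    for _ in range(max_iter):
        WZ = W @ Z
        G = np.tanh(WZ)
        g_prime = 1.0 - G ** 2
        W_new = (G @ Z.T) / n_samp - g_prime.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            break
    if not converged:
        warnings.warn("FastICA did not converge; returning best iterate",
                      RuntimeWarning)

    unmixing = W @ K
    sources = unmixing @ Xc
    mixing = np.linalg.pinv(unmixing)

    # order by explained variance in channel space, fix signs
    var = np.sum(mixing ** 2, axis=0) * sources.var(axis=1)
    order = np.argsort(var)[::-1]
    unmixing, sources = unmixing[order], sources[order]
    mixing, W = mixing[:, order], W[order]
    for i in range(n_components):
        j = np.argmax(np.abs(mixing[:, i]))
        if mixing[j, i] < 0:
            mixing[:, i] *= -1
            unmixing[i] *= -1
            sources[i] *= -1
            W[i] *= -1

    return ICADecomposition(unmixing=unmixing, mixing=mixing, sources=sources,
                            mean=mean, unmixing_white=W,
                            component_flags=np.zeros(n_components, bool),
                            converged=converged)


def flag_artifact_components(ica: ICADecomposition, rec: EEGRecording,
                             kurtosis_z: float = 2.5,
                             line_ratio: float = 0.6,
                             line_freq: float = 50.0) -> ICADecomposition:
    """Flag blink-like and mains-like independent components.

    A component is flagged when (a) its excess kurtosis is an outlier among
    components — robust z-score (median / scaled MAD) above ``kurtosis_z`` —
    or (b) the fraction of its periodogram mass within +/-1 Hz of
    ``line_freq`` exceeds ``line_ratio``.  The robust scale is floored at one
    excess-kurtosis unit so that, with the few components a small montage
    yields, a near-zero MAD cannot inflate the z-score: a blink-like
    component must be materially leptokurtic relative to the others.
    Returns a new decomposition with ``component_flags`` set.
    """
    S = ica.sources
    kurt = _kurtosis(S, axis=1, fisher=True, bias=True)
    med = np.median(kurt)
    mad = np.median(np.abs(kurt - med)) * 1.4826
    z = (kurt - med) / max(mad, 1.0)
    flags = z > kurtosis_z

    freqs = np.fft.rfftfreq(S.shape[1], 1.0 / rec.fs)
    power = np.abs(np.fft.rfft(S, axis=1)) ** 2
    in_band = np.abs(freqs - line_freq) <= 1.0
    total = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, power[:, in_band].sum(axis=1) / total, 0.0)
    flags |= ratio > line_ratio

    out = ICADecomposition(unmixing=ica.unmixing, mixing=ica.mixing,
                           sources=ica.sources, mean=ica.mean,
                           unmixing_white=ica.unmixing_white,
                           component_flags=flags, converged=ica.converged)
    return out


# ---------------------------------------------------------------------------
# Denoising pipeline and epoching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenoiseConfig:
    """Settings for the HHT + FastICA denoising pipeline."""

    freq_low_hz: float = MIN_BAND_EDGE_HZ    # drop IMFs slower than this
    freq_high_hz: float = MAX_BAND_EDGE_HZ   # drop IMFs faster than this
    max_imfs: int = 10
    sd_stop: float = 0.2
    ica_tol: float = 1e-5
    ica_max_iter: int = 500
    kurtosis_z: float = 2.5
    line_ratio: float = 0.6
    line_freq: float = 50.0
    seed: int = 0


def _hht_clean_channel(x: np.ndarray, fs: float, config: DenoiseConfig) -> np.ndarray:
    dec = emd(x, max_imfs=config.max_imfs, sd_stop=config.sd_stop)
    out = np.zeros_like(x)
    for imf in dec.imfs:
        _, freq = hilbert_instantaneous(imf, fs)
        med = float(np.median(freq))
        if config.freq_low_hz <= med <= config.freq_high_hz:
            out += imf
    # the residue is sub-delta drift by construction and is dropped
    return out


def denoise(rec: EEGRecording, config: DenoiseConfig | None = None) -> EEGRecording:
    """FastICA artifact rejection across channels, then HHT per channel.

    The spatially coherent artifacts (blinks, mains) are removed first by
    zeroing flagged independent components, so that their large transients
    and high-frequency lines cannot drag brain rhythms into the discarded
    modes of the subsequent per-channel EMD stage (mode mixing).  The EMD
    stage then drops modes whose median instantaneous frequency falls
    outside the 0.5–45 Hz rhythm range (residual drift and supra-gamma
    content).  Single-channel recordings get the HHT stage only (with a
    warning); the output shape and sampling rate equal the input's.
    """
    if config is None:
        config = DenoiseConfig()
    out = rec.copy()
    if rec.n_channels < 2:
        logger.warning("single-channel recording: skipping the ICA stage")
    else:
        ica = fastica(out.data, tol=config.ica_tol,
                      max_iter=config.ica_max_iter, seed=config.seed)
        ica = flag_artifact_components(ica, out, kurtosis_z=config.kurtosis_z,
                                       line_ratio=config.line_ratio,
                                       line_freq=config.line_freq)
        out.data = ica.reconstruct(zero_flagged=True)
    for ch in range(rec.n_channels):
        out.data[ch] = _hht_clean_channel(out.data[ch], rec.fs, config)
    return out


@dataclass
class EpochSet:
    """Fixed-length labeled epochs cut from one or more recordings."""

    epochs: np.ndarray       # [n_epochs x n_channels x epoch_samples]
    labels: np.ndarray       # condition ids, 0-4
    subject_ids: np.ndarray  # strings
    fs: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def segment_epochs(recs, epoch_s: float = 4.0, overlap: float = 0.0) -> EpochSet:
    """Cut recordings into sliding windows; trailing partial windows dropped."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if isinstance(recs, EEGRecording):
        recs = [recs]
    if not recs:
        raise ValueError("no recordings supplied")
    fs = recs[0].fs
    win = int(round(epoch_s * fs))
    if win < 64:
        raise ValueError("epoch_s * fs must be >= 64 samples")
    stride = int(round(win * (1 - overlap)))
    stride = max(stride, 1)

    epochs, labels, subjects = [], [], []
    for rec in recs:
        if rec.fs != fs:
            raise ValueError("all recordings must share one sampling rate")
        n = rec.n_samples
        if n < win:
            logger.warning("recording %s/%s shorter than one epoch; skipped",
                           rec.subject_id, rec.condition_id)
            continue
        for start in range(0, n - win + 1, stride):
            epochs.append(rec.data[:, start:start + win])
            labels.append(rec.condition_id)
            subjects.append(rec.subject_id)
    if not epochs:
        raise ValueError("no epochs produced (all recordings too short)")
    return EpochSet(epochs=np.stack(epochs), labels=np.asarray(labels, int),
                    subject_ids=np.asarray(subjects, object), fs=fs)
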