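"""Shared oracles and fixtures: independent reference computations used to
check the package's signal-processing operations."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from eegmusic.bands import RHYTHM_BANDS


def periodogram_band_mass(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """FFT periodogram mass in [lo, hi) Hz — independent of the HWPT path."""
    power = np.abs(np.fft.rfft(np.asarray(x, float))) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return float(power[(freqs >= lo) & (freqs < hi)].sum())


def band_fractions(x: np.ndarray, fs: float) -> np.ndarray:
    """Periodogram fractions of the five rhythms over their union."""
    masses = np.array([periodogram_band_mass(x, fs, lo, hi)
                       for lo, hi in RHYTHM_BANDS.values()])
    return masses / masses.sum()


def sampen_bruteforce(x, m: int = 2, r: float = 0.2):
    """O(N^2) double-loop SampEn match counting (A, B) — the reference."""
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()
    nt = n - m  # templates that admit an (m+1)-length extension
    A = B = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= tol:
                B += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    A += 1
    return A, B


def rbm_exact_loglik(rbm, data: np.ndarray) -> float:
    """Exact mean log-likelihood by brute-force enumeration of all visible
    states (the partition function oracle for enumerable RBMs)."""
    def neg_free_energy(v):
        return float(v @ rbm.b_visible
                     + np.sum(np.logaddexp(0.0, rbm.W @ v + rbm.b_hidden)))

    states = [np.array(s, float)
              for s in itertools.product([0, 1], repeat=rbm.n_visible)]
    log_z = np.logaddexp.reduce([neg_free_energy(v) for v in states])
    return float(np.mean([neg_free_energy(v) - log_z for v in data]))


@pytest.fixture(scope="session")
def alpha_profile():
    from eegmusic.synthetic import ConditionProfile

    return ConditionProfile(
        condition_id=0,
        band_power={"delta": 0, "theta": 0, "alpha": 1, "beta": 0, "gamma": 0},
        regularity=1.0)
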