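"""Synthetic multi-channel EEG with class-specific rhythm power and regularity.

The generator emulates a five-condition music-perception experiment: each
condition is described by a :class:`ConditionProfile` giving relative power
per rhythm (delta..gamma) and a *regularity* knob in [0, 1] that mixes
fixed-frequency sinusoids (regular, low sample entropy) with band-limited
noise (irregular, high sample entropy).  Ocular blink transients and mains
interference can be injected on top so the denoising stage has something
real to remove.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``;
identical arguments always produce bit-identical signals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .bands import MAX_BAND_EDGE_HZ, RHYTHM_BANDS, RHYTHM_NAMES, ConfigurationError

#: fixed frontal-weighted blink topography, cycled over channels
BLINK_TOPOGRAPHY = (1.0, 0.8, 0.3, 0.1)

#: overall signal scale in microvolts RMS
SIGNAL_SCALE_UV = 20.0


@dataclass(frozen=True)
class ConditionProfile:
    """Spectral/regularity description of one experimental condition.

    Parameters
    ----------
    condition_id : int
        Class label, 0–4 (0 = no music, 1–4 = music styles).
    band_power : dict
        Relative (dimensionless, >= 0) power weight per rhythm name; must
        cover exactly the five canonical rhythms and not be all zero.
    regularity : float
        In [0, 1]; fraction of each band's power carried by a phase-jittered
        sinusoid rather than band-passed noise.  Higher regularity means a
        more deterministic signal and hence lower sample entropy.
    """

    condition_id: int
    band_power: dict = field(default_factory=dict)
    regularity: float = 0.5

    def __post_init__(self):
        if set(self.band_power) != set(RHYTHM_NAMES):
            raise ConfigurationError(
                f"band_power must cover exactly {RHYTHM_NAMES}, got "
                f"{sorted(self.band_power)}"
            )
        if any(w < 0 for w in self.band_power.values()):
            raise ConfigurationError("band_power weights must be >= 0")
        if not any(w > 0 for w in self.band_power.values()):
            raise ConfigurationError("band_power weights are all zero")
        if not 0.0 <= self.regularity <= 1.0:
            raise ConfigurationError("regularity must lie in [0, 1]")

    def normalized_power(self) -> np.ndarray:
        w = np.array([self.band_power[name] for name in RHYTHM_NAMES], float)
        return w / w.sum()


@dataclass(frozen=True)
class ArtifactSpec:
    """Blink and mains-interference contamination levels."""

    blink_rate: float = 12.0  # events per minute
    blink_amplitude: float = 80.0  # microvolts
    line_freq: float = 50.0  # Hz
    line_amplitude: float = 10.0  # microvolts

    def __post_init__(self):
        if min(self.blink_rate, self.blink_amplitude, self.line_amplitude) < 0:
            raise ConfigurationError("artifact rates/amplitudes must be >= 0")
        if self.line_freq < 0:
            raise ConfigurationError("line_freq must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(blink_rate=0.0, blink_amplitude=0.0, line_amplitude=0.0)


@dataclass
class EEGRecording:
    """A multi-channel EEG recording (microvolts) with its metadata."""

    data: np.ndarray  # [n_channels x n_samples]
    fs: float
    channel_labels: list
    subject_id: str
    condition_id: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return dataclasses.replace(self, data=self.data.copy(),
                                   channel_labels=list(self.channel_labels))


def _seed_int(*keys: int) -> int:
    """Deterministic 31-bit seed derived from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi) Hz via FFT boxcar."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


#: broadband sensor-noise power as a fraction of the brain-signal power;
#: zero by default — contamination is modelled explicitly by ArtifactSpec
SENSOR_NOISE_FRACTION = 0.0


def _latent_source(rng: np.random.Generator, n: int, fs: float,
                   weights: np.ndarray, r: float) -> np.ndarray:
    """One unit-power cortical source with the profile's band fractions.

    Each rhythm contributes ``sqrt(r) * sinusoid + sqrt(1-r) * band noise``
    (independent unit-power parts), scaled by the square root of its
    normalized weight.  The sinusoid sits at the band centre with a slow
    random-walk phase jitter so its line stays well inside the band.
    """
    t = np.arange(n) / fs
    x = np.zeros(n)
    for (name, (lo, hi)), w in zip(RHYTHM_BANDS.items(), weights):
        if w == 0:
            continue
        fc = 0.5 * (lo + hi)
        phi0 = rng.uniform(0, 2 * np.pi)
        jitter = np.cumsum(rng.normal(0.0, 0.02, n))
        sine = np.sqrt(2.0) * np.sin(2 * np.pi * fc * t + phi0 + jitter)
        noise = _band_limited_noise(rng, n, fs, lo, hi)
        x += np.sqrt(w) * (np.sqrt(r) * sine + np.sqrt(1.0 - r) * noise)
    return x


def generate_recording(profile: ConditionProfile, duration_s: float = 60.0,
                       fs: float = 256.0, n_channels: int = 4,
                       seed: int = 0, subject_id: str = "S00",
                       n_sources: int | None = None,
                       sensor_noise: float = SENSOR_NOISE_FRACTION,
                       ) -> EEGRecording:
    """Generate one recording whose band-power fractions follow the profile.

    Channels are volume-conducted mixtures of a small number of latent
    cortical sources (default ``max(1, n_channels - 2)``), each carrying the
    profile's band-power fractions; the mixing rows are unit-norm so every
    channel keeps those fractions exactly.  ``sensor_noise`` optionally adds
    an independent broadband noise floor per channel (as a fraction of the
    signal power; zero by default, since contamination is modelled
    explicitly by :class:`ArtifactSpec`).  The channel scale is ~20 uV RMS.
    """
    if duration_s < 4:
        raise ConfigurationError("duration_s must be >= 4 s")
    if fs < 100 or fs <= 2 * MAX_BAND_EDGE_HZ:
        raise ConfigurationError(
            f"fs={fs} too low: need fs >= 100 and fs > {2 * MAX_BAND_EDGE_HZ}")
    if n_channels < 1:
        raise ConfigurationError("n_channels must be >= 1")

    n = int(round(duration_s * fs))
    weights = profile.normalized_power()
    r = profile.regularity
    if n_sources is None:
        n_sources = max(1, n_channels - 2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sources = np.stack([_latent_source(rng, n, fs, weights, r)
                        for _ in range(n_sources)])
    mixing = rng.uniform(0.2, 1.0, (n_channels, n_sources))
    mixing *= rng.choice([-1.0, 1.0], mixing.shape)
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    data = mixing @ sources
    if sensor_noise > 0:
        noise = rng.standard_normal((n_channels, n))
        noise /= noise.std(axis=1, keepdims=True)
        data += np.sqrt(sensor_noise) * noise
    data *= SIGNAL_SCALE_UV
    labels = [f"CH{c + 1}" for c in range(n_channels)]
    return EEGRecording(data=data, fs=float(fs), channel_labels=labels,
                        subject_id=subject_id, condition_id=profile.condition_id)


def _blink_kernel(fs: float, width_s: float = 0.3) -> np.ndarray:
    """Smooth unipolar bump (Hann window) of ~width_s seconds, unit peak."""
    w = max(int(round(width_s * fs)), 3)
    return np.hanning(w)


def inject_artifacts(rec: EEGRecording, spec: ArtifactSpec,
                     seed: int = 0) -> EEGRecording:
    """Return a new recording = input + blink transients + mains sinusoid.

    The random draws happen in a fixed order (Poisson blink count, blink
    times, line phase) from ``default_rng(seed)``, so the number of injected
    blinks is exactly reproducible from the seed alone.
    """
    if spec.line_freq >= rec.fs / 2:
        raise ConfigurationError(
            f"line_freq {spec.line_freq} must be below Nyquist ({rec.fs / 2})")
    rng = np.random.default_rng(seed)
    out = rec.copy()
    n = rec.n_samples
    duration = rec.duration_s

    n_blinks = int(rng.poisson(spec.blink_rate * duration / 60.0))
    times = np.sort(rng.uniform(0.0, duration, n_blinks))
    kernel = _blink_kernel(rec.fs)
    topo = np.array([BLINK_TOPOGRAPHY[c % len(BLINK_TOPOGRAPHY)]
                     for c in range(rec.n_channels)])
    blink = np.zeros(n)
    for t0 in times:
        start = int(round(t0 * rec.fs))
        stop = min(start + kernel.size, n)
        blink[start:stop] += kernel[: stop - start]
    out.data += spec.blink_amplitude * topo[:, None] * blink[None, :]

    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / rec.fs
    line = spec.line_amplitude * np.sin(2 * np.pi * spec.line_freq * t + phase)
    out.data += line[None, :]
    return out


def blink_count(spec: ArtifactSpec, duration_s: float, seed: int) -> int:
    """The exact blink count :func:`inject_artifacts` will draw for this seed."""
    rng = np.random.default_rng(seed)
    return int(rng.poisson(spec.blink_rate * duration_s / 60.0))


def default_profiles(regularities=(0.2, 0.35, 0.5, 0.65, 0.8),
                     dominance: float = 6.0) -> list:
    """Five well-separated profiles, condition *i* dominated by rhythm *i*.

    Each condition's dominant rhythm carries ``dominance`` times the weight
    of every other rhythm, and regularity is spread over ``regularities`` so
    conditions differ both spectrally and in entropy.
    """
    profiles = []
    for cid, (dom, reg) in enumerate(zip(RHYTHM_NAMES, regularities)):
        bp = {name: (dominance if name == dom else 1.0) for name in RHYTHM_NAMES}
        profiles.append(ConditionProfile(condition_id=cid, band_power=bp,
                                         regularity=reg))
    return profiles


def generate_cohort(n_subjects: int, profiles, duration_s: float = 60.0,
                    fs: float = 256.0, n_channels: int = 4,
                    artifacts: ArtifactSpec | None = None,
                    seed: int = 0) -> list:
    """Generate ``n_subjects x len(profiles)`` recordings.

    Per-subject gain (uniform within +/-20%) and per-recording seeds are
    derived deterministically from the master seed, so two cohorts with the
    same arguments are identical and different master seeds decorrelate
    everything.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if not profiles:
        raise ConfigurationError("profiles must be non-empty")
    cids = [p.condition_id for p in profiles]
    if len(set(cids)) != len(cids):
        raise ConfigurationError("duplicate condition_ids in profiles")

    recordings = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        gain_rng = np.random.default_rng(_seed_int(seed, s, 0xA11))
        gain = gain_rng.uniform(0.8, 1.2)
        for profile in profiles:
            rec_seed = _seed_int(seed, s, profile.condition_id)
            rec = generate_recording(profile, duration_s=duration_s, fs=fs,
                                     n_channels=n_channels, seed=rec_seed,
                                     subject_id=sid)
            rec.data *= gain
            if artifacts is not None:
                rec = inject_artifacts(rec, artifacts,
                                       seed=_seed_int(seed, s,
                                                      profile.condition_id, 0xAF))
            recordings.append(rec)
    return recordings
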