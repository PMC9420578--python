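"""Canonical EEG rhythm bands shared by the generator and the feature extractor.

The five clinical rhythms tile 0.5–45 Hz without overlap.  Everything in the
package that speaks about "bands" resolves them through this single table so
the simulator and the band-energy features can never disagree about edges.
"""

from __future__ import annotations

from collections import OrderedDict

#: rhythm name -> (low_hz, high_hz), ascending, non-overlapping
RHYTHM_BANDS: "OrderedDict[str, tuple[float, float]]" = OrderedDict(
    [
        ("delta", (0.5, 4.0)),
        ("theta", (4.0, 8.0)),
        ("alpha", (8.0, 13.0)),
        ("beta", (13.0, 30.0)),
        ("gamma", (30.0, 45.0)),
    ]
)

RHYTHM_NAMES: tuple[str, ...] = tuple(RHYTHM_BANDS)

#: upper edge of the highest rhythm; signals must be sampled above 2x this
MAX_BAND_EDGE_HZ: float = max(hi for _, hi in RHYTHM_BANDS.values())
MIN_BAND_EDGE_HZ: float = min(lo for lo, _ in RHYTHM_BANDS.values())


class ConfigurationError(ValueError):
    """Raised for invalid simulation / pipeline settings."""


def validate_bands(bands: "OrderedDict[str, tuple[float, float]]") -> None:
    """Check that a band table is ascending and non-overlapping."""
    prev_hi = -1.0
    for name, (lo, hi) in bands.items():
        if not (0 <= lo < hi):
            raise ConfigurationError(f"band {name!r} has invalid edges ({lo}, {hi})")
        if lo < prev_hi:
            raise ConfigurationError(f"band {name!r} overlaps its predecessor")
        prev_hi = hi
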