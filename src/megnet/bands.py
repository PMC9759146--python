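"""Frequency-band definitions for multi-band MEG analysis.

The pipeline decomposes source-level signals into seven canonical bands,
from delta up to the fast-ripple range used in high-frequency-oscillation
work: delta (1-4 Hz), theta (4-8), alpha (8-12), beta (12-30), gamma
(30-80), ripple (80-250) and fast ripple (250-500).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")

    def valid_for(self, fs: float) -> bool:
        """True if the band lies at or below the Nyquist frequency of *fs*."""
        return self.hi <= fs / 2

    @property
    def width(self) -> float:
        return self.hi - self.lo


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
    BandDefinition("ripple", 80.0, 250.0),
    BandDefinition("fast_ripple", 250.0, 500.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}


def get_band(name: str) -> BandDefinition:
    try:
        return BAND_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(BAND_BY_NAME)}") from None
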