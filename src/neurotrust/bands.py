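"""Canonical EEG frequency bands.

Four bands are analysed throughout: theta (4-8 Hz), alpha (8-12 Hz),
beta (12-35 Hz) and gamma (35-60 Hz). Band-limited operations (phase
extraction, band power) take a :class:`BandDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [lo, hi) in Hz with a canonical name."""

    name: str
    symbol: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi, got [{self.lo}, {self.hi}]")
        if self.lo < 0:
            raise ValueError(f"band {self.name}: negative lower edge")

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi


THETA = BandDefinition("theta", "θ", 4.0, 8.0)
ALPHA = BandDefinition("alpha", "α", 8.0, 12.0)
BETA = BandDefinition("beta", "β", 12.0, 35.0)
GAMMA = BandDefinition("gamma", "γ", 35.0, 60.0)

#: The four analysis bands, in canonical order.
BANDS: tuple[BandDefinition, ...] = (THETA, ALPHA, BETA, GAMMA)

BAND_BY_NAME = {b.name: b for b in BANDS}
BAND_BY_SYMBOL = {b.symbol: b for b in BANDS}


def get_band(key: str | BandDefinition) -> BandDefinition:
    """Resolve a band from its name ('theta'), symbol ('θ') or itself."""
    if isinstance(key, BandDefinition):
        return key
    if key in BAND_BY_NAME:
        return BAND_BY_NAME[key]
    if key in BAND_BY_SYMBOL:
        return BAND_BY_SYMBOL[key]
    raise KeyError(f"unknown frequency band {key!r}")
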