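"""Canonical names for the 96-dimensional trust feature space.

Twelve cognitive features (MW, six per-system mental loads, SA, E, BR, AI, CT)
plus 84 functional features: per band (θ, α, β, γ), six within-system strengths
and fifteen between-system communications, named ``"<band>:<system>"`` and
``"<band>:<sysA>-<sysB>"`` with systems in the canonical order F, PF, C, T,
Pa, O. Pair names are order-normalized, so "γ:PF-F" resolves to "γ:F-PF".
"""

from __future__ import annotations

from itertools import combinations

from .bands import BANDS, get_band
from .parcellation import SYSTEMS

#: The 12 cognitive feature names, in canonical order.
COGNITIVE_NAMES: tuple[str, ...] = (
    "MW", "ML_F", "ML_PF", "ML_C", "ML_T", "ML_Pa", "ML_O",
    "SA", "E", "BR", "AI", "CT",
)

#: System pairs in canonical order (15 unordered pairs).
SYSTEM_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(SYSTEMS, 2))


def strength_name(band, system: str) -> str:
    """Canonical name of a within-system strength feature, e.g. 'γ:F'."""
    band = get_band(band)
    if system not in SYSTEMS:
        raise KeyError(f"unknown system {system!r}")
    return f"{band.symbol}:{system}"


def communication_name(band, sys_a: str, sys_b: str) -> str:
    """Canonical name of a between-system communication feature, e.g. 'γ:F-Pa'."""
    band = get_band(band)
    if sys_a == sys_b:
        raise ValueError("communication requires two distinct systems")
    for s in (sys_a, sys_b):
        if s not in SYSTEMS:
            raise KeyError(f"unknown system {s!r}")
    a, b = sorted((sys_a, sys_b), key=SYSTEMS.index)
    return f"{band.symbol}:{a}-{b}"


def _functional_names() -> tuple[str, ...]:
    names: list[str] = []
    for band in BANDS:
        names.extend(strength_name(band, s) for s in SYSTEMS)
        names.extend(communication_name(band, a, b) for a, b in SYSTEM_PAIRS)
    return tuple(names)


#: The 84 functional feature names (21 per band × 4 bands), in canonical order.
FUNCTIONAL_NAMES: tuple[str, ...] = _functional_names()

#: All 96 canonical feature names: 12 cognitive followed by 84 functional.
ALL_FEATURE_NAMES: tuple[str, ...] = COGNITIVE_NAMES + FUNCTIONAL_NAMES

#: Functional features are phase-locking averages, bounded to [0, 1].
UNIT_INTERVAL_FEATURES: frozenset[str] = frozenset(FUNCTIONAL_NAMES) | {"MW", "E", "BR"}


def normalize_feature_name(name: str) -> str:
    """Map a display name onto its canonical form.

    Accepts band symbols or names ('γ:F-Pa', 'gamma:F-Pa') and either pair
    order ('γ:PF-F' → 'γ:F-PF'). Cognitive names pass through unchanged.
    """
    if name in COGNITIVE_NAMES:
        return name
    if ":" in name:
        band_key, rest = name.split(":", 1)
        band = get_band(band_key)
        if "-" in rest:
            a, b = rest.split("-", 1)
            return communication_name(band, a.strip(), b.strip())
        return strength_name(band, rest.strip())
    raise KeyError(f"unrecognized feature name {name!r}")


#: The three key features reported for the simple task (UVA), γ band,
#: in descending selection-rank order.
KEY_FEATURES_UVA: tuple[str, ...] = ("γ:F", "γ:F-Pa", "γ:F-C")

#: The nine key features reported for the complex task (LND), descending rank:
#: seven γ-band functional features, then blink rate and asymmetry index.
KEY_FEATURES_LND: tuple[str, ...] = (
    "γ:F", "γ:F-PF", "γ:PF-Pa", "γ:F-Pa", "γ:T-O", "γ:F-C", "γ:F-O", "BR", "AI",
)
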