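"""Parcellation of the 20-channel scalp montage into six cognitive systems.

The systems group electrodes by cortical function: frontal (F; cognition and
action), prefrontal (PF; cognition), central (C; action), temporal
(T; perception), parietal (Pa; cognition) and occipital (O; perception).
Strength and communication features are aggregates of the pairwise
phase-synchronization matrix over these groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical order of the six cognitive systems.
SYSTEMS: tuple[str, ...] = ("F", "PF", "C", "T", "Pa", "O")

#: The 20 scalp channels handled by the pipeline, in montage order.
CHANNELS_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8",
    "C3", "Cz", "C4", "T3", "T4", "T5", "T6",
    "P3", "Pz", "P4", "POz", "O1", "O2",
)

_DEFAULT_SYSTEMS: dict[str, tuple[str, ...]] = {
    "F": ("F3", "Fz", "F4", "F7", "F8"),
    "PF": ("Fp1", "Fp2"),
    "C": ("C3", "Cz", "C4"),
    "T": ("T3", "T4", "T5", "T6"),
    "Pa": ("P3", "Pz", "P4", "POz"),
    "O": ("O1", "O2"),
}


@dataclass(frozen=True)
class SystemParcellation:
    """Disjoint mapping of channels onto the six cognitive systems.

    Invariants: systems are pairwise disjoint, every mapped channel appears
    exactly once, and each system contains at least two channels.
    """

    systems: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SYSTEMS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, chans in self.systems.items():
            if len(chans) < 2:
                raise ValueError(f"system {name} has fewer than two channels")
            for ch in chans:
                if ch in seen:
                    raise ValueError(f"channel {ch} assigned to more than one system")
                seen.add(ch)

    @property
    def system_names(self) -> tuple[str, ...]:
        return tuple(s for s in SYSTEMS if s in self.systems) + tuple(
            s for s in self.systems if s not in SYSTEMS
        )

    def channels(self, system: str) -> tuple[str, ...]:
        try:
            return self.systems[system]
        except KeyError:
            raise KeyError(f"unknown cognitive system {system!r}") from None

    def system_of(self, channel: str) -> str:
        for name, chans in self.systems.items():
            if channel in chans:
                return name
        raise KeyError(f"channel {channel!r} is not mapped to any system")

    @property
    def all_channels(self) -> tuple[str, ...]:
        out: list[str] = []
        for name in self.system_names:
            out.extend(self.systems[name])
        return tuple(out)


#: Default parcellation of the 20-channel montage.
DEFAULT_PARCELLATION = SystemParcellation()
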