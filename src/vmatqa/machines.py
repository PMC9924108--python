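"""Treatment-machine geometry and delivery limits.

A :class:`MachineModel` carries everything the complexity metrics need to
know about the linac: the MLC leaf-width profile projected to isocenter,
the maximum dose rate and gantry speed used to reconstruct per-segment
delivery dynamics, and the gap below which an opposed leaf pair is treated
as closed.

Two standard Varian 60-pair MLC profiles are built in:

``HD120``
    High-definition MLC: 14 outer pairs of 5 mm, 32 central pairs of
    2.5 mm, 14 outer pairs of 5 mm (220 mm total span).
``Millennium120``
    Standard MLC: 10 outer pairs of 10 mm, 40 central pairs of 5 mm,
    10 outer pairs of 10 mm (400 mm total span).

Maximum dose rate depends on the beam mode; treatment plans do not store
it, so it is configured here.  Defaults follow common TrueBeam/Edge
commissioning values: 600 MU/min for flattened beams, 1400 MU/min for
6 MV FFF, 2400 MU/min for 10 MV FFF; maximum gantry speed 4.8 deg/s.
All values are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MachineModel",
    "MLC_PROFILES",
    "MAX_DOSE_RATE_BY_ENERGY",
    "DEFAULT_MAX_DOSE_RATE",
    "DEFAULT_MAX_GANTRY_SPEED",
    "DEFAULT_MIN_GAP",
]

#: Leaf widths (mm at isocenter) for the built-in 60-pair MLC profiles.
MLC_PROFILES: dict[str, tuple[float, ...]] = {
    "HD120": tuple([5.0] * 14 + [2.5] * 32 + [5.0] * 14),
    "Millennium120": tuple([10.0] * 10 + [5.0] * 40 + [10.0] * 10),
}

#: Maximum dose rate (MU/min) per beam-mode label.
MAX_DOSE_RATE_BY_ENERGY: dict[str, float] = {
    "6X": 600.0,
    "10X": 600.0,
    "15X": 600.0,
    "6FFF": 1400.0,
    "10FFF": 2400.0,
}

DEFAULT_MAX_DOSE_RATE = 600.0  # MU/min, flattened beam
DEFAULT_MAX_GANTRY_SPEED = 4.8  # deg/s
DEFAULT_MIN_GAP = 0.5  # mm; leaf gap at or below this counts as closed


@dataclass(frozen=True)
class MachineModel:
    """MLC geometry and delivery limits of a linac.

    Parameters
    ----------
    name
        Profile name, e.g. ``"HD120"``.
    leaf_widths
        Per-pair leaf widths in mm projected to isocenter, ordered from
        the most negative y (IEC 61217).
    max_dose_rate
        Maximum dose rate in MU/min.
    max_gantry_speed
        Maximum gantry speed in deg/s.
    min_gap
        Leaf gap (mm) at or below which an opposed pair is considered
        closed (dynamic-leaf-gap convention).
    """

    name: str
    leaf_widths: tuple[float, ...]
    max_dose_rate: float = DEFAULT_MAX_DOSE_RATE
    max_gantry_speed: float = DEFAULT_MAX_GANTRY_SPEED
    min_gap: float = DEFAULT_MIN_GAP
    #: n+1 leaf-pair boundary y-coordinates (mm), centered on the midline.
    leaf_boundaries: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        widths = np.asarray(self.leaf_widths, dtype=float)
        if widths.ndim != 1 or widths.size == 0 or np.any(widths <= 0):
            raise ValueError("leaf_widths must be a non-empty 1-D sequence of positive widths")
        if self.max_dose_rate <= 0:
            raise ValueError("max_dose_rate must be > 0")
        if self.max_gantry_speed <= 0:
            raise ValueError("max_gantry_speed must be > 0")
        bounds = np.concatenate([[0.0], np.cumsum(widths)])
        bounds -= bounds[-1] / 2.0
        object.__setattr__(self, "leaf_boundaries", bounds)

    @property
    def n_leaf_pairs(self) -> int:
        return len(self.leaf_widths)

    @property
    def leaf_centers(self) -> np.ndarray:
        """Per-pair center y-coordinates (mm)."""
        b = self.leaf_boundaries
        return 0.5 * (b[:-1] + b[1:])

    @classmethod
    def from_profile(
        cls,
        profile: str,
        energy: str | None = None,
        *,
        max_dose_rate: float | None = None,
        max_gantry_speed: float = DEFAULT_MAX_GANTRY_SPEED,
        min_gap: float = DEFAULT_MIN_GAP,
    ) -> "MachineModel":
        """Build a machine from a built-in MLC profile name.

        ``energy`` (e.g. ``"6FFF"``) selects the default maximum dose
        rate from :data:`MAX_DOSE_RATE_BY_ENERGY`; an explicit
        ``max_dose_rate`` wins over the energy lookup.
        """
        try:
            widths = MLC_PROFILES[profile]
        except KeyError:
            raise ValueError(
                f"unknown MLC profile {profile!r}; known: {sorted(MLC_PROFILES)}"
            ) from None
        if max_dose_rate is None:
            max_dose_rate = MAX_DOSE_RATE_BY_ENERGY.get(energy or "", DEFAULT_MAX_DOSE_RATE)
        return cls(
            name=profile,
            leaf_widths=widths,
            max_dose_rate=max_dose_rate,
            max_gantry_speed=max_gantry_speed,
            min_gap=min_gap,
        )

    def with_overrides(self, **overrides) -> "MachineModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)
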