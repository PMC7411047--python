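"""Stimulus-geometry arithmetic for rotating-sector flash-grab displays.

The flash-grab effect (FGE) is induced by a sectored disk (or wedge) that
rotates back and forth; a bar flashed at the moment of a motion reversal is
perceived displaced or tilted in the post-reversal motion direction.  The
two quantities computed here — Michelson contrast of the sector pattern and
the rotation angle covered between reversals — fully describe the display
geometry the downstream analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StimulusSpec",
    "michelson_contrast",
    "rotation_per_reversal",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry of a rotating-sector inducer display.

    Parameters
    ----------
    rotation_speed : float
        Rotation speed of the sector pattern, degrees of rotation per second.
    reversal_interval_ms : float
        Time between motion-direction reversals, in milliseconds.
    luminance_max, luminance_min : float
        Luminances of the brighter and darker sectors (arbitrary units).
    bar_duration_ms : float
        On-screen duration of the flashed bar, in milliseconds.
    """

    rotation_speed: float
    reversal_interval_ms: float
    luminance_max: float
    luminance_min: float
    bar_duration_ms: float = 33.0

    def __post_init__(self) -> None:
        if self.rotation_speed <= 0:
            raise ValueError("rotation_speed must be positive")
        if self.reversal_interval_ms < 0:
            raise ValueError("reversal_interval_ms must be non-negative")
        if not (self.luminance_max >= self.luminance_min >= 0):
            raise ValueError("require luminance_max >= luminance_min >= 0")
        if self.luminance_max == 0 and self.luminance_min == 0:
            raise ValueError("sector luminances cannot both be zero")

    @property
    def contrast(self) -> float:
        """Michelson contrast of the sector pattern."""
        return michelson_contrast(self.luminance_max, self.luminance_min)

    @property
    def sweep_angle(self) -> float:
        """Degrees of rotation covered between consecutive reversals."""
        return rotation_per_reversal(self.rotation_speed, self.reversal_interval_ms)


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast ``(L_max - L_min) / (L_max + L_min)``.

    Parameters
    ----------
    l_max, l_min : float
        Luminance of the brighter and darker sectors.  ``l_max`` must not be
        smaller than ``l_min`` and both must be non-negative.

    Returns
    -------
    float
        Contrast in ``[0, 1]``.
    """
    if l_min > l_max:
        raise ValueError(
            f"l_max ({l_max}) must be the brighter luminance; got l_min={l_min} > l_max"
        )
    if l_min < 0:
        raise ValueError("luminances must be non-negative")
    total = l_max + l_min
    if total == 0:
        raise ValueError("contrast undefined: both luminances are zero")
    return (l_max - l_min) / total


def rotation_per_reversal(speed: float, interval_ms: float) -> float:
    """Degrees of rotation covered between two motion reversals.

    Parameters
    ----------
    speed : float
        Rotation speed in degrees per second (>= 0).
    interval_ms : float
        Reversal interval in milliseconds (>= 0).
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if interval_ms < 0:
        raise ValueError("interval_ms must be non-negative")
    return speed * interval_ms / 1000.0
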