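"""Viewing geometry: conversions between simulated distance and disparity.

Stimuli are shown on a screen a distance ``S`` in front of the animal.  A
virtual object nearer than the screen is simulated by separating the left-
and right-eye images horizontally on the screen by the *screen parallax*
``P`` (cm).  The angle that ``P`` subtends at the midpoint between the eyes
is the *screen disparity* ``alpha``; the angle the interocular separation
``I`` subtends at the virtual object is the *retinal disparity* ``Delta``.

Sign convention: crossed geometry (object nearer than the screen, lines of
sight intersecting in front of it) has positive ``P`` and ``alpha``;
simulated distances beyond the screen give negative values.  Uncrossed
control stimuli (left/right images swapped) are therefore described by
negating ``P``.  All angles at the interface are in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ViewingGeometry",
    "DisparitySpec",
    "parallax_from_distance",
    "screen_disparity_from_parallax",
    "screen_disparity_from_distance",
    "distance_from_screen_disparity",
    "parallax_from_screen_disparity",
    "retinal_disparity_from_distance",
    "distance_from_retinal_disparity",
    "screen_from_retinal",
]


@dataclass(frozen=True)
class ViewingGeometry:
    """Fixed experimental geometry.

    Parameters
    ----------
    interocular_separation : float
        Distance ``I`` between the eyes, cm.  Default 0.7 cm (7 mm).
    screen_distance : float
        Physical distance ``S`` of the display screen, cm.  Default 10 cm.
    """

    interocular_separation: float = 0.7
    screen_distance: float = 10.0

    def __post_init__(self) -> None:
        if self.interocular_separation <= 0:
            raise ValueError("interocular separation must be positive")
        if self.screen_distance <= 0:
            raise ValueError("screen distance must be positive")


DEFAULT_GEOMETRY = ViewingGeometry()


def parallax_from_distance(distance: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
    """On-screen image separation ``P = I (S - D) / D`` (cm) simulating
    an object at ``distance`` ``D`` (cm).

    Negative for distances beyond the screen (uncrossed geometry).
    """
    if distance <= 0:
        raise ValueError(f"simulated distance must be positive, got {distance}")
    I, S = geom.interocular_separation, geom.screen_distance
    return I * (S - distance) / distance


def screen_disparity_from_parallax(parallax: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
    """Screen disparity ``alpha = 2 arctan(P / 2S)`` in degrees; odd in P."""
    return math.degrees(2.0 * math.atan(0.5 * parallax / geom.screen_distance))


def screen_disparity_from_distance(distance: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
    """Screen disparity (deg) of an object simulated at ``distance`` (cm)."""
    return screen_disparity_from_parallax(parallax_from_distance(distance, geom), geom)


def parallax_from_screen_disparity(alpha: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
    """Inverse of :func:`screen_disparity_from_parallax` (cm)."""
    return 2.0 * geom.screen_distance * math.tan(math.radians(alpha) / 2.0)


def distance_from_screen_disparity(alpha: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
    """Simulated distance ``D = I S / (I + 2 S tan(alpha/2))`` (cm).

    Raises
    ------
    ValueError
        If the denominator is non-positive: strongly uncrossed disparities
        have no finite simulated distance.
    """
    I, S = geom.interocular_separation, geom.screen_distance
    denom = I + 2.0 * S * math.tan(math.radians(alpha) / 2.0)
    if denom <= 0:
        raise ValueError(
            f"screen disparity {alpha} deg does not correspond to a finite simulated distance"
        )
    return I * S / denom


def retinal_disparity_from_distance(distance: float, interocular_separation: float = 0.7) -> float:
    """Retinal disparity ``Delta = 2 arctan(I / 2D)`` (deg) of an object at
    ``distance`` (cm); decreases monotonically to 0 as D grows."""
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    return math.degrees(2.0 * math.atan(0.5 * interocular_separation / distance))


def distance_from_retinal_disparity(delta: float, interocular_separation: float = 0.7) -> float:
    """Inverse of :func:`retinal_disparity_from_distance` (cm)."""
    t = math.tan(math.radians(delta) / 2.0)
    if t <= 0:
        raise ValueError("retinal disparity must be positive for a finite distance")
    return 0.5 * interocular_separation / t


def screen_from_retinal(delta: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
    """Screen disparity (deg) equivalent to retinal disparity ``delta`` (deg).

    Uses ``tan(alpha/2) = ((S - D)/S) tan(Delta/2)`` with the distance
    recovered from ``delta``; the two disparities coincide when the screen
    is at infinity.
    """
    if delta == 0:
        return 0.0
    D = distance_from_retinal_disparity(delta, geom.interocular_separation)
    S = geom.screen_distance
    t = (S - D) / S * math.tan(math.radians(delta) / 2.0)
    return math.degrees(2.0 * math.atan(t))


@dataclass(frozen=True)
class DisparitySpec:
    """All four equivalent descriptions of one stereoscopic configuration.

    ``simulated_distance`` is ``None`` for presentations with no coherent
    single-object interpretation (monocular stimuli, raw uncrossed swaps).
    The numeric fields are mutually consistent for the attached geometry.
    """

    screen_parallax: float
    screen_disparity: float
    retinal_disparity: float | None
    simulated_distance: float | None
    geometry: ViewingGeometry = field(default=DEFAULT_GEOMETRY)

    @classmethod
    def from_distance(cls, distance: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> "DisparitySpec":
        P = parallax_from_distance(distance, geom)
        return cls(
            screen_parallax=P,
            screen_disparity=screen_disparity_from_parallax(P, geom),
            retinal_disparity=retinal_disparity_from_distance(distance, geom.interocular_separation),
            simulated_distance=distance,
            geometry=geom,
        )

    @classmethod
    def from_parallax(cls, parallax: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> "DisparitySpec":
        alpha = screen_disparity_from_parallax(parallax, geom)
        return cls.from_screen_disparity(alpha, geom)

    @classmethod
    def from_screen_disparity(cls, alpha: float, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> "DisparitySpec":
        P = parallax_from_screen_disparity(alpha, geom)
        try:
            D = distance_from_screen_disparity(alpha, geom)
        except ValueError:
            D = None
        delta = (
            retinal_disparity_from_distance(D, geom.interocular_separation)
            if D is not None
            else None
        )
        return cls(
            screen_parallax=P,
            screen_disparity=alpha,
            retinal_disparity=delta,
            simulated_distance=D,
            geometry=geom,
        )

    @classmethod
    def zero(cls, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> "DisparitySpec":
        """Zero disparity: object on the screen plane (D = S)."""
        return cls.from_distance(geom.screen_distance, geom)

    def swapped(self) -> "DisparitySpec":
        """The uncrossed counterpart: left/right images exchanged, i.e. the
        parallax negated.  Simulated distance becomes that of the negated
        disparity (or None when the lines of sight diverge too strongly)."""
        return DisparitySpec.from_parallax(-self.screen_parallax, self.geometry)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check mutual consistency of the stored fields."""
        g = self.geometry
        alpha = screen_disparity_from_parallax(self.screen_parallax, g)
        if not math.isclose(alpha, self.screen_disparity, rel_tol=rtol, abs_tol=rtol):
            raise ValueError("parallax and screen disparity are inconsistent")
        if self.simulated_distance is not None:
            P = parallax_from_distance(self.simulated_distance, g)
            if not math.isclose(P, self.screen_parallax, rel_tol=rtol, abs_tol=rtol):
                raise ValueError("distance and parallax are inconsistent")
            if self.retinal_disparity is not None:
                d = retinal_disparity_from_distance(
                    self.simulated_distance, g.interocular_separation
                )
                if not math.isclose(d, self.retinal_disparity, rel_tol=rtol, abs_tol=rtol):
                    raise ValueError("distance and retinal disparity are inconsistent")
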