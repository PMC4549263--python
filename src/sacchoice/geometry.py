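"""Screen geometry for the saccadic-choice display.

The display is an 800x600 px screen viewed at 50 cm. Two stimulus images
(14x14 deg) are centered 8.6 deg left and right of fixation, so the inner
image borders sit at 8.6 - 7 = 1.6 deg eccentricity. The physical pixel
pitch is a free parameter; ``px_per_deg`` defaults to 25 px/deg, which
places the outer image edge (15.6 deg) just inside the half-screen width.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScreenGeometry:
    """Display layout and angular calibration.

    Parameters
    ----------
    width, height : int
        Screen resolution in pixels.
    px_per_deg : float
        Linear pixel pitch (small-angle approximation).
    eccentricity_deg : float
        Distance of each image center from fixation.
    image_size_deg : float
        Side of the square stimulus image.
    viewing_distance_cm : float
        Eye-to-screen distance (informational; px_per_deg carries the
        calibration).
    """

    width: int = 800
    height: int = 600
    px_per_deg: float = 25.0
    eccentricity_deg: float = 8.6
    image_size_deg: float = 14.0
    viewing_distance_cm: float = 50.0

    @property
    def center(self) -> tuple[float, float]:
        return self.width / 2.0, self.height / 2.0

    def deg_to_px(self, deg: float) -> float:
        return deg * self.px_per_deg

    def px_to_deg(self, px: float) -> float:
        return px / self.px_per_deg

    @property
    def inner_border_deg(self) -> float:
        """Eccentricity of the image edge nearest fixation."""
        return self.eccentricity_deg - self.image_size_deg / 2.0

    @property
    def inner_border_px(self) -> float:
        return self.deg_to_px(self.inner_border_deg)

    @property
    def border_x_left(self) -> float:
        """x-coordinate of the left image's inner border (px)."""
        return self.center[0] - self.inner_border_px

    @property
    def border_x_right(self) -> float:
        return self.center[0] + self.inner_border_px


DEFAULT_GEOMETRY = ScreenGeometry()
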