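"""Straight-line representation shared by the fitting and evaluation stages.

Image coordinates: origin at the top-left corner, x rightward, y downward.
Crop rows are near-vertical, so lines are parameterized axis-swapped as
``x = a*y + b``: the slope never blows up for the lines this package fits,
and conversion to endpoint / angle form is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateError


@dataclass(frozen=True)
class Line:
    """A straight, non-horizontal line in image pixel coordinates.

    Parameters
    ----------
    a, b :
        Coefficients of ``x = a*y + b``.
    height :
        Image height in pixels; fixes the endpoint representation
        ``(x_top, 0) -- (x_bot, height-1)``.
    """

    a: float
    b: float
    height: int

    @classmethod
    def from_endpoints(cls, p1: tuple[float, float], p2: tuple[float, float],
                       height: int | None = None) -> "Line":
        (x1, y1), (x2, y2) = p1, p2
        if y1 == y2:
            if x1 == x2:
                raise DegenerateError("coincident endpoints define no line")
            raise DegenerateError("horizontal line has no x = a*y + b form")
        a = (x2 - x1) / (y2 - y1)
        b = x1 - a * y1
        if height is None:
            height = int(round(max(y1, y2))) + 1
        return cls(a=a, b=b, height=height)

    @property
    def x_top(self) -> float:
        return self.b

    @property
    def x_bot(self) -> float:
        return self.a * (self.height - 1) + self.b

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.x_top, 0.0), (self.x_bot, float(self.height - 1))

    @property
    def direction(self) -> tuple[float, float]:
        """Unit direction vector (dx, dy) in image coordinates."""
        n = math.hypot(self.a, 1.0)
        return (self.a / n, 1.0 / n)

    @property
    def angle_deg(self) -> float:
        """Angle vs. the image-bottom horizontal, in (0, 180) degrees.

        Computed in conventional (y-up) orientation so a vertical row reads
        90 deg regardless of the image-coordinate flip.
        """
        return math.degrees(math.atan2(1.0, -self.a))

    def x_at(self, y: float) -> float:
        return self.a * y + self.b

    def to_dict(self) -> dict:
        (xt, yt), (xb, yb) = self.endpoints
        return {
            "x_top": xt, "y_top": yt, "x_bot": xb, "y_bot": yb,
            "a": self.a, "b": self.b, "angle_deg": self.angle_deg,
        }
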