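"""Core spatial containers: observation windows, point patterns, samples.

All coordinates are held internally in millimetres so that the scaling
statistic ``beta_hat = L / sqrt(N * A)`` is computed with the observation
area ``A`` in mm^2, the unit in which stomatal densities are conventionally
reported (stomata per mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: absolute tolerance (mm) for the point-in-window containment check;
#: 1e-9 mm is far below micrograph digitisation precision.
CONTAINMENT_ATOL = 1e-9


class DuplicatePointError(ValueError):
    """Two centroids coincide exactly (zero-length MST edge)."""


@dataclass(frozen=True)
class ObservationWindow:
    """Axis-aligned rectangular observation window, bounds in mm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def area(self) -> float:
        """Window area in mm^2."""
        return self.width * self.height

    def contains(self, points: np.ndarray, atol: float = CONTAINMENT_ATOL) -> np.ndarray:
        """Boolean mask of points inside or on the boundary (tolerance atol)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= self.x_min - atol)
            & (pts[:, 0] <= self.x_max + atol)
            & (pts[:, 1] >= self.y_min - atol)
            & (pts[:, 1] <= self.y_max + atol)
        )

    def scaled(self, s: float) -> "ObservationWindow":
        return ObservationWindow(self.x_min * s, self.y_min * s, self.x_max * s, self.y_max * s)

    def translated(self, dx: float, dy: float) -> "ObservationWindow":
        return ObservationWindow(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    @staticmethod
    def square(area_mm2: float, x_min: float = 0.0, y_min: float = 0.0) -> "ObservationWindow":
        """Square window of the given area with its lower-left corner at (x_min, y_min)."""
        if area_mm2 <= 0:
            raise ValueError(f"area must be positive, got {area_mm2}")
        side = float(np.sqrt(area_mm2))
        return ObservationWindow(x_min, y_min, x_min + side, y_min + side)


UNIT_WINDOW = ObservationWindow(0.0, 0.0, 1.0, 1.0)


@dataclass(frozen=True)
class PointPattern:
    """A set of 2-D centroid coordinates (mm) inside an observation window.

    Invariants enforced at construction: every point lies in the window
    (within :data:`CONTAINMENT_ATOL`) and no two points coincide exactly
    unless ``allow_duplicates`` is set (jitter mode in the readers resolves
    duplicates before construction).
    """

    points: np.ndarray
    window: ObservationWindow
    allow_duplicates: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        object.__setattr__(self, "points", pts)
        inside = self.window.contains(pts)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise ValueError(
                f"{bad.size} point(s) outside window, first offender index {bad[0]}: "
                f"{pts[bad[0]].tolist()}"
            )
        if not self.allow_duplicates and len(pts) > 1:
            uniq = np.unique(pts, axis=0)
            if len(uniq) < len(pts):
                raise DuplicatePointError(
                    f"{len(pts) - len(uniq)} coincident point(s) in pattern"
                )

    @property
    def n(self) -> int:
        return len(self.points)

    def density(self) -> float:
        """Point intensity in points per mm^2."""
        return self.n / self.window.area()

    def scaled(self, s: float) -> "PointPattern":
        """Pattern with all coordinates (and the window) scaled by s > 0."""
        if s <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, points=self.points * s, window=self.window.scaled(s))

    def translated(self, dx: float, dy: float) -> "PointPattern":
        return replace(
            self,
            points=self.points + np.array([dx, dy]),
            window=self.window.translated(dx, dy),
        )

    def rotated(self, theta: float) -> "PointPattern":
        """Rigid rotation by theta radians about the window centre.

        The rectangular window does not rotate; the rotated points are
        re-wrapped in their tight bounding box (plus a hair of padding for
        points on the hull) so the containment invariant holds. Window area
        changes, so this helper is for rigid-motion invariance checks of
        MST length, not for density-based statistics.
        """
        c = np.array(
            [(self.window.x_min + self.window.x_max) / 2, (self.window.y_min + self.window.y_max) / 2]
        )
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts = (self.points - c) @ rot.T + c
        pad = 10 * CONTAINMENT_ATOL
        if len(pts) == 0:
            return replace(self, points=pts)
        win = ObservationWindow(
            pts[:, 0].min() - pad, pts[:, 1].min() - pad, pts[:, 0].max() + pad, pts[:, 1].max() + pad
        )
        return replace(self, points=pts, window=win)


@dataclass(frozen=True)
class StomatalSample:
    """A point pattern plus the biological metadata the analysis needs.

    ``stomatal_diameter_um`` is the per-sample mean of stomatal length and
    width in micrometres; it sets the hard-core inhibition distance of the
    over-dispersed benchmark simulation.
    """

    sample_id: str
    species: str
    site: str
    pattern: PointPattern
    stomatal_diameter_um: float

    def __post_init__(self) -> None:
        if self.stomatal_diameter_um <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: stomatal diameter must be positive, "
                f"got {self.stomatal_diameter_um}"
            )

    @property
    def diameter_mm(self) -> float:
        return self.stomatal_diameter_um / 1000.0

    @property
    def area_mm2(self) -> float:
        return self.pattern.window.area()
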