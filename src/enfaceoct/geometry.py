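"""Tilted six-sector peripapillary grid and circle sampling.

Angle convention
----------------
Grid angles are measured from the fovea-disc axis (0° points from the ONH
center toward the fovea) and increase clockwise for right eyes (OD) and
anticlockwise for left eyes (OS), so that for either eye the sector order
around the circle is temporal → superior → nasal → inferior. The six sectors
tile the circle with half-open intervals (widths 90/40/40/110/40/40°):

====  =================  ==============
name  meaning            grid interval
====  =================  ==============
TMP   temporal           [-45°, 45°)
TS    temporal superior  [45°, 85°)
NS    nasal superior     [85°, 125°)
NAS   nasal              [125°, 235°)
NI    nasal inferior     [235°, 275°)
TI    temporal inferior  [275°, 315°)
====  =================  ==============

In image (pixel) space, angles of a point relative to the ONH center are
computed with ``atan2(d_row, d_col)``, which increases clockwise on screen
because row indices grow downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import CIRCLE_RADIUS_UM

SECTOR_NAMES: tuple[str, ...] = ("TMP", "TS", "NS", "NAS", "NI", "TI")
SECTOR_WIDTHS_DEG: tuple[float, ...] = (90.0, 40.0, 40.0, 110.0, 40.0, 40.0)

#: Sector start angles (deg, grid convention); sector s spans
#: [start, start + width) with wrap at 360.
SECTOR_STARTS_DEG: tuple[float, ...] = (315.0, 45.0, 85.0, 125.0, 235.0, 275.0)


class GeometryError(ValueError):
    """Raised when requested geometry does not fit the image."""


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to [0, 360)."""
    return np.mod(angle, 360.0)


@dataclass(frozen=True)
class SectorGrid:
    """Peripapillary measurement geometry for one eye.

    Parameters
    ----------
    center_px : (row, col) of the ONH center in pixels.
    fovea_disc_angle_deg : screen angle (atan2(d_row, d_col), degrees) of the
        fovea as seen from the ONH center; defines the grid's 0° axis.
    laterality : "OD" (right) or "OS" (left); sets the direction in which
        grid angles increase on screen.
    radius_um : measurement-circle radius (default 1750 µm = 3.5 mm circle).
    """

    center_px: tuple[float, float]
    fovea_disc_angle_deg: float
    laterality: str
    radius_um: float = CIRCLE_RADIUS_UM
    sectors: tuple[tuple[str, float, float], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        object.__setattr__(
            self,
            "sectors",
            tuple(
                (name, start, wrap_deg(start + width))
                for name, start, width in zip(
                    SECTOR_NAMES, SECTOR_STARTS_DEG, SECTOR_WIDTHS_DEG
                )
            ),
        )

    @property
    def _spin(self) -> float:
        """+1 if grid angles increase clockwise on screen (OD), else -1."""
        return 1.0 if self.laterality == "OD" else -1.0

    def grid_angle_of_pixel(self, row, col):
        """Grid angle(s) in [0, 360) of pixel position(s) relative to center."""
        screen = np.degrees(
            np.arctan2(np.asarray(row) - self.center_px[0], np.asarray(col) - self.center_px[1])
        )
        return wrap_deg(self._spin * (screen - self.fovea_disc_angle_deg))

    def pixel_of_grid_angle(self, angle_deg, radius_px):
        """(row, col) of the point at grid angle(s) and radius (pixels)."""
        screen = np.radians(self._spin * np.asarray(angle_deg) + self.fovea_disc_angle_deg)
        return (
            self.center_px[0] + radius_px * np.sin(screen),
            self.center_px[1] + radius_px * np.cos(screen),
        )

    def to_dict(self) -> dict:
        return {
            "center_px": list(self.center_px),
            "fovea_disc_angle_deg": self.fovea_disc_angle_deg,
            "laterality": self.laterality,
            "radius_um": self.radius_um,
            "sectors": [list(s) for s in self.sectors],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectorGrid":
        return cls(
            center_px=tuple(d["center_px"]),
            fovea_disc_angle_deg=d["fovea_disc_angle_deg"],
            laterality=d["laterality"],
            radius_um=d.get("radius_um", CIRCLE_RADIUS_UM),
        )


@dataclass
class CircleProfile:
    """Reflectance sampled on the measurement circle, one row per slab.

    ``values[k, j]`` is the bilinear sample of slab ``k`` at grid angle
    ``angles_deg[j]``; angles are uniform on [0, 360).
    """

    angles_deg: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.angles_deg.size:
            raise ValueError("values must be (n_slabs, n_angles)")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def step_deg(self) -> float:
        return 360.0 / self.angles_deg.size


def build_sector_grid(
    center_px: tuple[float, float],
    fovea_px: tuple[float, float],
    laterality: str,
    radius_um: float = CIRCLE_RADIUS_UM,
) -> SectorGrid:
    """Construct the tilted sector grid from ONH center and fovea position.

    The grid is tilted so the temporal sector is centered on the individual
    fovea-disc axis; ``laterality`` selects the direction of increasing
    angles (clockwise on screen for OD, anticlockwise for OS).
    """
    d_row = fovea_px[0] - center_px[0]
    d_col = fovea_px[1] - center_px[1]
    if d_row == 0 and d_col == 0:
        raise GeometryError("fovea and ONH center coincide; fovea-disc axis undefined")
    fovea_angle = float(np.degrees(np.arctan2(d_row, d_col)))
    return SectorGrid(
        center_px=tuple(float(c) for c in center_px),
        fovea_disc_angle_deg=fovea_angle,
        laterality=laterality,
        radius_um=radius_um,
    )


def sector_of(angle_deg, grid: SectorGrid | None = None):
    """Name(s) of the sector owning grid angle(s); intervals half-open.

    The partition does not depend on the grid instance (angles are already in
    grid convention); the argument is accepted for interface symmetry.
    """
    # Shift so TMP starts at 0: bins at 0/90/130/170/280/320.
    shifted = wrap_deg(np.asarray(angle_deg, dtype=float) + 45.0)
    edges = np.array([90.0, 130.0, 170.0, 280.0, 320.0, 360.0])
    idx = np.searchsorted(edges, shifted, side="right")
    if np.ndim(angle_deg) == 0:
        return SECTOR_NAMES[int(idx)]
    return np.asarray(SECTOR_NAMES)[idx]


def sample_circle(stack, grid: SectorGrid, n_angles: int = 720) -> CircleProfile:
    """Sample every slab on the measurement circle by bilinear interpolation.

    Returns a :class:`CircleProfile` with ``n_angles`` uniform grid angles.
    Raises :class:`GeometryError` if the circle leaves the image bounds.
    """
    radius_px = grid.radius_um / stack.transverse_scale_um_per_px
    n_rows, n_cols = stack.slabs.shape[1:]
    if (
        grid.center_px[0] - radius_px < 0
        or grid.center_px[1] - radius_px < 0
        or grid.center_px[0] + radius_px > n_rows - 1
        or grid.center_px[1] + radius_px > n_cols - 1
    ):
        raise GeometryError(
            f"3.5 mm circle (radius {radius_px:.1f} px) exceeds image bounds "
            f"{n_rows}x{n_cols} around center {grid.center_px}"
        )
    angles = np.arange(n_angles) * (360.0 / n_angles)
    rows, cols = grid.pixel_of_grid_angle(angles, radius_px)
    coords = np.vstack([rows, cols])
    values = np.empty((stack.slabs.shape[0], n_angles), dtype=float)
    for k in range(stack.slabs.shape[0]):
        values[k] = ndimage.map_coordinates(stack.slabs[k], coords, order=1, mode="nearest")
    return CircleProfile(angles_deg=angles, values=values)
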