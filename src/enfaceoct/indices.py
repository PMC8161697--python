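"""Objective extraction of the two peripapillary reflectance indices.

Given a circle profile (reflectance per slab per angle), this module
thresholds bundle presence, masks blood vessels, and per sector reports:

* **first gap** — the shallowest slab whose anterior-edge depth shows a
  bundle-free angular run of at least ``gap_min_deg`` crossing the circle in
  the sector (total absence of bundles counts as a gap, so a sector with no
  bundles at the first slab reports 0 µm);
* **last visible bundle** — the deepest slab with a contiguous bundle run of
  at least ``bundle_min_deg`` in the sector.

Depths are anterior-edge slab depths k·3.87 µm; the reported angle is the
qualifying run's midpoint. Vessel angles carry no bundle evidence: they are
removed before run analysis and run lengths are measured as remaining-sample
count × angular step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MAX_DEPTH_UM, SLAB_UM
from .geometry import (
    SECTOR_NAMES,
    SECTOR_STARTS_DEG,
    SECTOR_WIDTHS_DEG,
    CircleProfile,
    SectorGrid,
    wrap_deg,
)

#: Number of deepest slabs pooled as the bundle-free reference for the
#: reflectance threshold.
REFERENCE_SLABS: int = 5

#: Fraction of slabs in which an angle must be bright to be called a vessel.
VESSEL_PERSISTENCE: float = 0.90


@dataclass
class VisibilityMap:
    """Boolean bundle presence per (slab, angle) with the vessel mask.

    ``bundle[k, j]`` is True where slab ``k`` shows a bundle at angle
    ``angles_deg[j]`` after thresholding and angular opening; vessel angles
    are already False in ``bundle`` and True in ``vessel``.
    """

    angles_deg: np.ndarray
    bundle: np.ndarray
    vessel: np.ndarray
    threshold: float
    params: dict = field(default_factory=dict)

    @property
    def step_deg(self) -> float:
        return 360.0 / self.angles_deg.size


@dataclass
class SectorIndex:
    """One index in one sector: depth, angle, and validity flags."""

    depth_um: float
    angle_deg: float
    censored: bool = False  # no qualifying gap down to 193.5 µm
    no_bundle: bool = False  # no bundle at any depth

    @property
    def valid(self) -> bool:
        return not self.censored


@dataclass
class EnfaceIndexSet:
    """Per-sector first gap / last visible bundle plus weighted averages."""

    first_gap: dict[str, SectorIndex]
    last_visible: dict[str, SectorIndex]
    weighted_first_gap_um: float | None
    weighted_last_visible_um: float | None

    def to_frame(self, eye_id: str = "") -> pd.DataFrame:
        rows = []
        for index_name, per_sector in (
            ("first_gap", self.first_gap),
            ("last_visible", self.last_visible),
        ):
            for sector, r in per_sector.items():
                rows.append(
                    {
                        "eye_id": eye_id,
                        "sector": sector,
                        "index": index_name,
                        "depth_um": r.depth_um,
                        "angle_deg": r.angle_deg,
                        "censored": r.censored,
                        "no_bundle": r.no_bundle,
                    }
                )
        return pd.DataFrame(rows)


class ThicknessProfile:
    """Circumpapillary RNFL thickness vs grid angle on the 3.5 mm circle.

    Angles need not be uniform but must be unique in [0, 360); queries
    interpolate linearly with angular wrap-around.
    """

    def __init__(self, angles_deg, thickness_um):
        angles = wrap_deg(np.asarray(angles_deg, dtype=float))
        thickness = np.asarray(thickness_um, dtype=float)
        if angles.size == 0:
            raise ValueError("empty thickness profile")
        if angles.size != thickness.size:
            raise ValueError("angles and thickness must have equal length")
        if np.any(thickness < 0):
            raise ValueError("thickness must be >= 0")
        order = np.argsort(angles)
        self.angles_deg = angles[order]
        self.thickness_um = thickness[order]
        if np.any(np.diff(self.angles_deg) == 0):
            raise ValueError("duplicate angles in thickness profile")

    @classmethod
    def from_csv(cls, path) -> "ThicknessProfile":
        df = pd.read_csv(path)
        return cls(df["angle_deg"].to_numpy(), df["thickness_um"].to_numpy())

    def at(self, angle_deg: float) -> float:
        return thickness_at_angle(self, angle_deg)

    def sector_means(self) -> dict[str, float]:
        from .geometry import sector_of

        names = sector_of(self.angles_deg)
        return {
            s: float(np.mean(self.thickness_um[names == s])) for s in SECTOR_NAMES
        }

    def global_mean(self) -> float:
        return float(np.mean(self.thickness_um))


def thickness_at_angle(profile: ThicknessProfile, angle_deg: float) -> float:
    """Linear, wrap-aware interpolation of the thickness profile."""
    a = float(wrap_deg(angle_deg))
    angles = profile.angles_deg
    values = profile.thickness_um
    if angles.size == 1:
        return float(values[0])
    # pad with the wrapped neighbours so queries outside [first, last] work
    padded_angles = np.concatenate([[angles[-1] - 360.0], angles, [angles[0] + 360.0]])
    padded_values = np.concatenate([[values[-1]], values, [values[0]]])
    return float(np.interp(a, padded_angles, padded_values))


def detect_visibility(
    profile: CircleProfile,
    threshold_k: float = 4.0,
    min_run_deg: float = 1.0,
    vessel_mask: np.ndarray | None = None,
) -> VisibilityMap:
    """Threshold bundle presence on the circle and mask vessels.

    The threshold is ``median + threshold_k · MAD`` of the pooled deepest
    five slabs of the profile — at 174–193.5 µm below the ILM the slab lies
    beyond the nerve fiber layer everywhere, so that pool is a bundle-free
    reference (vessels, the only bright elements there, occupy a small
    angular fraction and barely move the median). Runs shorter than
    ``min_run_deg`` are erased (angular opening, wrap-aware). Unless supplied,
    the vessel mask flags angles bright in ≥90% of slabs: only vessels stay
    hyperreflective at every depth.
    """
    step = profile.step_deg
    min_samples = max(1, int(np.ceil(min_run_deg / step)))
    if min_samples > profile.angles_deg.size:
        raise ValueError("min_run_deg exceeds the sampled circle")
    pool = profile.values[-REFERENCE_SLABS:].ravel()
    med = float(np.median(pool))
    mad = float(np.median(np.abs(pool - med)))
    # floor the MAD so a noiseless profile does not put the threshold exactly
    # at the background level, where interpolation round-off would flip bits
    threshold = med + threshold_k * max(mad, 1e-6)
    bright = profile.values > threshold
    if vessel_mask is None:
        vessel = bright.mean(axis=0) >= VESSEL_PERSISTENCE
    else:
        vessel = np.asarray(vessel_mask, dtype=bool)
        if vessel.shape != profile.angles_deg.shape:
            raise ValueError("vessel_mask length must match n_angles")
    bundle = bright & ~vessel[None, :]
    bundle = _open_runs_wrapped(bundle, min_samples)
    return VisibilityMap(
        angles_deg=profile.angles_deg.copy(),
        bundle=bundle,
        vessel=vessel,
        threshold=threshold,
        params={"threshold_k": threshold_k, "min_run_deg": min_run_deg,
                "median": med, "mad": mad},
    )


def _open_runs_wrapped(bundle: np.ndarray, min_samples: int) -> np.ndarray:
    """Erase circular runs of True shorter than ``min_samples`` per slab."""
    if min_samples <= 1:
        return bundle
    n = bundle.shape[1]
    out = bundle.copy()
    for k in range(bundle.shape[0]):
        row = bundle[k]
        if row.all() or not row.any():
            continue
        # rotate so the row starts on a False sample, making runs non-wrapping
        start = int(np.argmin(row))
        rolled = np.roll(row, -start)
        padded = np.concatenate([[False], rolled, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        for a, b in zip(starts, stops):
            if b - a < min_samples:
                rolled[a:b] = False
        out[k] = np.roll(rolled, start)
    return out


def _sector_samples(vis: VisibilityMap, sector: str) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ordered along the sector) and angles of non-vessel samples."""
    i = SECTOR_NAMES.index(sector)
    start, width = SECTOR_STARTS_DEG[i], SECTOR_WIDTHS_DEG[i]
    rel = wrap_deg(vis.angles_deg - start)
    in_sector = rel < width
    order = np.argsort(rel[in_sector], kind="stable")
    idx = np.flatnonzero(in_sector)[order]
    idx = idx[~vis.vessel[idx]]
    return idx, vis.angles_deg[idx]


def first_gap(
    vis: VisibilityMap,
    grid: SectorGrid,
    sector: str,
    gap_min_deg: float = 3.0,
) -> SectorIndex:
    """Shallowest anterior-edge depth with a qualifying bundle-free run.

    Scans slabs from the ILM downward; a qualifying gap is a contiguous
    non-bundle run of at least ``gap_min_deg`` among the sector's non-vessel
    angles (absence of all bundles qualifies). If no slab down to 193.5 µm
    qualifies the result is censored at 193.5 µm (flagged, never silent).
    """
    idx, angles = _sector_samples(vis, sector)
    if idx.size == 0:
        raise ValueError(f"sector {sector} has no non-vessel angles")
    step = vis.step_deg
    min_samples = max(1, int(np.ceil(gap_min_deg / step)))
    for k in range(vis.bundle.shape[0]):
        gap = ~vis.bundle[k, idx]
        runs = _runs(gap, min_samples)
        if runs:
            a, b = runs[0]
            return SectorIndex(
                depth_um=k * SLAB_UM,
                angle_deg=float(angles[(a + b - 1) // 2]),
                censored=False,
            )
    return SectorIndex(depth_um=MAX_DEPTH_UM, angle_deg=float("nan"), censored=True)


def last_visible(
    vis: VisibilityMap,
    grid: SectorGrid,
    sector: str,
    bundle_min_deg: float = 1.0,
) -> SectorIndex:
    """Deepest anterior-edge depth with a qualifying bundle run.

    Scans slabs from 193.5 µm upward; a qualifying bundle is a contiguous
    run of at least ``bundle_min_deg`` among the sector's non-vessel angles.
    A sector with no bundle at any depth reports 0 µm with the ``no_bundle``
    flag set.
    """
    idx, angles = _sector_samples(vis, sector)
    if idx.size == 0:
        raise ValueError(f"sector {sector} has no non-vessel angles")
    step = vis.step_deg
    min_samples = max(1, int(np.ceil(bundle_min_deg / step)))
    for k in range(vis.bundle.shape[0] - 1, -1, -1):
        runs = _runs(vis.bundle[k, idx], min_samples)
        if runs:
            a, b = runs[0]
            return SectorIndex(
                depth_um=k * SLAB_UM,
                angle_deg=float(angles[(a + b - 1) // 2]),
            )
    return SectorIndex(depth_um=0.0, angle_deg=float("nan"), no_bundle=True)


def _runs(mask: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    """(start, stop) pairs of True runs of length >= min_samples."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_samples]


def weighted_average(per_sector: dict[str, float], grid: SectorGrid) -> float:
    """Sector-width-weighted mean: Σ value·width / 360.

    Raises ``ValueError`` if any sector is missing or non-finite, so a
    censored sector propagates as an invalid average rather than a number.
    """
    total = 0.0
    for name, width in zip(SECTOR_NAMES, SECTOR_WIDTHS_DEG):
        if name not in per_sector:
            raise ValueError(f"weighted average needs all six sectors; missing {name}")
        v = per_sector[name]
        if v is None or not np.isfinite(v):
            raise ValueError(f"sector {name} is invalid ({v!r}); cannot average")
        total += v * width
    return total / 360.0


def extract_indices(
    profile: CircleProfile,
    grid: SectorGrid,
    threshold_k: float = 4.0,
    min_run_deg: float = 1.0,
    gap_min_deg: float = 3.0,
    bundle_min_deg: float = 1.0,
    vessel_mask: np.ndarray | None = None,
) -> EnfaceIndexSet:
    """Full per-eye extraction: visibility → both indices → weighted averages.

    Weighted averages are None when any sector is censored (first gap) —
    the invalidity is carried by the per-sector flags.
    """
    vis = detect_visibility(
        profile, threshold_k=threshold_k, min_run_deg=min_run_deg, vessel_mask=vessel_mask
    )
    fg = {s: first_gap(vis, grid, s, gap_min_deg) for s in SECTOR_NAMES}
    lv = {s: last_visible(vis, grid, s, bundle_min_deg) for s in SECTOR_NAMES}
    try:
        w_fg = weighted_average(
            {s: (r.depth_um if not r.censored else float("nan")) for s, r in fg.items()},
            grid,
        )
    except ValueError:
        w_fg = None
    w_lv = weighted_average({s: r.depth_um for s, r in lv.items()}, grid)
    return EnfaceIndexSet(
        first_gap=fg,
        last_visible=lv,
        weighted_first_gap_um=w_fg,
        weighted_last_visible_um=w_lv,
    )
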