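"""Synthetic eyes and cohorts with known ground truth.

Two levels of simulation:

* :func:`generate_eye` — image-level. Renders a normalized enface depth
  stack in which hyperreflective nerve-fiber bundles radiate from the ONH as
  angular striations whose depth extent follows a smooth ISNT-like profile
  ``T(θ)``, optionally carved by glaucomatous wedge defects; blood vessels
  stay hyperreflective at every depth; speckle-like Gaussian noise on top.
  The returned :class:`EyeTruth` carries the analytically derived per-sector
  *first gap* and *last visible bundle* so the image pipeline can be checked
  against ground truth.

* :func:`generate_cohort` — index-level. Draws long-format eye × sector
  tables of the two depth indices under a variance-components model (eye and
  sector random intercepts + residual, glaucoma fixed offsets) with paired
  RNFL thickness linearly related to depth at configurable correlation.

The generator emulates the qualitative phenomenology of peripapillary
enface OCT, not OCT physics: no speckle statistics, no beam-incidence
effects, no pathology beyond wedge/diffuse bundle loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .constants import MAX_DEPTH_UM, N_SLABS, SLAB_UM
from .enface import EnfaceStack
from .geometry import (
    SECTOR_NAMES,
    SectorGrid,
    wrap_deg,
)

#: Grid angles (deg) of the sector centers used to anchor the extent profile.
SECTOR_CENTER_DEG: dict[str, float] = {
    "TMP": 0.0, "TS": 65.0, "NS": 105.0, "NAS": 180.0, "NI": 255.0, "TI": 295.0,
}

#: Illustrative healthy bundle depth extents (µm) at the sector centers.
#: There are no published per-sector norms; these are loosely calibrated to
#: a worked healthy temporal sector (first gap 58 µm, last visible 108 µm)
#: with an ISNT-like superior/inferior dominance.
DEFAULT_EXTENT_ANCHORS_UM: dict[str, float] = {
    "TMP": 110.0, "TS": 145.0, "NS": 125.0, "NAS": 100.0, "NI": 135.0, "TI": 150.0,
}

DEFAULT_VESSEL_ANGLES: tuple[tuple[float, float], ...] = (
    (62.0, 1.5), (74.0, 1.5), (248.0, 1.5), (262.0, 1.5),
)

BUNDLE_LEVEL: float = 0.85
BACKGROUND_LEVEL: float = 0.10


@dataclass
class EyeTruth:
    """Ground truth for one synthetic eye.

    ``extent_anchors_um`` anchor the smooth periodic extent profile T(θ)
    (depth, µm, to which bundles remain visible at grid angle θ on the
    3.5 mm circle); ``wedge_defects`` are (center°, full width°, reduction µm)
    raised-cosine notches; ``vessel_angles`` are (center°, half-width°).
    ``true_first_gap_um`` / ``true_last_visible_um`` are derived analytically
    per sector on the slab grid (anterior-edge convention); the matching
    ``*_angle_deg`` dicts hold the qualifying-run midpoints (NaN where a
    sector has no qualifying run below 193.5 µm or no bundle at all).
    """

    extent_anchors_um: dict[str, float]
    bundle_period_deg: float
    bundle_duty: float
    vessel_angles: tuple[tuple[float, float], ...]
    wedge_defects: tuple[tuple[float, float, float], ...]
    laterality: str
    fovea_disc_angle_deg: float
    md_db: float
    true_first_gap_um: dict[str, float] = field(default_factory=dict)
    true_first_gap_angle_deg: dict[str, float] = field(default_factory=dict)
    true_last_visible_um: dict[str, float] = field(default_factory=dict)
    true_last_visible_angle_deg: dict[str, float] = field(default_factory=dict)
    first_gap_censored: dict[str, bool] = field(default_factory=dict)
    no_bundle: dict[str, bool] = field(default_factory=dict)

    def extent_profile(self, theta_deg):
        """Bundle depth extent T(θ) in µm, vectorized over grid angles."""
        return _extent_profile(
            np.asarray(theta_deg, dtype=float),
            self.extent_anchors_um,
            self.wedge_defects,
        )

    def bundle_mask(self, theta_deg):
        """Boolean striation pattern: True where a bundle covers angle θ."""
        phase = np.mod(np.asarray(theta_deg, dtype=float), self.bundle_period_deg)
        return phase < self.bundle_duty * self.bundle_period_deg

    def vessel_mask(self, theta_deg):
        """True where angle θ falls inside a blood vessel."""
        theta = np.asarray(theta_deg, dtype=float)
        mask = np.zeros(theta.shape, dtype=bool)
        for center, half_width in self.vessel_angles:
            delta = np.abs(wrap_deg(theta - center + 180.0) - 180.0)
            mask |= delta <= half_width
        return mask

    def to_dict(self) -> dict:
        return {
            "extent_anchors_um": self.extent_anchors_um,
            "bundle_period_deg": self.bundle_period_deg,
            "bundle_duty": self.bundle_duty,
            "vessel_angles": [list(v) for v in self.vessel_angles],
            "wedge_defects": [list(w) for w in self.wedge_defects],
            "laterality": self.laterality,
            "fovea_disc_angle_deg": self.fovea_disc_angle_deg,
            "md_db": self.md_db,
            "true_first_gap_um": self.true_first_gap_um,
            "true_first_gap_angle_deg": self.true_first_gap_angle_deg,
            "true_last_visible_um": self.true_last_visible_um,
            "true_last_visible_angle_deg": self.true_last_visible_angle_deg,
            "first_gap_censored": self.first_gap_censored,
            "no_bundle": self.no_bundle,
        }


def _extent_profile(
    theta_deg: np.ndarray,
    anchors_um: dict[str, float],
    wedges: tuple[tuple[float, float, float], ...],
) -> np.ndarray:
    """Smooth periodic profile through the sector-center anchors minus wedges.

    Shape-preserving (PCHIP) interpolation on a tripled period: the extent
    varies monotonically between neighbouring anchors, with none of the
    overshoot ringing a cubic spline would add — anatomically the bundle
    depth extent has no sharp notches between sectors (wedge defects model
    those explicitly).
    """
    centers = np.array([SECTOR_CENTER_DEG[s] for s in SECTOR_NAMES])
    depths = np.array([anchors_um[s] for s in SECTOR_NAMES])
    order = np.argsort(centers)
    xs, ys = centers[order], depths[order]
    x3 = np.concatenate([xs - 360.0, xs, xs + 360.0])
    y3 = np.tile(ys, 3)
    interp = PchipInterpolator(x3, y3)
    # evaluate inside the central copy -> exactly periodic
    base = interp(np.mod(theta_deg - xs[0], 360.0) + xs[0])
    for center, width, reduction in wedges:
        delta = wrap_deg(theta_deg - center + 180.0) - 180.0
        inside = np.abs(delta) < width / 2.0
        taper = np.zeros_like(base)
        taper[inside] = reduction * 0.5 * (1.0 + np.cos(2.0 * np.pi * delta[inside] / width))
        base = base - taper
    return np.clip(base, 0.0, MAX_DEPTH_UM)


def _qualifying_runs(mask: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs with length >= min_samples."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_samples]


def _true_indices(
    truth: EyeTruth,
    gap_min_deg: float,
    step_deg: float = 0.05,
) -> None:
    """Fill the per-sector true indices by dense angular enumeration.

    Vessel angles carry no bundle evidence and are removed before run
    analysis; run lengths are measured as sample count × angular step on the
    remaining angles, the same convention the extractor uses.
    """
    from .geometry import SECTOR_STARTS_DEG, SECTOR_WIDTHS_DEG

    for name, start, width in zip(SECTOR_NAMES, SECTOR_STARTS_DEG, SECTOR_WIDTHS_DEG):
        offsets = np.arange(0.0, width, step_deg)
        angles = wrap_deg(start + offsets)
        keep = ~truth.vessel_mask(angles)
        angles = angles[keep]
        extent = truth.extent_profile(angles)
        on_pattern = truth.bundle_mask(angles)

        visible_depths = extent[on_pattern]
        if visible_depths.size and visible_depths.max() > 0:
            t_max = float(visible_depths.max())
            k_last = int(np.ceil(t_max / SLAB_UM)) - 1  # deepest slab with k*SLAB < T
            truth.no_bundle[name] = False
            truth.true_last_visible_um[name] = k_last * SLAB_UM
            at_max = angles[on_pattern][np.argmax(visible_depths)]
            truth.true_last_visible_angle_deg[name] = float(at_max)
        else:
            truth.no_bundle[name] = True
            truth.true_last_visible_um[name] = 0.0
            truth.true_last_visible_angle_deg[name] = float("nan")

        gap_min_samples = max(1, int(np.ceil(gap_min_deg / step_deg)))
        truth.first_gap_censored[name] = True
        truth.true_first_gap_um[name] = float("nan")
        truth.true_first_gap_angle_deg[name] = float("nan")
        for k in range(N_SLABS):
            gap = ~(on_pattern & (extent > k * SLAB_UM))
            runs = _qualifying_runs(gap, gap_min_samples)
            if runs:
                a, b = runs[0]
                truth.first_gap_censored[name] = False
                truth.true_first_gap_um[name] = k * SLAB_UM
                truth.true_first_gap_angle_deg[name] = float(angles[(a + b - 1) // 2])
                break


def generate_eye(
    extent_anchors_um: dict[str, float] | None = None,
    wedge_defects: tuple[tuple[float, float, float], ...] = (),
    vessel_angles: tuple[tuple[float, float], ...] = DEFAULT_VESSEL_ANGLES,
    bundle_period_deg: float = 2.0,
    bundle_duty: float = 0.5,
    laterality: str = "OD",
    fovea_disc_angle_deg: float = 0.0,
    md_db: float = 0.0,
    noise_sd: float = 0.05,
    seed: int | None = None,
    image_shape: tuple[int, int] = (512, 512),
    transverse_scale_um_per_px: float = 10.0,
    gap_min_deg: float = 3.0,
) -> tuple[EnfaceStack, EyeTruth]:
    """Render one synthetic eye and its ground truth.

    The stack is already normalized (values in [0, 1]): bundles at 0.85 over
    a 0.10 background, additive N(0, noise_sd²) noise clipped back to [0, 1].
    A pixel at grid angle θ in slab k is bundle-bright iff the striation
    pattern is on at θ and ``k·3.87 < T(θ)``; vessel angles are bright in
    every slab. ``gap_min_deg`` parameterizes the analytic first-gap rule
    (matching the extractor default); the true last visible bundle is the
    quantized sector maximum of T over striation-on, non-vessel angles.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < bundle_duty < 1:
        raise ValueError("bundle_duty must be in (0, 1)")
    anchors = dict(DEFAULT_EXTENT_ANCHORS_UM if extent_anchors_um is None else extent_anchors_um)
    truth = EyeTruth(
        extent_anchors_um=anchors,
        bundle_period_deg=bundle_period_deg,
        bundle_duty=bundle_duty,
        vessel_angles=tuple(tuple(v) for v in vessel_angles),
        wedge_defects=tuple(tuple(w) for w in wedge_defects),
        laterality=laterality,
        fovea_disc_angle_deg=fovea_disc_angle_deg,
        md_db=md_db,
    )
    _true_indices(truth, gap_min_deg=gap_min_deg)

    n_rows, n_cols = image_shape
    center = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    grid = SectorGrid(
        center_px=center,
        fovea_disc_angle_deg=fovea_disc_angle_deg,
        laterality=laterality,
    )
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    theta = grid.grid_angle_of_pixel(rows, cols)
    extent = truth.extent_profile(theta)
    striation = truth.bundle_mask(theta)
    vessel = truth.vessel_mask(theta)

    depths = np.arange(N_SLABS) * SLAB_UM
    slabs = np.full((N_SLABS, n_rows, n_cols), BACKGROUND_LEVEL)
    bundle_base = striation & ~vessel
    for k, d in enumerate(depths):
        bright = (bundle_base & (extent > d)) | vessel
        slabs[k][bright] = BUNDLE_LEVEL
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        slabs = slabs + rng.normal(0.0, noise_sd, size=slabs.shape)
    slabs = np.clip(slabs, 0.0, 1.0)

    stack = EnfaceStack(
        slabs=slabs,
        normalized=True,
        transverse_scale_um_per_px=transverse_scale_um_per_px,
        meta={"synthetic": True, "seed": seed, "noise_sd": noise_sd},
    )
    return stack, truth


#: Illustrative healthy per-sector means (µm) for the two indices; the
#: temporal values match a worked healthy eye (first gap 58, last visible
#: 108 µm), the rest follow the ISNT-like extent defaults.
DEFAULT_CONTROL_MEAN_FG: dict[str, float] = {
    "TMP": 58.0, "TS": 75.0, "NS": 65.0, "NAS": 50.0, "NI": 70.0, "TI": 80.0,
}
DEFAULT_CONTROL_MEAN_LV: dict[str, float] = {
    "TMP": 108.0, "TS": 135.0, "NS": 115.0, "NAS": 90.0, "NI": 125.0, "TI": 140.0,
}


@dataclass
class CohortSpec:
    """Generative model for an index-level cohort (long eye × sector table).

    Depth indices follow the variance-components model

        y = mean[sector] − offset·[glaucoma] + u_eye + v_sector + ε,

    with ``u ~ N(0, sd_eye²)`` per eye, ``v ~ N(0, sd_sector²)`` per sector
    (shared across eyes, i.e. crossed), ``ε ~ N(0, sd_resid²)`` per cell,
    clipped to [0, 193.5] µm. Paired thickness is
    ``intercept + slope·depth + N(0, σ_ε²)``; if a ``target_r_*`` is set the
    group's σ_ε is derived from the closed form
    ``r = β σ_w / sqrt(β² σ_w² + σ_ε²)`` with σ_w² = sd_sector² + sd_resid²
    (the within-eye depth variance that drives the repeated-measures
    correlation), otherwise ``thickness_noise_sd`` is used directly.

    Default effect sizes are the reported glaucoma–control differences
    (39.1 µm first gap, 48.1 µm last visible bundle); default group
    correlations 0.92 (healthy) / 0.80 (glaucoma); mean deviation is
    group-dependent Gaussian (+0.6 ± 1.1 dB controls, −4.5 ± 3.1 dB
    glaucoma) solely to exercise the early-glaucoma subgroup filter.
    """

    n_per_group: int = 20
    control_mean_fg: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEAN_FG)
    )
    control_mean_lv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEAN_LV)
    )
    glaucoma_offset_fg: float = 39.1
    glaucoma_offset_lv: float = 48.1
    sd_eye: float = 10.0
    sd_sector: float = 5.0
    sd_resid: float = 8.0
    thickness_slope: float = 0.5
    thickness_intercept: float = 30.0
    thickness_noise_sd: float | None = None
    target_r_healthy: float | None = 0.92
    target_r_glaucoma: float | None = 0.80
    md_mean_control: float = 0.6
    md_sd_control: float = 1.1
    md_mean_glaucoma: float = -4.5
    md_sd_glaucoma: float = 3.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("sd_eye", "sd_sector", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thickness_noise_sd is not None and self.thickness_noise_sd < 0:
            raise ValueError("thickness_noise_sd must be >= 0")
        for name in ("target_r_healthy", "target_r_glaucoma"):
            r = getattr(self, name)
            if r is not None and not 0 < r <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def thickness_noise_for(self, group: str, index: str = "fg") -> float:
        """σ_ε of the thickness noise for a group/index, from target r if set.

        Inverts r = β σ_x / sqrt(β² σ_x² + σ_ε²) for σ_ε, where σ_x² is the
        within-eye depth variance: the spread of the per-sector means plus
        the sector and residual variance components (within-subject demeaning
        shrinks the depth signal and the noise by the same factor, so the
        un-demeaned variances give the repeated-measures correlation).
        """
        target = self.target_r_healthy if group == "control" else self.target_r_glaucoma
        if target is None:
            if self.thickness_noise_sd is None:
                raise ValueError("set thickness_noise_sd or a target correlation")
            return self.thickness_noise_sd
        means = self.control_mean_fg if index == "fg" else self.control_mean_lv
        var_means = float(np.var(list(means.values())))  # offsets shift, not spread
        sigma_x = float(np.sqrt(var_means + self.sd_sector**2 + self.sd_resid**2))
        beta = abs(self.thickness_slope)
        if target >= 1.0:
            return 0.0
        return beta * sigma_x * float(np.sqrt(1.0 / target**2 - 1.0))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format cohort table from a :class:`CohortSpec`.

    Columns: eye_id, group, sector, first_gap_um, last_visible_um,
    thickness_at_fg_um, thickness_at_lv_um, md_db. One row per eye × sector;
    reproducible bit-for-bit under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sectors = list(SECTOR_NAMES)
    # Crossed sector intercepts: one draw per sector per index, shared by all
    # eyes, matching the mixed model's random ONH-sector term.
    v_fg = rng.normal(0.0, spec.sd_sector, size=len(sectors))
    v_lv = rng.normal(0.0, spec.sd_sector, size=len(sectors))
    rows = []
    for group, md_mean, md_sd in (
        ("control", spec.md_mean_control, spec.md_sd_control),
        ("glaucoma", spec.md_mean_glaucoma, spec.md_sd_glaucoma),
    ):
        offset_fg = 0.0 if group == "control" else spec.glaucoma_offset_fg
        offset_lv = 0.0 if group == "control" else spec.glaucoma_offset_lv
        sigma_eps_fg = spec.thickness_noise_for(group, "fg")
        sigma_eps_lv = spec.thickness_noise_for(group, "lv")
        for i in range(spec.n_per_group):
            eye_id = f"{group[0].upper()}{i:03d}"
            u_fg = rng.normal(0.0, spec.sd_eye)
            u_lv = rng.normal(0.0, spec.sd_eye)
            md = rng.normal(md_mean, md_sd)
            for s_idx, sector in enumerate(sectors):
                fg = (
                    spec.control_mean_fg[sector] - offset_fg
                    + u_fg + v_fg[s_idx] + rng.normal(0.0, spec.sd_resid)
                )
                lv = (
                    spec.control_mean_lv[sector] - offset_lv
                    + u_lv + v_lv[s_idx] + rng.normal(0.0, spec.sd_resid)
                )
                fg = float(np.clip(fg, 0.0, MAX_DEPTH_UM))
                lv = float(np.clip(lv, 0.0, MAX_DEPTH_UM))
                th_fg = (
                    spec.thickness_intercept + spec.thickness_slope * fg
                    + rng.normal(0.0, sigma_eps_fg)
                )
                th_lv = (
                    spec.thickness_intercept + spec.thickness_slope * lv
                    + rng.normal(0.0, sigma_eps_lv)
                )
                rows.append(
                    {
                        "eye_id": eye_id,
                        "group": group,
                        "sector": sector,
                        "first_gap_um": fg,
                        "last_visible_um": lv,
                        "thickness_at_fg_um": max(th_fg, 0.0),
                        "thickness_at_lv_um": max(th_lv, 0.0),
                        "md_db": float(md),
                    }
                )
    return pd.DataFrame(rows)
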