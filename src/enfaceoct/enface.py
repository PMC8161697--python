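"""Enface depth-stack construction from ILM-flattened OCT volumes.

Pipeline: per-A-scan depth-resolved attenuation coefficients → single-sample
enface slabs on the 3.87 µm grid (0–193.5 µm below the ILM) → optional
montage of overlapping scans (maximum rule) → background subtraction and
99th-percentile normalization to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import MAX_DEPTH_UM, N_SLABS, SLAB_UM

logger = logging.getLogger(__name__)

#: Depth (µm below ILM) of the bundle-free raphe slab used for background.
BACKGROUND_DEPTH_UM: float = 35.0


@dataclass
class AlignedVolume:
    """ILM-flattened volume, ``intensity[depth, row, col]`` on a linear scale.

    ``origin_px`` places the volume's (row 0, col 0) on a common montage
    canvas. ``validity`` (same shape as ``intensity``) marks voxels whose
    attenuation coefficient could be computed; it is None for raw intensity.
    """

    intensity: np.ndarray
    axial_step_um: float = SLAB_UM
    transverse_scale_um_per_px: float = 10.0
    origin_px: tuple[int, int] = (0, 0)
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (depth, rows, cols)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.axial_step_um <= 0:
            raise ValueError("axial_step_um must be positive")


@dataclass
class EnfaceStack:
    """Stack of single-sample enface slabs, ``slabs[k, row, col]``.

    Slab ``k`` spans ``[k*3.87, (k+1)*3.87)`` µm below the ILM and is reported
    at its anterior edge ``k*3.87`` µm. After :func:`normalize_stack`,
    ``normalized`` is True and all values lie in [0, 1]. ``coverage`` marks
    canvas pixels covered by at least one scan after :func:`montage`.
    """

    slabs: np.ndarray
    normalized: bool = False
    transverse_scale_um_per_px: float = 10.0
    origin_px: tuple[int, int] = (0, 0)
    coverage: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slabs = np.asarray(self.slabs, dtype=float)
        if self.slabs.ndim != 3:
            raise ValueError("slabs must be 3-D (slab, rows, cols)")

    @property
    def n_slabs(self) -> int:
        return self.slabs.shape[0]

    def slab_depths_um(self) -> np.ndarray:
        """Reported (anterior-edge) depth of each slab, µm below the ILM."""
        return np.arange(self.n_slabs) * SLAB_UM


def compute_attenuation(volume: AlignedVolume, tail_epsilon: float = 1e-12) -> AlignedVolume:
    """Depth-resolved attenuation coefficients, mm⁻¹, per A-scan.

    For axial sample ``i`` with intensity ``I_i`` and axial step ``Δ`` (mm),

        μ_i = I_i / (2 Δ Σ_{j>i} I_j)

    i.e. each sample's intensity normalized by twice the integrated signal
    below it, which makes μ an intrinsic tissue property insensitive to
    overall signal strength. Samples whose below-tail sum is ≤ ``tail_epsilon``
    (including the deepest sample and any all-zero A-scan) get μ = 0 and are
    flagged invalid in the returned volume's ``validity`` mask.
    """
    if tail_epsilon < 0:
        raise ValueError("tail_epsilon must be >= 0")
    intensity = volume.intensity
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    delta_mm = volume.axial_step_um / 1000.0
    # tail[i] = sum of intensities strictly below sample i in the same A-scan
    below = np.flip(np.cumsum(np.flip(intensity, axis=0), axis=0), axis=0)
    tail = below - intensity
    valid = tail > tail_epsilon
    mu = np.zeros_like(intensity)
    np.divide(intensity, 2.0 * delta_mm * tail, out=mu, where=valid)
    return AlignedVolume(
        intensity=mu,
        axial_step_um=volume.axial_step_um,
        transverse_scale_um_per_px=volume.transverse_scale_um_per_px,
        origin_px=volume.origin_px,
        validity=valid,
    )


def extract_slabs(attenuation_volume: AlignedVolume) -> EnfaceStack:
    """Take the first 50 axial samples as single-sample enface slabs.

    No depth averaging is applied: slab ``k`` *is* depth sample ``k``.
    Raises ``ValueError`` if the volume is shallower than 50 samples.
    """
    depth = attenuation_volume.intensity.shape[0]
    if depth < N_SLABS:
        raise ValueError(
            f"volume has {depth} axial samples; {N_SLABS} are required to "
            f"cover 0-{MAX_DEPTH_UM} um below the ILM"
        )
    return EnfaceStack(
        slabs=attenuation_volume.intensity[:N_SLABS].copy(),
        normalized=False,
        transverse_scale_um_per_px=attenuation_volume.transverse_scale_um_per_px,
        origin_px=attenuation_volume.origin_px,
    )


def montage(stacks: list[EnfaceStack], reference_index: int = 0) -> EnfaceStack:
    """Montage overlapping enface stacks onto one canvas.

    Each stack is placed at its ``origin_px`` offset; where scans overlap the
    highest value wins (per pixel, per slab). Pixels covered by no scan are 0
    and marked False in the result's ``coverage`` mask. The reference stack
    contributes the metadata (scale); all stacks must share slab count and
    transverse scale.
    """
    if not stacks:
        raise ValueError("montage requires at least one stack")
    ref = stacks[reference_index]
    for s in stacks:
        if s.n_slabs != ref.n_slabs:
            raise ValueError("all stacks must have the same slab count")
        if s.transverse_scale_um_per_px != ref.transverse_scale_um_per_px:
            raise ValueError("all stacks must share the transverse scale")
    rows0 = min(s.origin_px[0] for s in stacks)
    cols0 = min(s.origin_px[1] for s in stacks)
    rows1 = max(s.origin_px[0] + s.slabs.shape[1] for s in stacks)
    cols1 = max(s.origin_px[1] + s.slabs.shape[2] for s in stacks)
    canvas = np.full((ref.n_slabs, rows1 - rows0, cols1 - cols0), -np.inf)
    coverage = np.zeros(canvas.shape[1:], dtype=bool)
    for s in stacks:
        r = s.origin_px[0] - rows0
        c = s.origin_px[1] - cols0
        view = canvas[:, r : r + s.slabs.shape[1], c : c + s.slabs.shape[2]]
        np.maximum(view, s.slabs, out=view)
        coverage[r : r + s.slabs.shape[1], c : c + s.slabs.shape[2]] = True
    canvas[:, ~coverage] = 0.0
    return EnfaceStack(
        slabs=canvas,
        normalized=False,
        transverse_scale_um_per_px=ref.transverse_scale_um_per_px,
        origin_px=(rows0, cols0),
        coverage=coverage,
    )


def background_slab_index() -> int:
    """Index of the slab containing the 35 µm background depth (⌊35/3.87⌋)."""
    return int(BACKGROUND_DEPTH_UM // SLAB_UM)


def normalize_stack(stack: EnfaceStack, background_roi: tuple | np.ndarray) -> EnfaceStack:
    """Background-subtract and normalize a stack to the [0, 1] range.

    The background level ``b`` is the mean of ``background_roi`` — a
    caller-chosen bundle-free region in the raphe — evaluated in the slab
    containing 35 µm below the ILM (slab 9). ``b`` is subtracted everywhere
    and negatives clipped to zero; the result is divided by the mean over all
    50 slabs of each slab's 99th percentile (linear-interpolation quantile,
    computed after subtraction) and values above 1 are clipped to 1.

    ``background_roi`` is either a boolean mask of the slab's shape or a
    ``(row_slice, col_slice)`` pair. Raises ``ValueError`` on an empty ROI or
    a zero normalizer (degenerate stack).
    """
    if stack.normalized:
        raise ValueError("stack is already normalized")
    k_bg = background_slab_index()
    bg_slab = stack.slabs[k_bg]
    if isinstance(background_roi, np.ndarray) and background_roi.dtype == bool:
        roi_values = bg_slab[background_roi]
    else:
        row_slice, col_slice = background_roi
        roi_values = bg_slab[row_slice, col_slice].ravel()
    if roi_values.size == 0:
        raise ValueError("background ROI is empty")
    b = float(np.mean(roi_values))
    shifted = np.clip(stack.slabs - b, 0.0, None)
    per_slab_p99 = np.percentile(shifted, 99.0, axis=(1, 2))  # type-7 quantile
    normalizer = float(np.mean(per_slab_p99))
    if normalizer <= 0:
        raise ValueError("zero normalizer: stack has no signal above background")
    logger.info("normalize_stack: background=%.6g normalizer=%.6g", b, normalizer)
    out = np.clip(shifted / normalizer, 0.0, 1.0)
    return EnfaceStack(
        slabs=out,
        normalized=True,
        transverse_scale_um_per_px=stack.transverse_scale_um_per_px,
        origin_px=stack.origin_px,
        coverage=None if stack.coverage is None else stack.coverage.copy(),
        meta={**stack.meta, "background": b, "normalizer": normalizer},
    )
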