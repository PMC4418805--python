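"""Detection and classification of F-actin bands in unwrapped space.

A band detected on the (s, θ) grid is summarized by its angular coverage
(union of occupied azimuth bins, computed with θ-wraparound so an arc
crossing θ = 0 is one segment), its obliquity (angle between the band's
principal direction and the transversal direction, measured in arc-length
coordinates (s, θ·r) so the angle is geometrically meaningful on fibers of
any radius), and its mean intensity.  Classification:

* **AG** (actin grip): near-complete ring — coverage ≥ 330° and obliquity
  below the longitudinal threshold.  The 330° default (rather than a strict
  360°) absorbs the 1-2 bins that interpolation and noise erode from true
  full rings.
* **LONGITUDINAL**: obliquity ≥ 60°, i.e. a stress fiber running along the
  fiber axis regardless of coverage.
* **CAB** (concave actin bundle): everything else — partial, often oblique
  arcs regarded as intermediates of ring assembly.

Two further indices operationalize qualitative observations about gripping:
marginal prominence (are bands at the cell's extremities brighter than
interior ones?) and the sharpness of stained/unstained transitions in the
fiber-channel axial profile (tight apposition blocks dye diffusion, giving
step-like edges bounded by rings).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from skimage import filters, measure

from .errors import EmptyForegroundError, NoTransitionError
from .unwrap import UnwrappedImage

__all__ = [
    "RingSegment",
    "MarginalProminence",
    "detect_bands",
    "classify_band",
    "marginal_prominence",
    "boundary_sharpness",
    "AG_MIN_COVERAGE_DEG",
    "LONG_MIN_OBLIQUITY_DEG",
]

AG_MIN_COVERAGE_DEG = 330.0
LONG_MIN_OBLIQUITY_DEG = 60.0


@dataclasses.dataclass
class RingSegment:
    """One detected F-actin band around a fiber."""

    fiber_id: int
    s_span: tuple[float, float]  # axial extent in μm
    angular_coverage: float  # degrees in (0, 360]
    angular_offset: float  # degrees, start of the covered arc
    obliquity: float  # degrees in [0, 90]
    mean_intensity: float
    band_class: str  # "AG" | "CAB" | "LONGITUDINAL"
    n_bins: int = 0

    @property
    def s_center(self) -> float:
        return 0.5 * (self.s_span[0] + self.s_span[1])


@dataclasses.dataclass
class MarginalProminence:
    """Marginal vs interior band intensity; ``defined`` is False when a group is empty."""

    ratio: float
    n_marginal: int
    n_interior: int
    defined: bool


def classify_band(
    angular_coverage: float,
    obliquity: float,
    ag_min_coverage: float = AG_MIN_COVERAGE_DEG,
    long_min_obliquity: float = LONG_MIN_OBLIQUITY_DEG,
) -> str:
    """AG / CAB / LONGITUDINAL decision; high obliquity dominates coverage."""
    if obliquity >= long_min_obliquity:
        return "LONGITUDINAL"
    if angular_coverage >= ag_min_coverage:
        return "AG"
    return "CAB"


def _merge_wraparound(labels: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """Union labels touching across the θ = 0 / θ = 360 seam."""
    parent = np.arange(labels.max() + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    left, right = labels[:, 0], labels[:, -1]
    # 8-connectivity across the seam: compare each left bin with the right
    # column's same row and row ± 1
    for shift in (-1, 0, 1):
        r = np.roll(right, shift, axis=0)
        both = (left > 0) & (r > 0)
        for a, b in zip(left[both], r[both]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    for i in range(len(parent)):
        parent[i] = find(i)
    return parent[labels]


def _circular_gap_start(occupied_bins: np.ndarray, n_theta: int) -> tuple[int, int]:
    """Return (arc start bin, largest circular gap size in bins)."""
    occ = np.zeros(n_theta, dtype=bool)
    occ[occupied_bins] = True
    if occ.all():
        return 0, 0
    free = np.flatnonzero(~occ)
    # gaps are runs of free bins, circularly
    breaks = np.flatnonzero(np.diff(free) > 1)
    runs = np.split(free, breaks + 1)
    if len(runs) > 1 and free[0] == 0 and free[-1] == n_theta - 1:
        runs[0] = np.concatenate([runs.pop(-1), runs[0]])
    best = max(runs, key=len)
    return int((best[-1] + 1) % n_theta), len(best)


def detect_bands(
    unwrapped: UnwrappedImage,
    threshold: str | float = "otsu",
    min_extent_bins: int = 2,
    ag_min_coverage: float = AG_MIN_COVERAGE_DEG,
    long_min_obliquity: float = LONG_MIN_OBLIQUITY_DEG,
) -> list[RingSegment]:
    """Segment supra-threshold bands on the periodic (s, θ) grid.

    Thresholding (Otsu on unmasked bins by default) is followed by
    8-connected labeling with wraparound in θ; specks thinner than
    ``min_extent_bins`` in both directions are dropped.
    """
    if not unwrapped.valid.any():
        raise EmptyForegroundError("unwrapped image is fully masked")
    vals = unwrapped.values
    if threshold == "otsu":
        thr = float(filters.threshold_otsu(vals[unwrapped.valid]))
    else:
        thr = float(threshold)
    fg = (vals > thr) & unwrapped.valid
    if not fg.any():
        return []
    labels = measure.label(fg, connectivity=2)
    labels = _merge_wraparound(labels, fg)
    n_theta = unwrapped.n_theta
    r_shell = max(0.5 * (unwrapped.shell_radii[0] + unwrapped.shell_radii[1]), 1e-6)
    dth_rad = np.radians(unwrapped.theta_spacing)
    segments = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        si, ti = np.nonzero(labels == lab)
        s_extent = si.max() - si.min() + 1
        occupied = np.unique(ti)
        if s_extent < min_extent_bins and len(occupied) < min_extent_bins:
            continue
        start_bin, gap = _circular_gap_start(occupied, n_theta)
        coverage = min(360.0, len(occupied) * unwrapped.theta_spacing)
        # unwrap θ bins so the covered arc is contiguous starting at 0
        t_shifted = (ti - start_bin) % n_theta
        x = t_shifted * dth_rad * r_shell  # arc length, μm
        y = unwrapped.s_start + si * unwrapped.s_spacing
        obliquity = _principal_angle(x, y)
        seg = RingSegment(
            fiber_id=unwrapped.fiber_id,
            s_span=(float(y.min()), float(y.max())),
            angular_coverage=float(coverage),
            angular_offset=float(start_bin * unwrapped.theta_spacing),
            obliquity=obliquity,
            mean_intensity=float(vals[si, ti].mean()),
            band_class="",
            n_bins=len(si),
        )
        seg.band_class = classify_band(
            seg.angular_coverage, seg.obliquity, ag_min_coverage, long_min_obliquity
        )
        segments.append(seg)
    return segments


def _principal_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Angle (deg, [0, 90]) between the principal axis of (x, y) and the x direction."""
    if len(x) < 2:
        return 0.0
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.cov(np.stack([xc, yc]))
    if not np.all(np.isfinite(cov)):
        return 0.0
    w, v = np.linalg.eigh(cov)
    principal = v[:, np.argmax(w)]
    return float(np.degrees(np.arccos(min(1.0, abs(principal[0])))))


def marginal_prominence(
    segments: Sequence[RingSegment],
    cell_extent: tuple[float, float],
    margin_frac: float = 0.2,
) -> MarginalProminence:
    """Mean intensity of marginal (cell-end) bands over interior bands.

    Only transversal bands (AG/CAB) are considered; a band is marginal when
    its axial center falls in the outer ``margin_frac`` of the cell extent at
    either end.  A ratio > 1 indicates bands concentrate/intensify at the
    cell's extremities.
    """
    if not 0 < margin_frac < 0.5:
        raise ValueError("margin_frac must be in (0, 0.5)")
    if not segments:
        raise EmptyForegroundError("no segments to analyze")
    s_lo, s_hi = cell_extent
    m = margin_frac * (s_hi - s_lo)
    marginal, interior = [], []
    for seg in segments:
        if seg.band_class == "LONGITUDINAL":
            continue
        c = seg.s_center
        if not s_lo <= c <= s_hi:
            continue
        (marginal if (c <= s_lo + m or c >= s_hi - m) else interior).append(
            seg.mean_intensity
        )
    if not marginal or not interior:
        return MarginalProminence(np.nan, len(marginal), len(interior), False)
    return MarginalProminence(
        float(np.mean(marginal) / np.mean(interior)), len(marginal), len(interior), True
    )


def _level_crossings(s: np.ndarray, v: np.ndarray, level: float) -> np.ndarray:
    """Positions where the profile crosses a level (linear interpolation)."""
    d = v - level
    idx = np.flatnonzero(d[:-1] * d[1:] < 0)
    frac = d[idx] / (d[idx] - d[idx + 1])
    exact = np.flatnonzero(d == 0)
    return np.sort(np.concatenate([s[idx] + frac * (s[idx + 1] - s[idx]), s[exact]]))


def boundary_sharpness(
    s: np.ndarray,
    intensity: np.ndarray,
    min_contrast: float = 0.05,
) -> np.ndarray:
    """Edge widths (μm) of stained/unstained transitions in an axial profile.

    Plateau levels are taken as the 10th/90th percentiles; each crossing of
    their midpoint marks a transition, whose width is the distance between
    the surrounding 25% and 75% crossings.  A profile whose dynamic range is
    below ``min_contrast`` of the high plateau has no transition.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(intensity, dtype=float)
    if len(s) != len(v) or len(s) < 3:
        raise ValueError("profile arrays must match and have >= 3 samples")
    if np.any(np.diff(s) > 0.5 + 1e-9):
        raise ValueError("profile must be sampled at <= 0.5 μm spacing")
    low, high = np.percentile(v, [10, 90])
    if high - low <= min_contrast * max(high, 1e-12):
        raise NoTransitionError("profile has no stained/unstained transition")
    mid = 0.5 * (low + high)
    l25 = low + 0.25 * (high - low)
    l75 = low + 0.75 * (high - low)
    mids = _level_crossings(s, v, mid)
    c25 = _level_crossings(s, v, l25)
    c75 = _level_crossings(s, v, l75)
    if len(mids) == 0:
        raise NoTransitionError("no midpoint crossing found")
    widths = []
    h = 0.25 * float(np.median(np.diff(s)))
    for sm in mids:
        rising = np.interp(sm + h, s, v) > np.interp(sm - h, s, v)
        lo_side, hi_side = (c25, c75) if rising else (c75, c25)
        before = lo_side[lo_side <= sm]
        after = hi_side[hi_side >= sm]
        if len(before) == 0 or len(after) == 0:
            continue  # transition truncated at the profile boundary
        widths.append(after[0] - before[-1])
    if not widths:
        raise NoTransitionError("transitions truncated at profile ends")
    return np.asarray(widths)
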