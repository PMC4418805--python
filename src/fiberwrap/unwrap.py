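"""Cylindrical unwrapping of the space around a fitted fiber axis.

Two flavors, mirroring how wrapped F-actin is visualized and quantified:

* **planar unwrapping** — for each (axial position s, azimuth θ) bin, project
  the intensity over a radial band ``[r_in, r_out]`` (max by default, mean
  optionally).  A full actin ring appears as a horizontal stripe spanning
  every θ bin; a longitudinal stress fiber as a vertical stripe at one θ.
* **layered unwrapping** — sample single cylindrical shells at a list of
  increasing radii, all sharing the (s, θ) grid, so signal can be localized
  radially (e.g. actin confined to the membrane-fiber interface shows up in
  the near shell and vanishes two micrometers further out).

The azimuthal frame is parallel-transported along the axis so that θ varies
smoothly without twist artifacts on curved fibers; θ = 0 is the frame vector
closest to +y at the first axis point (arbitrary but deterministic, and
shared with the synthetic-scene generator).  Sample points outside the image
volume are masked, not zero-filled, and all downstream statistics ignore
masked bins.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fibergeom import FiberAxis
from .io_stacks import ImageStack
from .synthgen import fiber_frame

__all__ = ["UnwrappedImage", "unwrap_planar", "unwrap_layered", "transport_frames"]


@dataclasses.dataclass
class UnwrappedImage:
    """2D intensity map indexed (axial s, azimuth θ) around one fiber.

    ``values`` has shape (n_s, n_theta); ``valid`` marks bins whose sample
    points fell inside the image volume.  θ spans [0°, 360°) periodically at
    ``theta_spacing`` degrees per bin; s spans the axis arc length at uniform
    ``s_spacing`` μm.  ``shell_radii`` records the sampled radius (single
    shell) or radial band (planar projection) in μm from the fiber axis.
    """

    values: np.ndarray
    valid: np.ndarray
    s_spacing: float
    theta_spacing: float
    shell_radii: tuple[float, float]
    fiber_id: int
    s_start: float = 0.0

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]

    @property
    def s_coords(self) -> np.ndarray:
        return self.s_start + np.arange(self.values.shape[0]) * self.s_spacing

    @property
    def theta_coords(self) -> np.ndarray:
        return np.arange(self.n_theta) * self.theta_spacing

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(self.valid.mean())


def transport_frames(axis: FiberAxis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parallel-transported orthonormal frames (u, e1, e2) along the axis.

    The initial frame follows the θ=0 convention of
    :func:`fiberwrap.synthgen.fiber_frame`; subsequent frames rotate by the
    minimal rotation mapping each tangent to the next, which keeps the θ
    origin from spinning about the axis on curved fibers.
    """
    if len(axis.points) < 2:
        raise ValueError("axis must have at least 2 points")
    u = axis.tangents()
    _, e1_0, _ = fiber_frame(u[0])
    e1 = np.empty_like(u)
    e1[0] = e1_0
    for i in range(1, len(u)):
        prev = e1[i - 1]
        # project previous reference onto the plane normal to the new tangent
        v = prev - (prev @ u[i]) * u[i]
        n = np.linalg.norm(v)
        if n < 1e-12:  # pathological kink; fall back to the static convention
            _, v, _ = fiber_frame(u[i])
            n = 1.0
        e1[i] = v / n
    e2 = np.cross(u, e1)
    return u, e1, e2


def _default_n_theta(radius: float, voxel_size) -> int:
    """θ bin count so surface arc length per bin ≈ in-plane voxel size."""
    dx = float(min(voxel_size[1], voxel_size[2]))
    return max(8, int(round(2 * np.pi * radius / dx)))


def _sample(volume: np.ndarray, voxel_size, points_um: np.ndarray) -> np.ndarray:
    """Trilinear sampling at physical points; NaN outside the volume."""
    vs = np.asarray(voxel_size, dtype=float)
    coords = (points_um / vs).T  # (3, N) in voxel units
    return ndimage.map_coordinates(
        volume.astype(np.float64), coords, order=1, mode="constant", cval=np.nan
    )


def _shell_points(axis, e1, e2, theta_rad, radii):
    """Sample positions p[i, j, k] = axis_i + r[i, k] · (cosθ_j e1_i + sinθ_j e2_i)."""
    cos_t, sin_t = np.cos(theta_rad), np.sin(theta_rad)
    # radial unit vector per (s, θ): (ns, nθ, 3)
    radial = cos_t[None, :, None] * e1[:, None, :] + sin_t[None, :, None] * e2[:, None, :]
    return (axis.points[:, None, None, :]
            + radii[:, None, :, None] * radial[:, :, None, :])


def _resolve_radius(axis: FiberAxis) -> np.ndarray:
    r = axis.local_radius.copy()
    if not np.isfinite(r).any():
        raise ValueError("axis has no local_radius defined; fit diameters first "
                         "or pass an explicit radial band")
    r[~np.isfinite(r)] = np.nanmedian(r)
    return r


def unwrap_planar(
    stack: ImageStack,
    channel: str,
    axis: FiberAxis,
    radial_band: tuple[float, float] | None = None,
    n_theta: int | None = None,
    projection: str = "max",
    radial_step: float | None = None,
    frame: int = 0,
) -> UnwrappedImage:
    """Project a radial band around the fiber onto the (s, θ) plane.

    By default the band is ``[local_radius, local_radius + 3 μm]`` at each
    axis point — the shell where wrapped cortical actin lives.  ``projection``
    is ``"max"`` (default; preserves thin rings) or ``"mean"``.
    """
    if projection not in ("max", "mean"):
        raise ValueError("projection must be 'max' or 'mean'")
    volume = stack.channel(channel, frame)
    u, e1, e2 = transport_frames(axis)
    if radial_band is not None:
        r_in, r_out = (float(r) for r in radial_band)
        if not r_out > r_in or r_in < 0:
            raise ValueError("need r_out > r_in >= 0")
        r_lo = np.full(len(axis.points), r_in)
        r_hi = np.full(len(axis.points), r_out)
        ref_radius = (r_in + r_out) / 2
    else:
        r_lo = _resolve_radius(axis)
        r_hi = r_lo + 3.0
        ref_radius = float(np.median(r_lo))
    if n_theta is None:
        n_theta = _default_n_theta(max(ref_radius, 1e-3), stack.voxel_size)
    theta = np.radians(np.arange(n_theta) * (360.0 / n_theta))
    if radial_step is None:
        radial_step = float(min(stack.voxel_size[1], stack.voxel_size[2])) / 2
    n_r = max(2, int(np.ceil((r_hi - r_lo).max() / radial_step)) + 1)
    frac = np.linspace(0.0, 1.0, n_r)
    radii = r_lo[:, None] + frac[None, :] * (r_hi - r_lo)[:, None]  # (ns, nr)

    pts = _shell_points(axis, e1, e2, theta, radii)  # (ns, nθ, nr, 3)
    vals = _sample(volume, stack.voxel_size, pts.reshape(-1, 3)).reshape(pts.shape[:3])
    valid = np.isfinite(vals).any(axis=2)
    if projection == "max":
        img = np.where(np.isfinite(vals), vals, -np.inf).max(axis=2)
        img[~valid] = 0.0
    else:
        cnt = np.isfinite(vals).sum(axis=2)
        img = np.nansum(np.where(np.isfinite(vals), vals, 0.0), axis=2)
        img = np.divide(img, cnt, out=np.zeros_like(img), where=cnt > 0)
    img[~valid] = 0.0
    s = axis.arclength
    return UnwrappedImage(
        values=img,
        valid=valid,
        s_spacing=float(s[1] - s[0]) if len(s) > 1 else 0.0,
        theta_spacing=360.0 / n_theta,
        shell_radii=(float(r_lo.min()), float(r_hi.max())),
        fiber_id=axis.fiber_id,
        s_start=float(s[0]),
    )


def unwrap_layered(
    stack: ImageStack,
    channel: str,
    axis: FiberAxis,
    radii: Sequence[float],
    n_theta: int | None = None,
    frame: int = 0,
) -> list[UnwrappedImage]:
    """Sample single cylindrical shells at each radius (no radial projection).

    All shells share the (s, θ) grid, so their bins compare one-to-one.
    ``radii`` must be strictly increasing.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) == 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be a non-empty strictly increasing sequence")
    volume = stack.channel(channel, frame)
    u, e1, e2 = transport_frames(axis)
    if n_theta is None:
        n_theta = _default_n_theta(float(radii[0]), stack.voxel_size)
    theta = np.radians(np.arange(n_theta) * (360.0 / n_theta))
    s = axis.arclength
    out = []
    for r in radii:
        r_arr = np.full((len(axis.points), 1), r)
        pts = _shell_points(axis, e1, e2, theta, r_arr)[:, :, 0, :]
        vals = _sample(volume, stack.voxel_size, pts.reshape(-1, 3)).reshape(pts.shape[:2])
        valid = np.isfinite(vals)
        vals = np.where(valid, vals, 0.0)
        out.append(UnwrappedImage(
            values=vals,
            valid=valid,
            s_spacing=float(s[1] - s[0]) if len(s) > 1 else 0.0,
            theta_spacing=360.0 / n_theta,
            shell_radii=(float(r), float(r)),
            fiber_id=axis.fiber_id,
            s_start=float(s[0]),
        ))
    return out
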