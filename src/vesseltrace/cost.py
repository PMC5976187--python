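"""Cost image construction.

The tracking cost at voxel x is

    p(x) = 1 / (eps + m(x)^alpha * s(x)^beta)

where ``m`` is a multi-scale circular medialness response in [0, 1] peaking
at the centre of tubular cross-sections, and ``s`` is a lumen-intensity
similarity in [0, 1] relative to the intensity statistics inside spherical
ROIs around the seed points.  With multiple co-registered sequences, the
voxelwise maximum of each term over the sequences is used.  A constant
``omega`` added to p (p_tilde = p + omega) penalises path length and hence
curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import SeedSet, Volume

__all__ = [
    "CostParams",
    "CostImage",
    "medialness",
    "lumen_similarity",
    "combine_cost",
    "multispectral_cost",
    "crop_roi",
]

DEFAULT_SCALES = (2.0, 2.5, 3.0, 3.5)


@dataclass(frozen=True)
class CostParams:
    """Tunables of the cost image.

    ``alpha``/``beta`` weight medialness vs. intensity similarity (equal by
    default), ``epsilon`` guards against division by zero, ``scales`` are
    the medialness radii in mm, the ROI radii size the seed spheres for the
    intensity statistics, and ``omega`` is the length/smoothness penalty.
    """

    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 1e-6
    scales: tuple[float, ...] = DEFAULT_SCALES
    roi_radius_cca: float = 3.5
    roi_radius_branch: float = 2.5
    omega: float = 0.0
    n_rays: int = 16

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if len(self.scales) == 0 or any(r <= 0 for r in self.scales):
            raise ValueError("scales must be non-empty and positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


@dataclass
class CostImage:
    """Cost volume p in (0, 1/eps] together with its parameters.

    ``p_tilde`` adds the smoothness constant omega voxelwise.
    """

    p: Volume
    params: CostParams

    @property
    def omega(self) -> float:
        return self.params.omega

    @property
    def p_tilde(self) -> Volume:
        return Volume(self.p.data + self.params.omega, self.p.spacing, self.p.origin)


def medialness(volume: Volume, scales=DEFAULT_SCALES, n_rays: int = 16) -> Volume:
    """Multi-scale in-plane circular medialness, normalised to [0, 1].

    Per voxel and per scale r, the response is the mean over ``n_rays``
    equally spaced in-plane directions of the inward radial intensity
    gradient sampled at distance r, with negative ray contributions clipped
    at zero.  The voxelwise maximum over scales is divided by its global
    maximum.  Carotids run roughly axially, so rays are cast in the x-y
    plane only; a constant image maps to an all-zero response.
    """
    data = volume.data
    hx, hy, _ = volume.spacing
    gx = np.gradient(data, hx, axis=0)
    gy = np.gradient(data, hy, axis=1)
    ii, jj, kk = np.meshgrid(
        np.arange(data.shape[0], dtype=float),
        np.arange(data.shape[1], dtype=float),
        np.arange(data.shape[2], dtype=float),
        indexing="ij",
    )
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    best = np.zeros_like(data)
    for r in scales:
        resp = np.zeros_like(data)
        for ang in angles:
            ux, uy = np.cos(ang), np.sin(ang)
            coords = [ii + r * ux / hx, jj + r * uy / hy, kk]
            gxs = ndimage.map_coordinates(gx, coords, order=1, mode="nearest")
            gys = ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
            inward = -(gxs * ux + gys * uy)
            resp += np.clip(inward, 0.0, None)
        best = np.maximum(best, resp / n_rays)
    peak = best.max()
    if peak > 0:
        best = best / peak
    return Volume(best, volume.spacing, volume.origin)


def _sphere_mask(volume: Volume, center: np.ndarray, radius: float) -> np.ndarray:
    xs, ys, zs = volume.axes_mm()
    dx = xs[:, None, None] - center[0]
    dy = ys[None, :, None] - center[1]
    dz = zs[None, None, :] - center[2]
    return dx * dx + dy * dy + dz * dz <= radius * radius


def lumen_similarity(volume: Volume, seeds: SeedSet, params: CostParams = CostParams()) -> Volume:
    """Gaussian intensity similarity to the seed-ROI lumen statistics.

    mu and sigma are the mean/sd of intensities over the union of spheres
    around x_C (radius ``roi_radius_cca``) and x_I, x_E (radius
    ``roi_radius_branch``); s(x) = exp(-(I(x)-mu)^2 / (2 sigma^2)).  With a
    degenerate ROI (sigma = 0), s is the indicator of I = mu.
    """
    for name, pt in (("x_C", seeds.x_C), ("x_I", seeds.x_I), ("x_E", seeds.x_E)):
        if not volume.contains_world(pt):
            raise ValueError(f"seed {name} lies outside the volume")
    mask = _sphere_mask(volume, seeds.x_C, params.roi_radius_cca)
    mask |= _sphere_mask(volume, seeds.x_I, params.roi_radius_branch)
    mask |= _sphere_mask(volume, seeds.x_E, params.roi_radius_branch)
    roi = volume.data[mask]
    mu = float(roi.mean())
    sigma = float(roi.std())
    if sigma == 0.0:
        s = (volume.data == mu).astype(float)
    else:
        s = np.exp(-((volume.data - mu) ** 2) / (2.0 * sigma * sigma))
    return Volume(s, volume.spacing, volume.origin)


def combine_cost(m: Volume, s: Volume, params: CostParams = CostParams()) -> Volume:
    """p = 1 / (eps + m^alpha * s^beta); values lie in (0, 1/eps]."""
    if m.shape != s.shape or m.spacing != s.spacing or m.origin != s.origin:
        raise ValueError("medialness and similarity volumes live on different grids")
    p = 1.0 / (params.epsilon + np.power(m.data, params.alpha) * np.power(s.data, params.beta))
    return Volume(p, m.spacing, m.origin)


def multispectral_cost(
    volumes: list[Volume], seeds: SeedSet, params: CostParams = CostParams()
) -> CostImage:
    """Cost from one or more co-registered sequences.

    The medialness and the similarity term are each maximised voxelwise over
    the sequences before combining, so adding a sequence can only lower p.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape != ref.shape or v.spacing != ref.spacing or v.origin != ref.origin:
            raise ValueError("all sequences must live on the same grid")
    m_star = None
    s_star = None
    for v in volumes:
        m = medialness(v, params.scales, params.n_rays).data
        s = lumen_similarity(v, seeds, params).data
        m_star = m if m_star is None else np.maximum(m_star, m)
        s_star = s if s_star is None else np.maximum(s_star, s)
    p = combine_cost(
        Volume(m_star, ref.spacing, ref.origin),
        Volume(s_star, ref.spacing, ref.origin),
        params,
    )
    return CostImage(p, params)


def crop_roi(cost: CostImage, seeds: SeedSet, pad_xy: int = 20, pad_z: int = 3) -> CostImage:
    """Crop to the seed bounding box padded by 20 voxels in x-y and 3 in z.

    The origin is updated so world coordinates of surviving voxels are
    unchanged.  The box is clipped at the volume borders.
    """
    vol = cost.p
    seeds.validate_in(vol)
    idx = np.array([vol.nearest_voxel(pt) for pt in seeds.present_points().values()])
    lo = idx.min(axis=0) - np.array([pad_xy, pad_xy, pad_z])
    hi = idx.max(axis=0) + np.array([pad_xy, pad_xy, pad_z])
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(vol.shape) - 1)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    new_origin = tuple(vol.voxel_to_world(lo))
    cropped = Volume(vol.data[sl].copy(), vol.spacing, new_origin)
    return CostImage(cropped, cost.params)
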