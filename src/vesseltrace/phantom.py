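"""Synthetic Y-shaped bifurcating-vessel phantoms.

The generator renders a common trunk that splits into two branches (think
CCA splitting into ICA and ECA) into two pseudo-sequences on an
anisotropic voxel grid, together with analytic ground-truth centerlines
and a seed set.  Each branch leaves the trunk axis along a circular arc
(tangent-continuous) and then runs straight at half the branch angle from
the axial direction, so the "first slice where both branches are visible"
used to place the bifurcation gap point is well defined.

The ``faint_branch_preset`` lowers the lumen contrast of one branch until
it barely differs from background: two independent minimum-cost paths then
collapse onto the clearly visible branch beyond the bifurcation, which is
the failure mode the cooperative extraction is designed to fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .volumes import Centerline, SeedSet, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "faint_branch_preset",
    "study_cost_params",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic bifurcating-tube phantom.

    All lengths in mm, intensities in arbitrary units. ``branch_contrast``
    multiplies the lumen intensity of (first, second) branch; the faint
    preset lowers one component. ``branch_radii`` default to 2.0 mm so that
    a constraint region of radius 1.75 mm (the default) covers the cheap
    core of the neighbour branch, mirroring carotid lumen calibre relative
    to the constraint diameter.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.9)
    trunk_radius: float = 3.5
    branch_radii: tuple[float, float] = (2.0, 2.0)
    bifurcation_z: float = 14.0
    branch_angle: float = 40.0
    arc_radius: float = 8.0
    lumen_intensity: float = 100.0
    background_intensity: float = 40.0
    branch_contrast: tuple[float, float] = (1.0, 1.0)
    seq2_branch_contrast: tuple[float, float] | None = None
    noise_sd: float = 3.0
    rng_seed: int = 0
    delta: float = 0.1
    z_margin_bottom: float = 3.6
    z_margin_top: float = 2.7

    def __post_init__(self) -> None:
        if self.trunk_radius <= 0 or any(r <= 0 for r in self.branch_radii):
            raise ValueError("radii must be positive")
        if not (10.0 < self.branch_angle < 120.0):
            raise ValueError("branch_angle must lie in (10, 120) degrees")
        if any(not (0.0 < c <= 1.0) for c in self.branch_contrast):
            raise ValueError("branch_contrast components must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Analytic ground truth: two centerlines, seeds, and the generating spec.

    ``centerline_ICA``/``centerline_ECA`` run from the common seed to each
    branch end and share an identical prefix up to the bifurcation;
    ``seeds.x_BIF`` sits in the gap between the branches at the first axial
    slice where their lumen cross-sections are disjoint.
    """

    centerline_ICA: Centerline
    centerline_ECA: Centerline
    seeds: SeedSet
    spec: PhantomSpec


def _branch_geometry(spec: PhantomSpec):
    """Piecewise-analytic description shared by both branches.

    Returns (cx, cy, z0, z1, trunk_len, arc_len, theta) where theta is the
    half branch angle in radians.
    """
    nx, ny, nz = spec.volume_shape
    hx, hy, hz = spec.spacing
    cx, cy = 0.5 * (nx - 1) * hx, 0.5 * (ny - 1) * hy
    z0 = spec.z_margin_bottom
    z1 = (nz - 1) * hz - spec.z_margin_top
    theta = np.deg2rad(spec.branch_angle) / 2.0
    if not (z0 < spec.bifurcation_z < z1):
        raise ValueError("bifurcation_z must lie between the z margins")
    trunk_len = spec.bifurcation_z - z0
    arc_len = spec.arc_radius * theta
    arc_top = spec.bifurcation_z + spec.arc_radius * np.sin(theta)
    if arc_top >= z1:
        raise ValueError("arc leaves the volume; lower branch_angle or bifurcation_z")
    return cx, cy, z0, z1, trunk_len, arc_len, theta


def _branch_point(spec: PhantomSpec, sign: float, s):
    """World point(s) on one branch centerline at arc length(s) ``s`` from x_C."""
    cx, cy, z0, z1, trunk_len, arc_len, theta = _branch_geometry(spec)
    R = spec.arc_radius
    s = np.atleast_1d(np.asarray(s, dtype=float))
    x = np.full_like(s, cx)
    z = np.empty_like(s)
    in_trunk = s <= trunk_len
    z[in_trunk] = z0 + s[in_trunk]
    in_arc = (s > trunk_len) & (s <= trunk_len + arc_len)
    phi = (s[in_arc] - trunk_len) / R
    x[in_arc] = cx + sign * R * (1.0 - np.cos(phi))
    z[in_arc] = spec.bifurcation_z + R * np.sin(phi)
    beyond = s > trunk_len + arc_len
    t = s[beyond] - trunk_len - arc_len
    x[beyond] = cx + sign * (R * (1.0 - np.cos(theta)) + t * np.sin(theta))
    z[beyond] = spec.bifurcation_z + R * np.sin(theta) + t * np.cos(theta)
    return np.column_stack([x, np.full_like(s, cy), z])


def _branch_total_length(spec: PhantomSpec) -> float:
    _, _, z0, z1, trunk_len, arc_len, theta = _branch_geometry(spec)
    straight = (z1 - (spec.bifurcation_z + spec.arc_radius * np.sin(theta))) / np.cos(theta)
    return trunk_len + arc_len + straight


def _branch_radius_profile(spec: PhantomSpec, branch: int, s: np.ndarray) -> np.ndarray:
    """Tube radius along arc length: trunk radius tapering to branch radius
    across the arc section."""
    _, _, _, _, trunk_len, arc_len, _ = _branch_geometry(spec)
    r0, r1 = spec.trunk_radius, spec.branch_radii[branch]
    w = np.clip((s - trunk_len) / max(arc_len, 1e-9), 0.0, 1.0)
    return r0 + (r1 - r0) * w


def _axis_separation(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """Distance between the two branch axes at height z (0 below bifurcation)."""
    _, _, _, _, _, _, theta = _branch_geometry(spec)
    R = spec.arc_radius
    z = np.asarray(z, dtype=float)
    dz = z - spec.bifurcation_z
    sep = np.zeros_like(z)
    arc_dz = R * np.sin(theta)
    in_arc = (dz > 0) & (dz <= arc_dz)
    sep[in_arc] = 2.0 * R * (1.0 - np.sqrt(1.0 - (dz[in_arc] / R) ** 2))
    beyond = dz > arc_dz
    sep[beyond] = 2.0 * (
        R * (1.0 - np.cos(theta)) + (dz[beyond] - arc_dz) / np.cos(theta) * np.sin(theta)
    )
    return sep


def _render_sequence(
    spec: PhantomSpec,
    contrast: tuple[float, float],
    rng: np.random.Generator,
    dense_axes: list[np.ndarray],
    dense_radii: list[np.ndarray],
) -> Volume:
    nx, ny, nz = spec.volume_shape
    hx, hy, hz = spec.spacing
    xs = np.arange(nx) * hx
    ys = np.arange(ny) * hy
    zs = np.arange(nz) * hz
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    edge = max(hx, hy)  # 1-voxel smooth rim, in-plane voxel size
    data = np.full(nx * ny * nz, float(spec.background_intensity))
    contribution = np.zeros(nx * ny * nz)
    for b in range(2):
        dist, idx = cKDTree(dense_axes[b]).query(grid, workers=-1)
        r = dense_radii[b][idx]
        inner, outer = r - edge / 2.0, r + edge / 2.0
        f = np.clip((outer - dist) / edge, 0.0, 1.0)
        ramp = (dist > inner) & (dist < outer)
        f[ramp] = 0.5 * (1.0 + np.cos(np.pi * (dist[ramp] - inner[ramp]) / edge))
        amp = spec.lumen_intensity * contrast[b] - spec.background_intensity
        contribution = np.maximum(contribution, amp * f)
    data += contribution
    data = data.reshape(nx, ny, nz)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return Volume(data, spacing=spec.spacing)


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, PhantomTruth]:
    """Render the phantom into two pseudo-sequences plus ground truth.

    Deterministic given ``spec.rng_seed``; the second sequence differs by an
    independent noise draw (and optionally different branch contrast).
    """
    nx, ny, nz = spec.volume_shape
    hx, hy, hz = spec.spacing
    cx, cy, z0, z1, trunk_len, arc_len, theta = _branch_geometry(spec)
    total = _branch_total_length(spec)

    # bounds check: branch end plus radius must stay inside the grid
    for b, sign in enumerate((+1.0, -1.0)):
        end = _branch_point(spec, sign, total)[0]
        r = spec.branch_radii[b]
        if end[0] - r < 0 or end[0] + r > (nx - 1) * hx:
            raise ValueError("branch tube leaves the volume in x; shrink branch_angle")
        if cy - spec.trunk_radius < 0 or cy + spec.trunk_radius > (ny - 1) * hy:
            raise ValueError("tube leaves the volume in y")

    # analytic truth centerlines at delta spacing (ICA = +x branch)
    n_pts = int(np.floor(total / spec.delta)) + 1
    s = np.arange(n_pts) * spec.delta
    if total - s[-1] > 1e-9:
        s = np.concatenate((s, [total]))
    truth_ica = Centerline(_branch_point(spec, +1.0, s), spec.delta)
    truth_eca = Centerline(_branch_point(spec, -1.0, s), spec.delta)

    # bifurcation gap point: first axial voxel slice where the lumen
    # cross-sections are disjoint (axis separation above the summed radii)
    zs = np.arange(nz) * hz
    sep = _axis_separation(spec, zs)
    disjoint = sep > (spec.branch_radii[0] + spec.branch_radii[1])
    visible = disjoint & (zs <= z1)
    if not visible.any():
        raise ValueError("branches never separate inside the volume")
    k = int(np.argmax(visible))
    x_bif = np.array([cx, cy, zs[k]])

    seeds = SeedSet(
        x_C=truth_ica.points[0].copy(),
        x_I=truth_ica.points[-1].copy(),
        x_E=truth_eca.points[-1].copy(),
        x_BIF=x_bif,
    )

    # dense axis samples for rendering (finer than the voxel size)
    ds = 0.25 * min(hx, hy, hz)
    s_dense = np.arange(0.0, total + ds, ds)
    dense_axes = [_branch_point(spec, sign, s_dense) for sign in (+1.0, -1.0)]
    dense_radii = [_branch_radius_profile(spec, b, s_dense) for b in range(2)]

    rng = np.random.default_rng(spec.rng_seed)
    seq1 = _render_sequence(spec, spec.branch_contrast, rng, dense_axes, dense_radii)
    contrast2 = spec.seq2_branch_contrast or spec.branch_contrast
    seq2 = _render_sequence(spec, contrast2, rng, dense_axes, dense_radii)

    truth = PhantomTruth(truth_ica, truth_eca, seeds, spec)
    return seq1, seq2, truth


def faint_branch_preset() -> PhantomSpec:
    """Fixed phantom in which one branch has strongly reduced lumen contrast.

    The second (ECA-side) branch is rendered at 45% lumen contrast, leaving
    it barely above background under the noise: independently extracted
    minimum-cost paths for both branches then run up the bright branch and
    only cross over to the faint seed near the top of the volume.  A
    shallow branch angle keeps that crossover short relative to the shared
    stretch, and branch radii of 1.5 mm keep each branch lumen coverable by
    the default 1.75 mm constraint radius, as in the carotid geometry the
    constraint diameter was chosen for.  Pair with ``study_cost_params``
    so the medialness scales match the radii.
    """
    return PhantomSpec(
        volume_shape=(64, 64, 48),
        spacing=(0.5, 0.5, 0.9),
        trunk_radius=3.5,
        branch_radii=(1.5, 1.5),
        bifurcation_z=6.0,
        branch_angle=16.0,
        lumen_intensity=100.0,
        background_intensity=40.0,
        branch_contrast=(1.0, 0.45),
        noise_sd=7.0,
        rng_seed=1234,
    )


def study_cost_params(spec: PhantomSpec, omega: float = 1.0, **kwargs):
    """Cost parameters whose medialness scales cover the phantom's radii.

    Uses the smallest branch radius, the trunk radius, and their midpoint
    as the scale set; a mild smoothing of omega = 1 by default.
    """
    from .cost import CostParams

    r_lo = min(spec.branch_radii)
    r_hi = spec.trunk_radius
    scales = tuple(sorted({r_lo, 0.5 * (r_lo + r_hi), r_hi}))
    return CostParams(scales=scales, omega=omega, **kwargs)
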