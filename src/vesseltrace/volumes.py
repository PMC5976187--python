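"""Spatial primitives: scalar volumes, centerlines, and seed sets.

Conventions
-----------
* Voxel indices are 0-based with axis order ``(x, y, z)``; ``z`` is the
  axial (slice) direction.
* World coordinates are millimetres in the volume's native frame; the
  mapping is axis aligned: ``world(i, j, k) = origin + (i*hx, j*hy, k*hz)``.
  Rotated/oblique orientations are deliberately unsupported.
* Centerlines are ordered polylines of world-mm points with a nominal arc
  spacing ``step`` (the tracking step size, default 0.1 mm elsewhere).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as _FsPath

import nibabel as nib
import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Volume",
    "Centerline",
    "SeedSet",
    "read_volume",
    "write_volume",
    "read_seeds",
    "write_seeds",
    "read_path",
    "write_path",
    "resample_path",
    "path_length",
    "UnsupportedOrientationError",
    "SeedSchemaError",
]


class UnsupportedOrientationError(ValueError):
    """Raised for NIfTI affines that are not axis aligned with positive spacing."""


class SeedSchemaError(KeyError):
    """Raised when a seed/centerline JSON file violates the expected schema."""


@dataclass
class Volume:
    """A 3D scalar grid with anisotropic voxel spacing and a world origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; must be finite unless ``allow_infinite`` is set
        (action maps store ``+inf`` at never-reached voxels).
    spacing : tuple of float
        Voxel size ``(hx, hy, hz)`` in mm, all strictly positive.
    origin : tuple of float
        World-mm coordinate of voxel index ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    allow_infinite: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(h) for h in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(h <= 0 for h in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.allow_infinite:
            if np.isnan(self.data).any():
                raise ValueError("volume data contains NaN")
        elif not np.isfinite(self.data).all():
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, index) -> np.ndarray:
        """World-mm coordinate(s) of continuous voxel index/indices."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, point) -> np.ndarray:
        """Continuous voxel index of world-mm point(s); inverse of voxel_to_world.

        Out-of-bounds indices are returned as-is; callers check bounds.
        """
        pt = np.asarray(point, dtype=float)
        return (pt - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_voxel(self, point) -> tuple[int, int, int]:
        """Integer voxel containing a world point (nearest-centre rounding)."""
        idx = np.rint(self.world_to_voxel(point)).astype(int)
        return tuple(int(v) for v in idx)

    def contains_world(self, point) -> bool:
        """True if the world point lies inside the voxel index range."""
        idx = self.world_to_voxel(point)
        hi = np.asarray(self.shape) - 1
        return bool(np.all(idx >= -0.5) and np.all(idx <= hi + 0.5))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )


def read_volume(path) -> Volume:
    """Read a NIfTI-1 volume; only axis-aligned affines are accepted."""
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise UnsupportedOrientationError(
            "non-axis-aligned affine; rotated/oblique volumes are unsupported"
        )
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise UnsupportedOrientationError(
            "affine has non-positive diagonal (flipped axes unsupported)"
        )
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return Volume(data, spacing=tuple(diag), origin=tuple(affine[:3, 3]))


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), affine), str(path))


@dataclass
class Centerline:
    """Ordered polyline of world-mm points sampled at nominal arc spacing ``step``.

    Invariants: at least two points, consecutive spacing at most ``2*step``
    (up to rounding), strictly positive total arc length.
    """

    points: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must have shape (n, 3)")
        if self.points.shape[0] < 2:
            raise ValueError("a centerline needs at least two points")
        self.step = float(self.step)
        if self.step <= 0:
            raise ValueError("step must be positive")
        seg = self.segment_lengths()
        if seg.max() > 2.0 * self.step * (1.0 + 1e-6):
            raise ValueError(
                f"consecutive point spacing {seg.max():.4g} exceeds 2*step={2 * self.step:.4g}"
            )
        if seg.sum() <= 0:
            raise ValueError("centerline arc length must be positive")

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        return np.concatenate(([0.0], np.cumsum(self.segment_lengths())))

    def point_at_arc(self, s: float) -> np.ndarray:
        """Linear interpolation of the polyline at arc position ``s`` (mm)."""
        arc = self.arc_positions()
        s = float(np.clip(s, 0.0, arc[-1]))
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(i, len(arc) - 2)
        seg = arc[i + 1] - arc[i]
        w = 0.0 if seg == 0 else (s - arc[i]) / seg
        return (1 - w) * self.points[i] + w * self.points[i + 1]

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(), self.step)


def path_length(path) -> float:
    """Total arc length (mm): sum of consecutive Euclidean distances."""
    pts = path.points if isinstance(path, Centerline) else np.asarray(path, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class SeedSet:
    """Seed points of a carotid bifurcation in world mm.

    ``x_C``, ``x_I``, ``x_E`` mark the common, internal and external carotid;
    ``x_BIF`` the annotated gap point at the artery bifurcation. ``x_BIF_s``
    (shifted along the CCA->BIF path) and ``x_BIF_e`` (estimated centerline
    bifurcation) are derived quantities.
    """

    x_C: np.ndarray
    x_I: np.ndarray
    x_E: np.ndarray
    x_BIF: np.ndarray | None = None
    x_BIF_s: np.ndarray | None = None
    x_BIF_e: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("x_C", "x_I", "x_E", "x_BIF", "x_BIF_s", "x_BIF_e"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float).reshape(3)
                setattr(self, name, val)
        pts = [self.x_C, self.x_I, self.x_E]
        for a in range(3):
            for b in range(a + 1, 3):
                if np.allclose(pts[a], pts[b]):
                    raise ValueError("x_C, x_I, x_E must be pairwise distinct")

    def present_points(self) -> dict[str, np.ndarray]:
        out = {"x_C": self.x_C, "x_I": self.x_I, "x_E": self.x_E}
        for name in ("x_BIF", "x_BIF_s", "x_BIF_e"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out

    def validate_in(self, volume: Volume) -> None:
        """Raise if any present seed lies outside the volume bounds."""
        for name, pt in self.present_points().items():
            if not volume.contains_world(pt):
                raise ValueError(f"seed {name}={pt.tolist()} lies outside the volume")


_SEED_KEYS = {"CCA": "x_C", "ICA": "x_I", "ECA": "x_E"}


def read_seeds(path) -> SeedSet:
    """Read a JSON seed file with keys CCA/ICA/ECA and optional BIF."""
    with open(path) as fh:
        raw = json.load(fh)
    kwargs = {}
    for key, attr in _SEED_KEYS.items():
        if key not in raw:
            raise SeedSchemaError(f"seed file {path} is missing required key {key!r}")
        kwargs[attr] = np.asarray(raw[key], dtype=float)
    if "BIF" in raw:
        kwargs["x_BIF"] = np.asarray(raw["BIF"], dtype=float)
    return SeedSet(**kwargs)


def write_seeds(seeds: SeedSet, path) -> None:
    out = {key: getattr(seeds, attr).tolist() for key, attr in _SEED_KEYS.items()}
    if seeds.x_BIF is not None:
        out["BIF"] = seeds.x_BIF.tolist()
    _FsPath(path).write_text(json.dumps(out, indent=1))


def read_path(path) -> Centerline:
    """Read a JSON centerline file ({"points": [[x,y,z],...], "step": delta})."""
    with open(path) as fh:
        raw = json.load(fh)
    if "points" not in raw or "step" not in raw:
        raise SeedSchemaError(f"centerline file {path} needs 'points' and 'step'")
    return Centerline(np.asarray(raw["points"], dtype=float), float(raw["step"]))


def write_path(centerline: Centerline, path) -> None:
    out = {"step": centerline.step, "points": centerline.points.tolist()}
    _FsPath(path).write_text(json.dumps(out))


def resample_path(points, step: float) -> Centerline:
    """Resample a point list at uniform arc spacing on an interpolating spline.

    A cubic spline (not-a-knot ends) parameterised by chord length is fit
    through the input points (a straight segment for two points) and
    evaluated at arc positions ``0, step, 2*step, ...``; both endpoints are
    preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    # collapse exactly repeated consecutive points; the spline needs strictly
    # increasing parameters
    keep = np.concatenate(([True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12))
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise ValueError("need at least two distinct points to resample")
    if step <= 0:
        raise ValueError("step must be positive")
    chord = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))))
    if pts.shape[0] == 2:
        def evaluate(t):
            w = np.asarray(t, dtype=float)[:, None] / chord[-1]
            return (1 - w) * pts[0] + w * pts[1]
    else:
        spline = CubicSpline(chord, pts, axis=0, bc_type="not-a-knot")
        evaluate = spline
    # dense arc-length table, then inverse lookup at multiples of `step`
    n_dense = max(int(np.ceil(chord[-1] / (step / 10.0))), 2 * pts.shape[0]) + 1
    t_dense = np.linspace(0.0, chord[-1], n_dense)
    x_dense = evaluate(t_dense)
    arc = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(x_dense, axis=0), axis=1))))
    total = arc[-1]
    n_full = int(np.floor(total / step + 1e-9))
    targets = np.arange(n_full + 1) * step
    if total - targets[-1] > 1e-9:
        targets = np.concatenate((targets, [total]))
    # strictly increasing arc table for interpolation
    t_at = np.interp(targets, arc, t_dense)
    out = evaluate(t_at)
    out[0] = pts[0]
    out[-1] = pts[-1]
    return Centerline(out, step)
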