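"""Cooperative centerline extraction at a bifurcation.

After a bifurcation two independently extracted minimum-cost paths often
collapse onto the more clearly visible branch.  The cooperative correction
constrains each branch path away from its neighbour: a blocking region
(spherical dilation of radius rho around the neighbour path beyond the
bifurcation) is written into the cost at a high constant K, and the path
is recomputed.  The correction is a single pass: first the neighbour path
is corrected against the best (lowest average cost) path, then the best
path is recomputed against the corrected neighbour.

Four method variants are provided:

* ``SCIE``  - separate extraction, common to internal and external;
* ``SCBIE`` - separate extraction through the shifted bifurcation seed;
* ``CCIE``  - cooperative extraction, common to internal and external;
* ``CCBIE`` - cooperative extraction through the shifted bifurcation seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cost import CostImage
from .marching import ActionMap, afm, backtrack, solve_action_map
from .volumes import Centerline, SeedSet, Volume, path_length

__all__ = [
    "ConstraintRegion",
    "MethodResult",
    "METHODS",
    "average_path_cost",
    "select_best",
    "constraint_start",
    "build_constraint",
    "apply_constraint",
    "cooperative_pair",
    "shift_bifurcation",
    "estimate_bifurcation",
    "run_method",
    "InfeasibleConstraintError",
]

METHODS = ("SCIE", "SCBIE", "CCIE", "CCBIE")

DEFAULT_RHO = 1.75  # mm; constraint diameter 3.5 mm covers a branch lumen
DEFAULT_K_FACTOR = 1e3
DEFAULT_SHIFT_T = 5.1  # mm, shift of the gap point back along the CCA path


class InfeasibleConstraintError(RuntimeError):
    """Raised when a constraint region engulfs the target endpoint."""


@dataclass
class ConstraintRegion:
    """Blocking region kappa: voxels within rho (world mm) of a constrained
    path segment, to be assigned cost K.

    ``segment`` keeps the constrained path points (minus any within rho of
    an ``exclude`` point) so violation checks can be done in world space
    rather than on the voxelised mask.
    """

    mask: np.ndarray
    rho: float
    K: float
    start_point: np.ndarray
    segment: np.ndarray | None = None

    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class MethodResult:
    """Extracted centerline pair plus run diagnostics."""

    method: str
    centerline_ICA: Centerline
    centerline_ECA: Centerline
    diagnostics: dict = field(default_factory=dict)


def average_path_cost(action: ActionMap, path: Centerline) -> float:
    """Action at the path endpoint divided by the path length (cost per mm)."""
    end_voxel = action.U.nearest_voxel(path.points[-1])
    u = action.U.data[end_voxel]
    if not np.isfinite(u):
        raise ValueError("path endpoint voxel is not alive in the action map")
    return float(u) / path_length(path)


def select_best(
    path_a: Centerline, path_b: Centerline, action: ActionMap
) -> tuple[Centerline, Centerline]:
    """Order two candidate paths as (best, neighbour) by average cost.

    Ties break toward the first argument.
    """
    ca = average_path_cost(action, path_a)
    cb = average_path_cost(action, path_b)
    return (path_a, path_b) if ca <= cb else (path_b, path_a)


def constraint_start(path: Centerline, x_ref) -> int:
    """Index of the path point closest to x_ref (earliest index on ties)."""
    d = np.linalg.norm(path.points - np.asarray(x_ref, dtype=float), axis=1)
    return int(np.argmin(d))


def build_constraint(
    path: Centerline,
    start_index: int,
    rho: float,
    grid: Volume,
    K: float,
    exclude=(),
) -> ConstraintRegion:
    """Spherical dilation (radius rho, world mm) of the path from start_index.

    Voxels within rho of any ``exclude`` point are removed from the mask so
    shared seed/target points stay reachable.  With anisotropic spacing the
    ball is ellipsoidal in voxel units but spherical in physical space.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if not (0 <= start_index <= path.points.shape[0]):
        raise ValueError("start_index out of range")
    seg = path.points[start_index:]
    mask = np.zeros(grid.shape, dtype=bool)
    start_point = (
        path.points[min(start_index, path.points.shape[0] - 1)].copy()
        if path.points.shape[0]
        else None
    )
    if seg.shape[0] == 0:
        return ConstraintRegion(mask, rho, K, start_point, seg.copy())
    xs, ys, zs = grid.axes_mm()
    centers = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(seg).query(centers, workers=-1)
    mask = (dist <= rho).reshape(grid.shape)
    keep = np.ones(seg.shape[0], dtype=bool)
    for pt in exclude:
        d_ex = np.linalg.norm(centers - np.asarray(pt, dtype=float), axis=1)
        mask &= (d_ex > rho).reshape(grid.shape)
        keep &= np.linalg.norm(seg - np.asarray(pt, dtype=float), axis=1) > rho
    return ConstraintRegion(mask, rho, K, start_point, seg[keep].copy())


def apply_constraint(p_tilde: Volume, kappa: ConstraintRegion) -> Volume:
    """Masked replacement: p_N = K inside kappa, p_tilde elsewhere (exact)."""
    if kappa.mask.shape != p_tilde.shape:
        raise ValueError("constraint mask and cost volume live on different grids")
    out = p_tilde.data.copy()
    out[kappa.mask] = kappa.K
    return Volume(out, p_tilde.spacing, p_tilde.origin)


def _path_enters(kappa: ConstraintRegion, path: Centerline, grid: Volume) -> bool:
    """True if the path comes closer than rho (minus half a voxel diagonal
    of discretisation slack) to the constrained, non-excluded segment."""
    if kappa.segment is None or kappa.segment.shape[0] == 0:
        return False
    slack = 0.5 * float(np.linalg.norm(grid.spacing))
    d, _ = cKDTree(kappa.segment).query(path.points, workers=-1)
    return bool(d.min() < kappa.rho - slack)


def cooperative_pair(
    p_tilde: Volume,
    A,
    B,
    C,
    x_ref,
    rho: float = DEFAULT_RHO,
    K: float | None = None,
    delta: float = 0.1,
) -> tuple[Centerline, Centerline, dict]:
    """Cooperatively extract the paths A->B and A->C (single-pass correction).

    1. extract both paths on p_tilde (one marching run from A);
    2. pick the best path (lowest average cost);
    3. block a rho-tube around the best path from its point closest to
       x_ref, keeping the neighbour's endpoint reachable;
    4. recompute the neighbour path on the blocked cost;
    5. block a rho-tube around the corrected neighbour likewise;
    6. recompute the best path on that cost.

    Returns the corrected (path-to-B, path-to-C) pair plus diagnostics.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if K is None:
        K = DEFAULT_K_FACTOR * float(p_tilde.data.max())
    action = solve_action_map(p_tilde, A, [B, C])
    path_b = backtrack(action, B, delta)
    path_c = backtrack(action, C, delta)
    best, neigh = select_best(path_b, path_c, action)
    best_is_b = best is path_b
    n_end = neigh.points[-1]
    b_end = best.points[-1]

    def _blocked_afm(base_path, start_ref, target, other_end):
        kappa = build_constraint(
            base_path,
            constraint_start(base_path, start_ref),
            rho,
            p_tilde,
            K,
            exclude=[other_end],
        )
        t_vox = p_tilde.nearest_voxel(target)
        if kappa.mask[t_vox]:
            raise InfeasibleConstraintError(
                "constraint region engulfs the target endpoint"
            )
        p_n = apply_constraint(p_tilde, kappa)
        path, act = afm(p_n, A, target, delta)
        return path, act, kappa

    corr_neigh, act_n, kappa1 = _blocked_afm(best, x_ref, n_end, b_end)
    corr_best, act_b, kappa2 = _blocked_afm(corr_neigh, x_ref, b_end, n_end)

    diagnostics = {
        "avg_cost_B": average_path_cost(action, path_b),
        "avg_cost_C": average_path_cost(action, path_c),
        "best": "B" if best_is_b else "C",
        "kappa1_start": kappa1.start_point.tolist(),
        "kappa2_start": kappa2.start_point.tolist(),
        "neighbour_enters_kappa": _path_enters(kappa1, corr_neigh, p_tilde),
        "best_enters_kappa": _path_enters(kappa2, corr_best, p_tilde),
    }
    if best_is_b:
        return corr_best, corr_neigh, diagnostics
    return corr_neigh, corr_best, diagnostics


def shift_bifurcation(
    p_tilde: Volume, x_C, x_BIF, t: float = DEFAULT_SHIFT_T, delta: float = 0.1
) -> np.ndarray:
    """Shift the annotated gap point back along the CCA->BIF path by t mm.

    The path x_C -> x_BIF is extracted on p_tilde and the point at arc
    length (total - t) from x_C is returned; with t = 0 this is x_BIF
    itself.  The shift moves the seed inside the vessel at the centerline
    bifurcation.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    path, _ = afm(p_tilde, x_C, x_BIF, delta)
    total = path.length
    if t >= total:
        raise ValueError(f"shift t={t} exceeds the CCA->BIF path length {total:.3f}")
    return path.point_at_arc(total - t)


def estimate_bifurcation(
    c_ica: Centerline, c_eca: Centerline, tol: float = 1.0
) -> np.ndarray:
    """Estimated centerline bifurcation from two annotated centerlines.

    Walking each path from its distal end toward the common start, the
    first point whose distance to the *other* centerline drops below
    ``tol`` (default 1 mm) is found; the mean of the two points is
    returned.  Raises if the paths never converge below tol.
    """
    found = []
    for own, other in ((c_ica, c_eca), (c_eca, c_ica)):
        tree = cKDTree(other.points)
        d, _ = tree.query(own.points[::-1], workers=-1)
        hit = np.nonzero(d < tol)[0]
        if hit.size == 0:
            raise ValueError("centerlines never approach within tol; no bifurcation")
        found.append(own.points[::-1][hit[0]])
    return 0.5 * (found[0] + found[1])


def _concat(prefix: Centerline, branch: Centerline) -> Centerline:
    """Join two paths sharing prefix-end == branch-start, without duplication."""
    if np.linalg.norm(prefix.points[-1] - branch.points[0]) > 1e-6:
        raise ValueError("paths do not share a junction point")
    pts = np.vstack([prefix.points, branch.points[1:]])
    return Centerline(pts, min(prefix.step, branch.step))


def run_method(
    method: str,
    cost: CostImage,
    seeds: SeedSet,
    rho: float = DEFAULT_RHO,
    K_factor: float = DEFAULT_K_FACTOR,
    delta: float = 0.1,
    shift_t: float = DEFAULT_SHIFT_T,
) -> MethodResult:
    """Extract both branch centerlines with one of the four method variants.

    Returns centerlines from x_C to x_I and x_C to x_E.  The *BIE variants
    route both centerlines through the shifted bifurcation seed x_BIF_s
    (computed from x_BIF when not already present in ``seeds``); the
    cooperative variants require x_BIF as the constraint reference.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    p_tilde = cost.p_tilde
    seeds.validate_in(p_tilde)
    K = K_factor * float(p_tilde.data.max())
    diagnostics: dict = {"method": method, "K": K, "rho": rho, "delta": delta}

    needs_bif = method in ("SCBIE", "CCBIE", "CCIE")
    if needs_bif and seeds.x_BIF is None:
        raise ValueError(f"{method} requires the bifurcation gap point x_BIF")

    if method == "SCIE":
        action = solve_action_map(p_tilde, seeds.x_C, [seeds.x_I, seeds.x_E])
        ica = backtrack(action, seeds.x_I, delta)
        eca = backtrack(action, seeds.x_E, delta)
        diagnostics["avg_cost_ICA"] = average_path_cost(action, ica)
        diagnostics["avg_cost_ECA"] = average_path_cost(action, eca)
        return MethodResult(method, ica, eca, diagnostics)

    if method == "CCIE":
        ica, eca, diag = cooperative_pair(
            p_tilde, seeds.x_C, seeds.x_I, seeds.x_E, seeds.x_BIF, rho, K, delta
        )
        diagnostics.update(diag)
        return MethodResult(method, ica, eca, diagnostics)

    # variants routed through the shifted bifurcation seed
    x_bif_s = seeds.x_BIF_s
    if x_bif_s is None:
        x_bif_s = shift_bifurcation(p_tilde, seeds.x_C, seeds.x_BIF, shift_t, delta)
    diagnostics["x_BIF_s"] = np.asarray(x_bif_s).tolist()
    prefix, _ = afm(p_tilde, seeds.x_C, x_bif_s, delta)

    if method == "SCBIE":
        action = solve_action_map(p_tilde, x_bif_s, [seeds.x_I, seeds.x_E])
        ica = backtrack(action, seeds.x_I, delta)
        eca = backtrack(action, seeds.x_E, delta)
    else:  # CCBIE
        ica, eca, diag = cooperative_pair(
            p_tilde, x_bif_s, seeds.x_I, seeds.x_E, seeds.x_BIF, rho, K, delta
        )
        diagnostics.update(diag)
    return MethodResult(method, _concat(prefix, ica), _concat(prefix, eca), diagnostics)
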