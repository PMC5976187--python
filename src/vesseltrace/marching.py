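"""Eikonal solver on anisotropic voxel grids and geodesic backtracking.

The minimal action map U accumulates cost from a source point p0 and
satisfies ||grad U|| = p_tilde with U(p0) = 0.  It is discretised with the
first-order upwind scheme

    sum_i ( max{U(x) - U(x - d_i), U(x) - U(x + d_i), 0} / h_i )^2
        = p_tilde(x)^2

on the 6-connected grid with per-axis voxel sizes h_i, and solved by fast
marching (ALIVE / TRIAL / FAR front propagation with a min-heap).  The
minimum-cost path is then recovered by integrating the normalised descent
field -grad(U)/||grad U|| from the endpoint back to the source with a
fourth-order Runge-Kutta scheme at step size delta.

``local_update`` and ``gauss_seidel_action_map`` form a slow reference
solver for the same scheme: iterated sweeps converge to the same fixed
point as the one-pass fast marching, which the test suite exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.interpolate import RegularGridInterpolator

from .volumes import Centerline, Volume

__all__ = [
    "ActionMap",
    "local_update",
    "solve_action_map",
    "gauss_seidel_action_map",
    "normalized_gradient",
    "backtrack",
    "afm",
    "BacktrackError",
]

FAR, TRIAL, ALIVE = 0, 1, 2


class BacktrackError(RuntimeError):
    """Raised when gradient-descent backtracking fails to reach the source."""


@dataclass
class ActionMap:
    """Accumulated-cost map from a fast-marching run.

    ``U`` holds the frozen action values (+inf at voxels the front never
    reached), ``alive`` flags the frozen set, and ``source`` is the world
    point where U = 0.  ``reached_all`` is False when the front exhausted
    the grid before freezing every requested stop point.
    """

    U: Volume
    alive: np.ndarray
    source: np.ndarray
    reached_all: bool = True

    @property
    def grid(self) -> Volume:
        return self.U

    def interpolate(self, points) -> np.ndarray:
        """Trilinear interpolation of U at world points.

        Non-alive voxels contribute the maximum finite action value, which
        can only overestimate near the front; used for monotonicity checks.
        """
        u = self.U.data
        finite = u[np.isfinite(u)]
        filled = np.where(np.isfinite(u), u, finite.max() if finite.size else 0.0)
        interp = RegularGridInterpolator(
            self.U.axes_mm(), filled, bounds_error=False, fill_value=None
        )
        return interp(np.atleast_2d(np.asarray(points, dtype=float)))


def local_update(neighbor_values, cost: float, spacing) -> float:
    """Smallest U satisfying the upwind quadratic at one voxel.

    ``neighbor_values`` holds one (U_minus, U_plus) pair per axis (entries
    may be +inf); per axis the smaller of the pair enters the stencil.  The
    finite per-axis values are sorted ascending and the quadratic is solved
    over the largest prefix whose solution exceeds every included value
    (upwind causality).  Pure-Python reference shared by the Gauss-Seidel
    sweeping solver.
    """
    if cost <= 0:
        raise ValueError("cost must be positive")
    a = sorted(
        (min(pair), h)
        for pair, h in zip(neighbor_values, spacing)
        if math.isfinite(min(pair))
    )
    if not a:
        raise ValueError("at least one finite neighbour value is required")
    s1 = s2 = s3 = 0.0
    best = math.inf
    for m, (am, hm) in enumerate(a):
        w = 1.0 / (hm * hm)
        s1 += w
        s2 += am * w
        s3 += am * am * w
        disc = s2 * s2 - s1 * (s3 - cost * cost)
        if disc < 0:
            break  # adding this axis is not causally consistent; keep prefix
        cand = (s2 + math.sqrt(disc)) / s1
        best = cand
        if m + 1 < len(a) and cand > a[m + 1][0]:
            continue  # next neighbour is also upwind; include it
        break
    return best


@njit(cache=False)
def _solve_quadratic(a0, a1, a2, h0, h1, h2, cost):
    # sort three (value, spacing) pairs by value (insertion sort, n = 3)
    av = np.array([a0, a1, a2])
    hv = np.array([h0, h1, h2])
    for i in range(1, 3):
        va, vh = av[i], hv[i]
        j = i - 1
        while j >= 0 and av[j] > va:
            av[j + 1] = av[j]
            hv[j + 1] = hv[j]
            j -= 1
        av[j + 1] = va
        hv[j + 1] = vh
    s1 = 0.0
    s2 = 0.0
    s3 = 0.0
    best = np.inf
    for m in range(3):
        if not np.isfinite(av[m]):
            break
        w = 1.0 / (hv[m] * hv[m])
        s1 += w
        s2 += av[m] * w
        s3 += av[m] * av[m] * w
        disc = s2 * s2 - s1 * (s3 - cost * cost)
        if disc < 0.0:
            break
        cand = (s2 + np.sqrt(disc)) / s1
        best = cand
        if m + 1 < 3 and np.isfinite(av[m + 1]) and cand > av[m + 1]:
            continue
        break
    return best


@njit(cache=False)
def _march_kernel(cost, hx, hy, hz, init_flat, init_u, stops, slack):
    """Fast marching with a binary min-heap and lazy deletion.

    ``init_flat``/``init_u`` seed the front (the source voxel at U = 0 plus
    a small exactly-initialised ball that removes the point-source
    singularity of the first-order scheme).  ``stops`` is an (n, 3) int64
    array of voxels whose freezing terminates the run (after an extra
    ``slack`` of action so the front forms a shell around them, which
    stabilises gradient interpolation at the endpoint); with n = 0 the
    whole grid is solved.  Returns (U, state, stops_left).
    """
    nx, ny, nz = cost.shape
    n = nx * ny * nz
    U = np.full(n, np.inf)
    state = np.zeros(n, dtype=np.uint8)
    locked = np.zeros(n, dtype=np.uint8)  # exactly-initialised ball: not relaxable
    sx, sy, sz = ny * nz, nz, 1

    cap = 7 * n + 2 * init_flat.size + 64
    heap_u = np.empty(cap)
    heap_i = np.empty(cap, dtype=np.int64)
    hn = 0

    for q in range(init_flat.size):
        v0 = init_flat[q]
        U[v0] = init_u[q]
        locked[v0] = 1
        heap_u[hn] = init_u[q]
        heap_i[hn] = v0
        pos = hn
        hn += 1
        while pos > 0:
            par = (pos - 1) // 2
            if heap_u[par] > heap_u[pos]:
                tu = heap_u[pos]
                ti = heap_i[pos]
                heap_u[pos] = heap_u[par]
                heap_i[pos] = heap_i[par]
                heap_u[par] = tu
                heap_i[par] = ti
                pos = par
            else:
                break

    n_stops = stops.shape[0]
    stop_flat = np.empty(n_stops, dtype=np.int64)
    for q in range(n_stops):
        stop_flat[q] = stops[q, 0] * sx + stops[q, 1] * sy + stops[q, 2] * sz
    stops_left = n_stops
    threshold = np.inf
    limiting = n_stops > 0

    while hn > 0:
        # pop min
        u = heap_u[0]
        v = heap_i[0]
        hn -= 1
        heap_u[0] = heap_u[hn]
        heap_i[0] = heap_i[hn]
        pos = 0
        while True:
            left = 2 * pos + 1
            if left >= hn:
                break
            small = left
            right = left + 1
            if right < hn and heap_u[right] < heap_u[left]:
                small = right
            if heap_u[small] < heap_u[pos]:
                tu = heap_u[pos]
                ti = heap_i[pos]
                heap_u[pos] = heap_u[small]
                heap_i[pos] = heap_i[small]
                heap_u[small] = tu
                heap_i[small] = ti
                pos = small
            else:
                break
        if state[v] == 2 or u > U[v]:
            continue  # stale entry
        state[v] = 2
        if limiting:
            if u > threshold:
                state[v] = 1  # un-freeze: past the stop shell
                break
            if stops_left > 0:
                for q in range(n_stops):
                    if stop_flat[q] == v:
                        stops_left -= 1
                        break
                if stops_left == 0:
                    threshold = u + slack

        i = v // sx
        j = (v - i * sx) // sy
        k = v - i * sx - j * sy
        for axis in range(3):
            for d in (-1, 1):
                ni, nj, nk = i, j, k
                if axis == 0:
                    ni += d
                elif axis == 1:
                    nj += d
                else:
                    nk += d
                if ni < 0 or ni >= nx or nj < 0 or nj >= ny or nk < 0 or nk >= nz:
                    continue
                w = ni * sx + nj * sy + nk * sz
                if state[w] == 2 or locked[w] == 1:
                    continue
                # per-axis minimum over ALIVE neighbours of w
                a0 = np.inf
                a1 = np.inf
                a2 = np.inf
                if ni > 0 and state[w - sx] == 2:
                    a0 = U[w - sx]
                if ni < nx - 1 and state[w + sx] == 2 and U[w + sx] < a0:
                    a0 = U[w + sx]
                if nj > 0 and state[w - sy] == 2:
                    a1 = U[w - sy]
                if nj < ny - 1 and state[w + sy] == 2 and U[w + sy] < a1:
                    a1 = U[w + sy]
                if nk > 0 and state[w - sz] == 2:
                    a2 = U[w - sz]
                if nk < nz - 1 and state[w + sz] == 2 and U[w + sz] < a2:
                    a2 = U[w + sz]
                unew = _solve_quadratic(a0, a1, a2, hx, hy, hz, cost[ni, nj, nk])
                if unew < U[w]:
                    U[w] = unew
                    state[w] = 1
                    # push (lazy decrease-key)
                    heap_u[hn] = unew
                    heap_i[hn] = w
                    pos = hn
                    hn += 1
                    while pos > 0:
                        par = (pos - 1) // 2
                        if heap_u[par] > heap_u[pos]:
                            tu = heap_u[pos]
                            ti = heap_i[pos]
                            heap_u[pos] = heap_u[par]
                            heap_i[pos] = heap_i[par]
                            heap_u[par] = tu
                            heap_i[par] = ti
                            pos = par
                        else:
                            break

    return U.reshape(cost.shape), state.reshape(cost.shape), stops_left


def _source_ball(p_tilde: Volume, p0: np.ndarray, src: tuple[int, int, int]):
    """Flat indices and exact action values of a small ball around the source.

    Within ``3 * max(spacing)`` of the source the action is initialised to
    ``cost(source) * distance`` (exact for locally uniform cost), which
    removes the first-order point-source error.  The source voxel itself
    gets U = 0 and comes first.
    """
    radius = 3.0 * max(p_tilde.spacing)
    nx, ny, nz = p_tilde.shape
    hx, hy, hz = p_tilde.spacing
    r_vox = np.array([radius / hx, radius / hy, radius / hz])
    lo = np.maximum(np.floor(np.asarray(src) - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(src) + r_vox).astype(int), np.array([nx, ny, nz]) - 1)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    centers = p_tilde.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    dist = np.linalg.norm(centers - p0, axis=1)
    keep = dist <= radius
    idx = (ii.ravel() * ny * nz + jj.ravel() * nz + kk.ravel())[keep]
    c_src = float(p_tilde.data[src])
    vals = c_src * dist[keep]
    src_flat = src[0] * ny * nz + src[1] * nz + src[2]
    vals[idx == src_flat] = 0.0
    order = np.argsort(vals, kind="stable")
    return idx[order].astype(np.int64), vals[order]


def _voxel_of(volume: Volume, point, name: str) -> tuple[int, int, int]:
    idx = volume.nearest_voxel(point)
    for a in range(3):
        if not (0 <= idx[a] < volume.shape[a]):
            raise ValueError(f"{name} {np.asarray(point).tolist()} lies outside the grid")
    return idx


def solve_action_map(p_tilde: Volume, p0, stop_points=()) -> ActionMap:
    """Fast-marching solution of the Eikonal equation for source p0.

    Propagation stops once the voxels of all ``stop_points`` are frozen
    (plus a small shell of extra front so gradients are defined around
    them); with no stop points the whole grid is solved.  U is +inf outside
    the frozen set.
    """
    cost = np.ascontiguousarray(p_tilde.data, dtype=float)
    if not np.all(cost > 0):
        raise ValueError("p_tilde must be strictly positive everywhere")
    p0 = np.asarray(p0, dtype=float)
    src = np.array(_voxel_of(p_tilde, p0, "source"), dtype=np.int64)
    stops = np.array(
        [_voxel_of(p_tilde, q, "stop point") for q in stop_points], dtype=np.int64
    ).reshape(-1, 3)
    if stops.shape[0] > 1:
        stops = np.unique(stops, axis=0)  # kernel counts distinct stop voxels
    if stops.shape[0] > 0:
        # extra action so a few voxel layers freeze beyond the stop points
        local = max(float(cost[tuple(s)]) for s in stops)
        slack = 3.0 * max(p_tilde.spacing) * local
    else:
        slack = 0.0
    init_flat, init_u = _source_ball(p_tilde, p0, tuple(int(s) for s in src))
    U, state, stops_left = _march_kernel(
        cost, *(float(h) for h in p_tilde.spacing), init_flat, init_u, stops, slack
    )
    alive = state == ALIVE
    U = np.where(alive, U, np.inf)
    return ActionMap(
        U=Volume(U, p_tilde.spacing, p_tilde.origin, allow_infinite=True),
        alive=alive,
        source=p0,
        reached_all=(stops_left == 0),
    )


def gauss_seidel_action_map(
    p_tilde: Volume, p0, tol: float = 1e-12, max_rounds: int = 2000
) -> ActionMap:
    """Reference Eikonal solver: alternating-direction Gauss-Seidel sweeps.

    Repeatedly applies ``local_update`` in the eight axis orderings until no
    value changes by more than ``tol``.  Slow (pure Python) but independent
    of the marching order; intended for small grids and as a test oracle.
    Uses the same exactly-initialised source ball as the marching solver,
    held fixed during the sweeps, so both converge to the same fixed point.
    """
    cost = np.asarray(p_tilde.data, dtype=float)
    if not np.all(cost > 0):
        raise ValueError("p_tilde must be strictly positive everywhere")
    nx, ny, nz = cost.shape
    h = p_tilde.spacing
    src = _voxel_of(p_tilde, p0, "source")
    U = np.full(cost.shape, np.inf)
    init_flat, init_u = _source_ball(p_tilde, np.asarray(p0, dtype=float), src)
    frozen = np.zeros(cost.shape, dtype=bool)
    for flat, val in zip(init_flat, init_u):
        ijk = np.unravel_index(int(flat), cost.shape)
        U[ijk] = val
        frozen[ijk] = True
    U[src] = 0.0
    ranges = [range(nx), range(ny), range(nz)]
    for rnd in range(max_rounds):
        delta = 0.0
        for dx in (1, -1):
            for dy in (1, -1):
                for dz in (1, -1):
                    for i in ranges[0][::dx]:
                        for j in ranges[1][::dy]:
                            for k in ranges[2][::dz]:
                                if frozen[i, j, k]:
                                    continue
                                pairs = (
                                    (
                                        U[i - 1, j, k] if i > 0 else np.inf,
                                        U[i + 1, j, k] if i < nx - 1 else np.inf,
                                    ),
                                    (
                                        U[i, j - 1, k] if j > 0 else np.inf,
                                        U[i, j + 1, k] if j < ny - 1 else np.inf,
                                    ),
                                    (
                                        U[i, j, k - 1] if k > 0 else np.inf,
                                        U[i, j, k + 1] if k < nz - 1 else np.inf,
                                    ),
                                )
                                if all(not math.isfinite(min(p)) for p in pairs):
                                    continue
                                unew = local_update(pairs, cost[i, j, k], h)
                                if unew < U[i, j, k]:
                                    change = (
                                        U[i, j, k] - unew
                                        if math.isfinite(U[i, j, k])
                                        else np.inf
                                    )
                                    delta = max(delta, change)
                                    U[i, j, k] = unew
        if delta <= tol:
            break
    alive = np.isfinite(U)
    return ActionMap(
        U=Volume(U, p_tilde.spacing, p_tilde.origin, allow_infinite=True),
        alive=alive,
        source=np.asarray(p0, dtype=float),
    )


def normalized_gradient(action: ActionMap) -> np.ndarray:
    """Unit-norm gradient field of U, shape (nx, ny, nz, 3).

    Central differences where both axis neighbours are alive, one-sided
    where only one is; exactly zero at non-alive voxels and at the source
    voxel, so those positions do not steer the tracking.
    """
    U = action.U.data
    alive = action.alive
    h = action.U.spacing
    grad = np.zeros(U.shape + (3,))
    Us = np.where(alive, U, 0.0)
    for axis in range(3):
        fwd_ok = np.zeros_like(alive)
        bwd_ok = np.zeros_like(alive)
        sl_f = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_f[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        fwd_ok[tuple(sl_f)] = alive[tuple(sl_b)]
        bwd_ok[tuple(sl_b)] = alive[tuple(sl_f)]
        u_fwd = np.zeros_like(U)
        u_bwd = np.zeros_like(U)
        u_fwd[tuple(sl_f)] = Us[tuple(sl_b)]
        u_bwd[tuple(sl_b)] = Us[tuple(sl_f)]
        d = np.zeros_like(U)
        both = fwd_ok & bwd_ok
        d[both] = (u_fwd[both] - u_bwd[both]) / (2.0 * h[axis])
        only_f = fwd_ok & ~bwd_ok
        d[only_f] = (u_fwd[only_f] - Us[only_f]) / h[axis]
        only_b = bwd_ok & ~fwd_ok
        d[only_b] = (Us[only_b] - u_bwd[only_b]) / h[axis]
        grad[..., axis] = d
    grad[~alive] = 0.0
    grad[action.U.nearest_voxel(action.source)] = 0.0
    norm = np.linalg.norm(grad, axis=-1)
    nz = norm > 0
    grad[nz] /= norm[nz][..., None]
    return grad


def backtrack(action: ActionMap, p1, delta: float = 0.1, max_steps: int | None = None) -> Centerline:
    """Integrate -grad(U)_N from p1 back to the source with RK4 at step delta.

    The integration stops once within max(delta, min voxel size) of the
    source, after which the source point is appended (the final jump is
    subdivided at delta so the arc-spacing contract holds).  An RK4 step is
    accepted only if the interpolated action does not increase; otherwise a
    discrete descent step to the lowest-action alive neighbour voxel is
    taken (this handles shocks where fronts wrapping around a blocking
    region collide and the interpolated field degenerates).  Raises
    BacktrackError if the step limit is exhausted or no descent exists.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    p1 = np.asarray(p1, dtype=float)
    vol = action.U
    v1 = _voxel_of(vol, p1, "endpoint")
    if not action.alive[v1]:
        raise ValueError("endpoint voxel was never reached by the front (not alive)")
    field = normalized_gradient(action)
    interp = RegularGridInterpolator(
        vol.axes_mm(), field, bounds_error=False, fill_value=None
    )
    U = vol.data
    finite_max = U[action.alive].max() if action.alive.any() else 0.0
    u_filled = np.where(action.alive, U, finite_max)
    u_interp = RegularGridInterpolator(
        vol.axes_mm(), u_filled, bounds_error=False, fill_value=None
    )
    lo = np.asarray(vol.origin)
    hi = vol.voxel_to_world(np.asarray(vol.shape) - 1)
    shape = np.asarray(vol.shape)

    def velocity(x):
        v = interp(np.clip(x, lo, hi)[None])[0]
        n = np.linalg.norm(v)
        return v / n if n > 1e-12 else np.zeros(3)

    def u_at(x):
        return float(u_interp(np.clip(x, lo, hi)[None])[0])

    def discrete_step(x):
        """Step to the lowest-U alive voxel in the 26-neighbourhood."""
        v = np.clip(np.rint(vol.world_to_voxel(x)).astype(int), 0, shape - 1)
        best_u = U[tuple(v)] if action.alive[tuple(v)] else np.inf
        best_v = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    w = v + np.array([di, dj, dk])
                    if np.any(w < 0) or np.any(w >= shape):
                        continue
                    tw = tuple(w)
                    if action.alive[tw] and U[tw] < best_u:
                        best_u = U[tw]
                        best_v = w
        if best_v is None:
            raise BacktrackError("no descending alive neighbour; descent is stuck")
        return vol.voxel_to_world(best_v)

    p0 = np.asarray(action.source, dtype=float)
    stop_r = max(delta, min(vol.spacing))
    extent = vol.voxel_to_world(np.asarray(vol.shape) - 1) - np.asarray(vol.origin)
    if max_steps is None:
        max_steps = int(10.0 * float(np.linalg.norm(extent)) / delta) + 10
    pts = [p1.copy()]
    x = p1.copy()
    u_cur = u_at(x)
    for _ in range(max_steps):
        if np.linalg.norm(x - p0) <= stop_r:
            break
        x_new = None
        k1 = velocity(x)
        if k1.any():
            k2 = velocity(x - 0.5 * delta * k1)
            k3 = velocity(x - 0.5 * delta * k2)
            k4 = velocity(x - delta * k3)
            cand = x - (delta / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if u_at(cand) <= u_cur + 1e-9:
                x_new = cand
        if x_new is None:
            if np.linalg.norm(x - p0) <= 2.0 * stop_r:
                break
            target = discrete_step(x)
            gap = np.linalg.norm(target - x)
            n_sub = max(int(np.ceil(gap / delta)), 1)
            for q in range(1, n_sub):
                pts.append(x + (target - x) * (q / n_sub))
            x_new = target
        x = x_new
        u_cur = u_at(x)
        pts.append(x.copy())
    else:
        raise BacktrackError("backtracking exhausted the step limit (divergent field)")
    # subdivide the final jump onto p0 so consecutive spacing stays <= delta
    gap = np.linalg.norm(pts[-1] - p0)
    if gap > 1e-12:
        n_sub = int(np.ceil(gap / delta))
        for q in range(1, n_sub):
            pts.append(pts[-1] + (p0 - pts[-1]) * (1.0 / (n_sub - q + 1)))
    pts.append(p0.copy())
    pts = np.asarray(pts[::-1])
    return Centerline(pts, delta)


def afm(p_tilde: Volume, p0, p1, delta: float = 0.1) -> tuple[Centerline, ActionMap]:
    """Minimum-cost path between p0 and p1 on cost p_tilde.

    Composition of ``solve_action_map`` and ``backtrack``; the action map is
    returned as well so callers can compute average path costs.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.linalg.norm(p1 - p0) < 1e-9:
        raise ValueError("p0 and p1 coincide; the path is degenerate")
    action = solve_action_map(p_tilde, p0, [p1])
    path = backtrack(action, p1, delta)
    return path, action
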