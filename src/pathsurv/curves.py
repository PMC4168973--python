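"""Hastie-Stuetzle principal curves by iterated local-average smoothing.

A principal curve is a smooth one-dimensional curve that passes through the
middle of a point cloud: every curve point is the conditional mean of the data
projecting onto it.  The classic fitting loop alternates (a) orthogonal
projection of the data onto the current polyline, (b) coordinate-wise
scatterplot smoothing of each dimension against the projection parameter, and
(c) arc-length reparameterization, starting from the first principal-component
segment.  The curve is represented as an ordered polyline with cumulative
arc-length node parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PrincipalCurve", "fit_principal_curve", "project_to_curve"]


class DegenerateInputError(ValueError):
    """Raised when the point cloud cannot support a curve fit."""


@dataclass
class PrincipalCurve:
    """An ordered polyline f(lambda) with arc-length node parameters.

    ``nodes`` is (m, d); ``node_params`` is the non-decreasing cumulative
    polyline length with node_params[0] == 0.  ``sq_dist_trace`` records the
    total squared orthogonal distance after each accepted iteration.
    """

    nodes: np.ndarray
    node_params: np.ndarray
    total_sq_dist: float
    converged: bool
    n_iterations: int
    sq_dist_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.node_params = np.asarray(self.node_params, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[0] != self.node_params.shape[0]:
            raise ValueError("nodes and node_params must align")
        if np.any(np.diff(self.node_params) < -1e-12) or abs(self.node_params[0]) > 1e-12:
            raise ValueError("node_params must be non-decreasing from 0")

    @property
    def length(self) -> float:
        return float(self.node_params[-1])

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]


def _arc_length_params(nodes: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def project_to_curve(points: np.ndarray, curve: PrincipalCurve) -> tuple[np.ndarray, np.ndarray]:
    """Project points orthogonally onto the polyline.

    Returns per point the arc-length parameter lambda of the nearest curve
    location (minimized over all segments, endpoints clamped) and the
    Euclidean distance to it.
    """
    nodes = curve.nodes
    if nodes.size == 0:
        raise ValueError("cannot project onto an empty curve")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != curve.dim:
        raise ValueError(f"point dimension {pts.shape[1]} != curve dimension {curve.dim}")
    if nodes.shape[0] == 1:
        dist = np.linalg.norm(pts - nodes[0], axis=1)
        return np.zeros(len(pts)), dist

    a = nodes[:-1]                       # (m, d) segment starts
    ab = nodes[1:] - a                   # (m, d)
    seg_len2 = np.einsum("md,md->m", ab, ab)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1.0)  # zero-length segments collapse to endpoint
    # (n, m) fractional position of the foot of the perpendicular on each segment
    ap = pts[:, None, :] - a[None, :, :]
    t = np.einsum("nmd,md->nm", ap, ab) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = np.einsum("nmd,nmd->nm", pts[:, None, :] - foot, pts[:, None, :] - foot)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(pts))
    lam = curve.node_params[best] + t[idx, best] * np.sqrt(seg_len2[best])
    dist = np.sqrt(d2[idx, best])
    return lam, dist


def _local_average_smooth(order: np.ndarray, values: np.ndarray, span: float) -> np.ndarray:
    """Running-mean smoother over a rank window of fractional width ``span``.

    ``order`` gives the positions of the points sorted by lambda; the smoothed
    value at rank i is the mean of values whose ranks fall within the centered
    window of ``max(2, round(span * n))`` points.
    """
    n = len(values)
    k = max(2, int(round(span * n)))
    half = k // 2
    v = values[order]
    csum = np.concatenate([[0.0], np.cumsum(v)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def fit_principal_curve(
    points: np.ndarray,
    span: float = 0.3,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> PrincipalCurve:
    """Fit a principal curve to an (n, d) point cloud.

    Initializes on the first principal-component segment, then alternates
    projection, per-dimension local-average smoothing against lambda, and
    arc-length reparameterization until the relative change of the total
    squared orthogonal distance falls below ``tol`` (or ``max_iter``).  An
    iteration that would increase the total squared distance is rejected and
    the loop stops, so the recorded distance trace is non-increasing.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 3:
        raise DegenerateInputError(f"need >= 3 distinct points, got {distinct.shape[0]}")
    if np.allclose(pts.std(axis=0), 0):
        raise DegenerateInputError("zero-variance point cloud")

    n, d = pts.shape
    center = pts.mean(axis=0)
    # first-PC initialization: nodes are the projections onto the PC1 line
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    pc1 = vt[0]
    lam0 = (pts - center) @ pc1
    order = np.argsort(lam0, kind="stable")
    nodes = center + np.outer(lam0[order], pc1)
    curve = PrincipalCurve(nodes, _arc_length_params(nodes), np.inf, False, 0)

    lam, dist = project_to_curve(pts, curve)
    total = float(np.sum(dist**2))
    trace = [total]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        order = np.argsort(lam, kind="stable")
        new_nodes = np.column_stack(
            [_local_average_smooth(order, pts[:, j], span) for j in range(d)]
        )
        new_curve = PrincipalCurve(new_nodes, _arc_length_params(new_nodes), np.inf, False, 0)
        new_lam, new_dist = project_to_curve(pts, new_curve)
        new_total = float(np.sum(new_dist**2))
        if new_total > total:           # reject non-improving step, keep last curve
            converged = True
            n_iter -= 1
            break
        rel_change = abs(total - new_total) / max(total, 1e-300)
        curve, lam, total = new_curve, new_lam, new_total
        trace.append(total)
        if rel_change < tol:
            converged = True
            break

    return PrincipalCurve(
        nodes=curve.nodes,
        node_params=curve.node_params,
        total_sq_dist=total,
        converged=converged,
        n_iterations=n_iter,
        sq_dist_trace=trace,
    )
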