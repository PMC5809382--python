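"""Thin-plate-spline warps between mean shapes.

A TPS warp is the smoothest (minimum bending energy) deformation of the
plane taking one point configuration onto another, with kernel
``U(r) = r^2 log r``.  Outlines enter as pseudo-landmark sets: after
equal-arc-length resampling, point ``i`` of the source corresponds to
point ``i`` of the target.  The warp is visualised as a deformation
grid (a regular grid mapped through the warp) and an iso-deformation
scalar field (per-node displacement magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TpsError(ValueError):
    """Raised for degenerate source configurations."""


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, evaluated from squared distances; U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)  # r^2 log r = r^2 * 0.5 * log r^2
    out[~np.isfinite(out)] = 0.0
    return out


@dataclass
class TpsWarp:
    """Fitted thin-plate-spline deformation of the plane."""

    source: np.ndarray = field(repr=False)
    target: np.ndarray = field(repr=False)
    affine: np.ndarray = field(repr=False)  # (3, 2): rows = const, x, y
    weights: np.ndarray = field(repr=False)  # (n, 2) non-affine kernel weights
    bending_energy: float = 0.0
    regularization: float = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map arbitrary points through the warp."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.source[None, :, :]) ** 2).sum(axis=2)
        K = _kernel(d2)
        P = np.column_stack([np.ones(len(pts)), pts])
        return P @ self.affine + K @ self.weights


def fit_tps(
    source: np.ndarray,
    target: np.ndarray,
    regularization: float = 0.0,
) -> TpsWarp:
    """Solve the TPS interpolation (or, with ridge, approximation) system.

    With ``regularization == 0`` the warp interpolates exactly:
    ``warp(source_i) == target_i``.  The bending energy is
    ``trace(W' K W)``, zero iff the mapping is affine.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise TpsError("source and target must be matching (n, 2) arrays")
    n = len(src)
    if n < 3:
        raise TpsError("need at least 3 correspondences")
    if regularization < 0:
        raise TpsError("regularization must be >= 0")
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    if np.any(d2[~np.eye(n, dtype=bool)] == 0.0):
        raise TpsError("duplicate source points")
    # collinearity check: rank of [1 | x | y]
    P = np.column_stack([np.ones(n), src])
    if np.linalg.matrix_rank(P) < 3:
        raise TpsError("collinear source points: affine part underdetermined")

    K = _kernel(d2) + regularization * np.eye(n)
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    sol = np.linalg.solve(L, rhs)
    W, A = sol[:n], sol[n:]
    # bending energy with the pure kernel (no ridge term)
    bend = float(np.trace(W.T @ _kernel(d2) @ W))
    return TpsWarp(
        source=src,
        target=tgt,
        affine=A,
        weights=W,
        bending_energy=max(bend, 0.0),
        regularization=regularization,
    )


@dataclass
class DeformationField:
    """Regular grid mapped through a warp plus displacement magnitudes."""

    grid_x: np.ndarray = field(repr=False)  # (ny, nx) source grid
    grid_y: np.ndarray = field(repr=False)
    warped_x: np.ndarray = field(repr=False)
    warped_y: np.ndarray = field(repr=False)
    magnitude: np.ndarray = field(repr=False)  # per-node displacement


def deformation_field(
    warp: TpsWarp,
    bounds: tuple[float, float, float, float] | None = None,
    spacing: float | None = None,
    n_cells: int = 24,
) -> DeformationField:
    """Map a regular grid through the warp.

    ``bounds`` is ``(xmin, xmax, ymin, ymax)``; by default the source
    point bounding box padded by 10%.  The scalar field is the Euclidean
    displacement per node, ready for contouring as iso-deformation
    lines.
    """
    if bounds is None:
        lo = warp.source.min(axis=0)
        hi = warp.source.max(axis=0)
        pad = 0.1 * (hi - lo)
        bounds = (lo[0] - pad[0], hi[0] + pad[0], lo[1] - pad[1], hi[1] + pad[1])
    xmin, xmax, ymin, ymax = bounds
    if spacing is not None:
        xs = np.arange(xmin, xmax + spacing / 2, spacing)
        ys = np.arange(ymin, ymax + spacing / 2, spacing)
    else:
        xs = np.linspace(xmin, xmax, n_cells + 1)
        ys = np.linspace(ymin, ymax, n_cells + 1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    warped = warp(pts)
    wx = warped[:, 0].reshape(gx.shape)
    wy = warped[:, 1].reshape(gy.shape)
    mag = np.hypot(wx - gx, wy - gy)
    return DeformationField(gx, gy, wx, wy, mag)
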