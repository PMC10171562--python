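"""Sphere geometry for square-root-transformed compositional data.

A 3-part composition ``c = (c1, c2, c3)`` (nonnegative, summing to 1 — here
the tissue proportions pCSF, pGM, pWM) is mapped by the elementwise square
root onto the closed positive segment of the unit sphere S².  On the sphere
the usual Riemannian toolkit applies: geodesic (great-circle) distance,
exponential and logarithm maps between the sphere and its tangent planes,
and intrinsic (Fréchet) means.  The Fisher–Rao distance between two
compositions is the geodesic distance between their square-root images,
``arccos`` of the Bhattacharyya coefficient.

Conventions
-----------
* Compositions, sphere points and tangent vectors are plain float arrays of
  shape ``(..., 3)``; all functions broadcast over leading axes.  The
  ``validate_*`` helpers check the type invariants (sum-to-one, unit norm,
  tangency).
* Fisher–Rao distance carries **no factor 2**: it equals the sphere geodesic
  distance after the square-root map, so ``fisher_rao_distance((1,0,0),
  (0,1,0)) == pi/2``.  Some references scale the same metric by 2; every
  scaled quantity reported by this package (e.g. scaled prediction errors)
  is invariant to that choice.
* Inner products are clipped to ``[-1, 1]`` before ``arccos`` so that
  machine-epsilon overshoot never produces NaN.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConvergenceError, GeometryError

__all__ = [
    "COMP_SUM_TOL",
    "UNIT_NORM_TOL",
    "TANGENT_TOL",
    "validate_composition",
    "validate_sphere_point",
    "validate_tangent_vector",
    "comp_to_sphere",
    "sphere_to_comp",
    "geodesic_distance",
    "exp_map",
    "log_map",
    "tangent_projection",
    "frechet_mean",
    "frechet_mean_batch",
    "project_to_positive_segment",
    "fisher_rao_distance",
]

COMP_SUM_TOL = 1e-8
UNIT_NORM_TOL = 1e-10
TANGENT_TOL = 1e-8


def _as_float(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape[-1] != 3:
        raise GeometryError(f"expected trailing dimension 3, got shape {a.shape}")
    return a


def validate_composition(c, tol: float = COMP_SUM_TOL) -> np.ndarray:
    """Check nonnegativity and sum-to-one; return the array unchanged."""
    c = _as_float(c)
    if np.any(c < -tol):
        raise GeometryError(f"composition has negative entries (min {c.min():.3g})")
    s = c.sum(axis=-1)
    if np.any(np.abs(s - 1.0) > tol):
        bad = np.abs(s - 1.0).max()
        raise GeometryError(f"composition entries must sum to 1 (max deviation {bad:.3g})")
    return c


def validate_sphere_point(p, tol: float = UNIT_NORM_TOL) -> np.ndarray:
    p = _as_float(p)
    n = np.linalg.norm(p, axis=-1)
    if np.any(np.abs(n - 1.0) > tol):
        raise GeometryError(f"point not on unit sphere (max |norm-1| = {np.abs(n - 1).max():.3g})")
    return p


def validate_tangent_vector(base, vec, tol: float = TANGENT_TOL) -> np.ndarray:
    base = validate_sphere_point(base, tol=1e-8)
    vec = _as_float(vec)
    d = np.abs(np.sum(base * vec, axis=-1))
    if np.any(d > tol):
        raise GeometryError(f"tangent vector not orthogonal to base (max |<v,p>| = {d.max():.3g})")
    return vec


def comp_to_sphere(c, renormalize: bool = False) -> np.ndarray:
    """Elementwise square-root map from the simplex to the positive segment of S².

    With ``renormalize=True`` the input may be raw nonnegative values (e.g.
    tissue volumes); each vector is first divided by its sum.
    """
    c = _as_float(c)
    if renormalize:
        if np.any(c < -COMP_SUM_TOL):
            raise GeometryError("negative entries cannot be renormalized to a composition")
        s = np.clip(c, 0.0, None).sum(axis=-1, keepdims=True)
        if np.any(s <= 0):
            raise GeometryError("zero row sum: cannot renormalize to a composition")
        c = np.clip(c, 0.0, None) / s
    else:
        c = validate_composition(c)
        c = np.clip(c, 0.0, None)
    p = np.sqrt(c)
    # kill the last few ulps of drift so downstream unit-norm checks pass
    return p / np.linalg.norm(p, axis=-1, keepdims=True)


def sphere_to_comp(p, tol: float = 1e-8) -> np.ndarray:
    """Inverse of :func:`comp_to_sphere` on the closed positive segment."""
    p = validate_sphere_point(p, tol=1e-8)
    if np.any(p < -tol):
        raise GeometryError(
            "sphere point lies outside the positive segment; "
            "apply project_to_positive_segment first"
        )
    c = np.clip(p, 0.0, None) ** 2
    return c / c.sum(axis=-1, keepdims=True)


def geodesic_distance(p, q) -> np.ndarray | float:
    """Great-circle distance in radians, in [0, pi]."""
    p = _as_float(p)
    q = _as_float(q)
    dot = np.clip(np.sum(p * q, axis=-1), -1.0, 1.0)
    return np.arccos(dot)


def tangent_projection(p, v) -> np.ndarray:
    """Project an ambient vector onto the tangent plane at ``p``."""
    p = _as_float(p)
    v = _as_float(v)
    return v - np.sum(p * v, axis=-1, keepdims=True) * p


def exp_map(p, v) -> np.ndarray:
    """Riemannian exponential: follow the geodesic from ``p`` with velocity ``v``."""
    p = _as_float(p)
    v = _as_float(v)
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    # sinc-style safe division: for ||v|| -> 0 the map is the identity
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(nv > 0, v / np.where(nv > 0, nv, 1.0), 0.0)
    out = np.cos(nv) * p + np.sin(nv) * unit
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def log_map(p, q, antipodal_tol: float = 1e-10) -> np.ndarray:
    """Riemannian logarithm: tangent vector at ``p`` pointing to ``q``.

    Undefined (raises :class:`GeometryError`) when ``q`` is within
    ``antipodal_tol`` of the antipode of ``p``.
    """
    p = _as_float(p)
    q = _as_float(q)
    dot = np.clip(np.sum(p * q, axis=-1), -1.0, 1.0)
    if np.any(dot <= -1.0 + antipodal_tol):
        raise GeometryError("logarithm undefined for (nearly) antipodal points")
    theta = np.arccos(dot)
    w = q - dot[..., None] * p
    nw = np.linalg.norm(w, axis=-1)
    # theta/sin(theta) -> 1 as theta -> 0; nw = sin(theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(nw > 1e-300, theta / np.where(nw > 1e-300, nw, 1.0), 1.0)
    return scale[..., None] * w


def _weighted_extrinsic_init(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    m = weights @ points / weights.sum()
    n = np.linalg.norm(m)
    if n < 1e-6:
        raise GeometryError(
            "extrinsic average nearly zero: points do not appear to lie "
            "within an open hemisphere, Fréchet mean may be ill-defined"
        )
    return m / n


def frechet_mean(
    points,
    weights=None,
    tol: float = 1e-10,
    max_iter: int = 100,
    init=None,
) -> np.ndarray:
    """Weighted intrinsic mean on the sphere.

    Fixed-point iteration with unit step: from the current estimate ``m``,
    average the log-mapped points in the tangent plane and step via the
    exponential map.  Initialized at the normalized extrinsic weighted
    average (well-defined within a hemisphere).
    """
    points = validate_sphere_point(points, tol=1e-8)
    points = np.atleast_2d(points)
    n = points.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise GeometryError("weights must be a 1-D array matching the number of points")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise GeometryError("need nonnegative weights with at least one strictly positive")
    m = _weighted_extrinsic_init(points, weights) if init is None else validate_sphere_point(init)
    wsum = weights.sum()
    for _ in range(max_iter):
        step = weights @ log_map(m, points) / wsum
        if np.linalg.norm(step) < tol:
            return m
        m = exp_map(m, step)
    raise ConvergenceError(
        f"Fréchet mean did not converge in {max_iter} iterations "
        f"(last step norm {np.linalg.norm(step):.3g})"
    )


def frechet_mean_batch(
    points: np.ndarray,
    weight_matrix: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Solve many weighted Fréchet means over the same point cloud at once.

    ``points`` has shape (N, 3); ``weight_matrix`` has shape (G, N), one row
    of nonnegative weights per target mean.  Returns (G, 3).  This is the
    workhorse behind kernel-localized mean estimation, vectorized so that
    bootstrap and simulation loops stay cheap.
    """
    Y = np.asarray(points, dtype=float)
    W = np.asarray(weight_matrix, dtype=float)
    if W.ndim != 2 or W.shape[1] != Y.shape[0]:
        raise GeometryError("weight_matrix must be (G, N) matching points (N, 3)")
    wsum = W.sum(axis=1)
    if np.any(wsum <= 0):
        raise GeometryError("every weight row needs at least one positive weight")
    if init is None:
        M = W @ Y
        norms = np.linalg.norm(M, axis=1)
        if np.any(norms < 1e-6 * wsum):
            raise GeometryError("degenerate extrinsic initialization (hemisphere violation?)")
        M = M / norms[:, None]
    else:
        M = np.array(init, dtype=float)
    for _ in range(max_iter):
        dots = np.clip(M @ Y.T, -1.0, 1.0)  # (G, N)
        if np.any((dots <= -1.0 + 1e-12) & (W > 0)):
            raise GeometryError("antipodal point with positive weight in Fréchet mean")
        theta = np.arccos(dots)
        sin_t = np.sqrt(np.clip(1.0 - dots * dots, 0.0, None))
        fac = np.where(sin_t > 1e-300, theta / np.where(sin_t > 1e-300, sin_t, 1.0), 1.0)
        WF = W * fac
        # sum_n w f (y_n - dot * m): expand to avoid forming the (G, N, 3) tensor
        step = (WF @ Y - ((WF * dots).sum(axis=1))[:, None] * M) / wsum[:, None]
        sn = np.linalg.norm(step, axis=1)
        M = exp_map(M, step)
        if sn.max() < tol:
            return M
    raise ConvergenceError(
        f"batch Fréchet mean: {int((sn >= tol).sum())} of {len(sn)} targets "
        f"unconverged after {max_iter} iterations (max step {sn.max():.3g})"
    )


def project_to_positive_segment(p) -> np.ndarray:
    """Geodesically nearest point of S² with all coordinates >= 0.

    For a unit vector the nearest point of the closed positive segment (in
    the geodesic, equivalently chordal, metric) maximizes the inner product
    over unit nonnegative vectors, which is the clamped-and-renormalized
    vector ``max(p, 0)/||max(p, 0)||``.  Idempotent; identity on the segment.
    """
    p = validate_sphere_point(p, tol=1e-8)
    clipped = np.clip(p, 0.0, None)
    n = np.linalg.norm(clipped, axis=-1, keepdims=True)
    if np.any(n <= 0):
        raise GeometryError("all coordinates nonpositive: projection undefined")
    return clipped / n


def fisher_rao_distance(c1, c2) -> np.ndarray | float:
    """Fisher–Rao distance between compositions: arccos of the Bhattacharyya coefficient.

    Equals the sphere geodesic distance after the square-root map (factor-1
    convention; see module docstring).
    """
    c1 = validate_composition(c1)
    c2 = validate_composition(c2)
    bc = np.sum(np.sqrt(np.clip(c1, 0, None) * np.clip(c2, 0, None)), axis=-1)
    return np.arccos(np.clip(bc, -1.0, 1.0))
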