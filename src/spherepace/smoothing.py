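"""Local-linear kernel smoothers with the Epanechnikov kernel.

These are the estimation primitives behind the mean-function and
covariance-surface steps of the sparse functional PCA: a 1-D local-linear
smoother for scalar (or multi-channel) curves and a 2-D local-plane
smoother for raw covariance entries on a grid x grid design.

Sparse longitudinal designs (many subjects with a single visit) leave some
kernel windows nearly empty, especially near the boundary of the age range.
Both smoothers therefore widen a deficient window by doubling the local
bandwidth up to ``max_widen`` times before giving up with a
:class:`~spherepace.exceptions.BandwidthError`.

Local-linear fits reproduce affine functions exactly at any admissible
bandwidth; the test suite leans on that defining property.
"""

from __future__ import annotations

import numpy as np

from .exceptions import BandwidthError

__all__ = [
    "epanechnikov",
    "local_linear_1d",
    "local_linear_2d",
    "select_bandwidth_cv",
]


def epanechnikov(u):
    """Epanechnikov kernel 0.75 (1 - u²) on |u| <= 1, else 0."""
    u = np.asarray(u, dtype=float)
    out = 0.75 * (1.0 - u * u)
    return np.where(np.abs(u) <= 1.0, out, 0.0)


def _check_xyw(x, y, w):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
        squeeze = True
    else:
        squeeze = False
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float).ravel()
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    return x, y, w, squeeze


def local_linear_1d(x, y, grid, bandwidth, weights=None, max_widen: int = 3):
    """Local-linear fit of ``y`` on ``x``, evaluated at ``grid``.

    ``y`` may be (N,) or (N, C); returns matching (G,) or (G, C).  At each
    grid point a weighted least-squares line is fitted within the kernel
    window; windows with fewer than two distinct predictor values are
    widened adaptively.
    """
    if bandwidth <= 0:
        raise BandwidthError("bandwidth must be positive")
    x, y, w, squeeze = _check_xyw(x, y, weights)
    grid = np.asarray(grid, dtype=float).ravel()

    K = epanechnikov((grid[:, None] - x[None, :]) / bandwidth) * w[None, :]
    fitted = np.full((len(grid), y.shape[1]), np.nan)
    bad: list[int] = []
    d = grid[:, None] - x[None, :]
    S0 = K.sum(axis=1)
    S1 = (K * d).sum(axis=1)
    S2 = (K * d * d).sum(axis=1)
    T0 = K @ y
    T1 = (K * d) @ y
    den = S2 * S0 - S1 * S1
    # relative check on the normalized design determinant
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_den = den / np.maximum(S0 * S0 * bandwidth**2, 1e-300)
    ok = (S0 > 0) & (rel_den > 1e-10)
    gi = np.where(ok)[0]
    fitted[gi] = (S2[gi, None] * T0[gi] - S1[gi, None] * T1[gi]) / den[gi, None]
    bad = list(np.where(~ok)[0])

    for g in bad:
        h = bandwidth
        done = False
        for _ in range(max_widen):
            h *= 2.0
            k = epanechnikov((grid[g] - x) / h) * w
            sup = x[k > 0]
            if len(sup) >= 2 and sup.max() - sup.min() > 0:
                dd = grid[g] - x
                s0 = k.sum()
                s1 = (k * dd).sum()
                s2 = (k * dd * dd).sum()
                t0 = k @ y
                t1 = (k * dd) @ y
                dn = s2 * s0 - s1 * s1
                if dn / max(s0 * s0 * h * h, 1e-300) > 1e-12:
                    fitted[g] = (s2 * t0 - s1 * t1) / dn
                    done = True
                    break
        if not done:
            raise BandwidthError(
                f"empty/deficient window at grid point {grid[g]:.4g} even after "
                f"{max_widen} doublings of bandwidth {bandwidth:.4g}"
            )
    return fitted[:, 0] if squeeze else fitted


def _plane_moments(s, t, values, grid, bandwidth, chunk):
    """Accumulate local-plane normal-equation moments over pair chunks."""
    G = len(grid)
    C = values.shape[1]
    S = np.zeros((6, G, G))
    T = np.zeros((C, 3, G, G))
    for lo in range(0, len(s), chunk):
        hi = min(lo + chunk, len(s))
        sc, tc, vc = s[lo:hi], t[lo:hi], values[lo:hi]
        ds = grid[:, None] - sc[None, :]
        dt = grid[:, None] - tc[None, :]
        Ks = epanechnikov(ds / bandwidth)
        Kt = epanechnikov(dt / bandwidth)
        Bs, Bt = Ks * ds, Kt * dt
        Cs, Ct = Bs * ds, Bt * dt
        S[0] += Ks @ Kt.T  # S00
        S[1] += Bs @ Kt.T  # S10
        S[2] += Ks @ Bt.T  # S01
        S[3] += Cs @ Kt.T  # S20
        S[4] += Ks @ Ct.T  # S02
        S[5] += Bs @ Bt.T  # S11
        for c in range(C):
            KsV = Ks * vc[:, c][None, :]
            BsV = Bs * vc[:, c][None, :]
            T[c, 0] += KsV @ Kt.T
            T[c, 1] += BsV @ Kt.T
            T[c, 2] += KsV @ Bt.T
    return S, T


def local_linear_2d(
    s,
    t,
    values,
    grid,
    bandwidth,
    max_widen: int = 3,
    symmetrize: bool = False,
    chunk: int = 100_000,
):
    """Local-plane (intercept + two slopes) smoother on ``grid`` x ``grid``.

    ``values`` may be (P,) for a scalar surface or (P, C) for C surfaces
    smoothed jointly with shared product-Epanechnikov weights.  Returns
    (G, G) or (G, G, C).  With ``symmetrize=True`` the scalar output is
    replaced by (S + Sᵀ)/2.
    """
    if bandwidth <= 0:
        raise BandwidthError("bandwidth must be positive")
    s = np.asarray(s, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
        squeeze = True
    else:
        squeeze = False
    if not (len(s) == len(t) == len(values)):
        raise ValueError("s, t, values must have equal length")
    grid = np.asarray(grid, dtype=float).ravel()
    G = len(grid)
    C = values.shape[1]

    S, T = _plane_moments(s, t, values, grid, bandwidth, chunk)
    S00, S10, S01, S20, S02, S11 = S
    A = np.empty((G, G, 3, 3))
    A[..., 0, 0], A[..., 0, 1], A[..., 0, 2] = S00, S10, S01
    A[..., 1, 0], A[..., 1, 1], A[..., 1, 2] = S10, S20, S11
    A[..., 2, 0], A[..., 2, 1], A[..., 2, 2] = S01, S11, S02
    rhs = np.moveaxis(T, (0, 1), (3, 2))  # (G, G, 3, C)

    det = np.linalg.det(A)
    ok = (S00 > 0) & (det / np.maximum(S00**3 * bandwidth**4, 1e-300) > 1e-12)
    out = np.full((G, G, C), np.nan)
    if ok.any():
        sol = np.linalg.solve(A[ok], rhs[ok])  # (M, 3, C)
        out[ok] = sol[:, 0, :]

    bad = np.argwhere(~ok)
    for a, b in bad:
        h = bandwidth
        done = False
        for _ in range(max_widen):
            h *= 2.0
            k = epanechnikov((grid[a] - s) / h) * epanechnikov((grid[b] - t) / h)
            m = k > 0
            if m.sum() < 3:
                continue
            X = np.column_stack([np.ones(m.sum()), s[m] - grid[a], t[m] - grid[b]])
            Aw = (X * k[m, None]).T @ X
            bw_ = (X * k[m, None]).T @ values[m]
            if np.linalg.det(Aw) / max(Aw[0, 0] ** 3 * h**4, 1e-300) > 1e-12:
                out[a, b] = np.linalg.solve(Aw, bw_)[0]
                done = True
                break
        if not done:
            raise BandwidthError(
                f"rank-deficient window at grid node ({grid[a]:.4g}, {grid[b]:.4g}) "
                f"even after {max_widen} doublings of bandwidth {bandwidth:.4g}"
            )
    if symmetrize:
        out = 0.5 * (out + np.transpose(out, (1, 0, 2)))
    return out[..., 0] if squeeze else out


def select_bandwidth_cv(
    x,
    y,
    candidates,
    k_folds: int = 5,
    seed: int = 0,
    groups=None,
    weights=None,
    max_widen: int = 3,
):
    """Pick the bandwidth minimizing k-fold cross-validated squared error.

    Folds are split by ``groups`` (subject identifiers) when given, so that
    within-subject correlation does not leak across folds.  Deterministic
    given ``seed``.  Candidates whose windows fail even after widening are
    discarded; if all fail, the collected diagnostics are raised.
    """
    x, y, w, _ = _check_xyw(x, y, weights)
    candidates = sorted(float(c) for c in candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate bandwidth")
    if groups is None:
        groups = np.arange(len(x))
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    fold_of_group = {g: perm[i] % k_folds for i, g in enumerate(uniq)}
    fold = np.array([fold_of_group[g] for g in groups])

    errors: dict[float, float] = {}
    failures: dict[float, str] = {}
    for h in candidates:
        sse = 0.0
        try:
            for f in range(k_folds):
                test = fold == f
                if not test.any() or test.all():
                    continue
                pred = local_linear_1d(
                    x[~test], y[~test], x[test], h, weights=w[~test], max_widen=max_widen
                )
                sse += float(np.sum(w[test, None] * (pred - y[test]) ** 2))
            errors[h] = sse
        except BandwidthError as e:
            failures[h] = str(e)
    if not errors:
        raise BandwidthError(
            "all candidate bandwidths failed window preconditions: "
            + "; ".join(f"{h:.4g}: {msg}" for h, msg in failures.items())
        )
    best = min(errors, key=lambda h: (errors[h], -h))  # ties -> larger bandwidth
    return best
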