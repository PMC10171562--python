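"""Sparse Riemannian functional principal component analysis on the sphere.

The model: each subject carries a smooth random trajectory ``X_i(t)`` on S²
(the square-root image of a tissue-proportion curve), observed at a few
irregular ages with intrinsic noise,

    Y_ij = Exp_{mu(T_ij)}( L_i(T_ij) + eps_ij ),

where ``mu`` is the Fréchet mean function and ``L_i(t) = Log_{mu(t)} X_i(t)``
is the tangent-space process with covariance ``Gamma(s, t) = E[L(s) L(t)ᵀ]``
and Karhunen–Loève expansion ``L_i(t) = sum_k xi_ik phi_k(t)``.

Estimation follows the conditional-expectation (PACE) recipe for sparse
designs, transplanted to the tangent bundle of the sphere:

1. kernel-localized Fréchet means on a regular grid (mean function),
2. log-map the observations into the tangent planes of the mean,
3. smooth the off-diagonal raw products ``L_ij L_ilᵀ`` (j != l) into the
   covariance surface — same-time products are excluded because they are
   inflated by the noise term,
4. eigendecompose the discretized covariance operator (projected to the
   tangent planes of the mean, so eigenfunctions are exactly tangent),
5. recover the noise variance from the gap between the smoothed same-time
   squared norms and the trace of the covariance surface,
6. per-subject scores by best linear unbiased prediction (BLUP), which
   handles subjects with as little as a single visit via shrinkage.

Noise convention: ``sigma2`` is the *total* expected squared tangent norm
``E||eps||²``; the error is assumed isotropic in the 2-D tangent plane, so
each tangent direction carries variance ``sigma2 / 2``.  Because tangent
vectors are stored in ambient coordinates and every vector entering the
BLUP system is tangent, adding ``(sigma2/2) I`` on the ambient block is
exactly equivalent to ``(sigma2/2)`` times the identity on each 2-D tangent
plane.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .exceptions import BandwidthError, GeometryError, ModelError, SpherePaceError
from .smoothing import epanechnikov, local_linear_1d, local_linear_2d, select_bandwidth_cv

__all__ = [
    "LongitudinalSample",
    "TangentData",
    "RFPCAOptions",
    "FittedRFPCA",
    "estimate_mean_function",
    "mean_at_times",
    "compute_log_data",
    "estimate_covariance",
    "eigendecompose",
    "estimate_noise_variance",
    "refine_eigenstructure",
    "select_K",
    "conditional_scores",
    "reconstruct_trajectory",
    "predict_at_age",
    "fit_rfpca",
    "save_fit",
    "load_fit",
]

DEFAULT_BW_FRACTIONS = (0.05, 0.075, 0.11, 0.17, 0.25)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class LongitudinalSample:
    """Sparse longitudinal sphere-valued observations, one block per subject.

    ``times[i]`` is a sorted (m_i,) array of ages (years) and ``values[i]``
    the matching (m_i, 3) array of unit vectors on the positive segment of
    S².  ``groups`` optionally labels each subject (e.g. maternal-education
    group).
    """

    ids: list
    times: list
    values: list
    groups: list | None = None

    def __post_init__(self):
        if not (len(self.ids) == len(self.times) == len(self.values)):
            raise ModelError("ids, times, values must have one entry per subject")
        if self.groups is not None and len(self.groups) != len(self.ids):
            raise ModelError("groups must have one entry per subject")
        self.times = [np.asarray(t, dtype=float).ravel() for t in self.times]
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for i, (t, v) in enumerate(zip(self.times, self.values)):
            if len(t) < 1:
                raise ModelError(f"subject {self.ids[i]!r} has no observations")
            if v.shape != (len(t), 3):
                raise ModelError(f"subject {self.ids[i]!r}: values shape {v.shape} != ({len(t)}, 3)")
            if np.any(np.diff(t) < 0):
                order = np.argsort(t, kind="stable")
                self.times[i] = t[order]
                self.values[i] = v[order]
            geo.validate_sphere_point(self.values[i], tol=1e-8)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(sum(len(t) for t in self.times))

    @property
    def domain(self) -> tuple[float, float]:
        lo = min(float(t[0]) for t in self.times)
        hi = max(float(t[-1]) for t in self.times)
        return lo, hi

    def stacked(self):
        """Pooled arrays: subject index (N,), times (N,), values (N, 3)."""
        idx = np.concatenate([np.full(len(t), i) for i, t in enumerate(self.times)])
        return idx.astype(int), np.concatenate(self.times), np.vstack(self.values)

    def subset(self, indices) -> "LongitudinalSample":
        """New sample holding the given subjects (repeats allowed, for bootstrap)."""
        indices = list(indices)
        return LongitudinalSample(
            ids=[self.ids[i] for i in indices],
            times=[self.times[i].copy() for i in indices],
            values=[self.values[i].copy() for i in indices],
            groups=None if self.groups is None else [self.groups[i] for i in indices],
        )

    def drop_observation(self, subject_index: int, obs_index: int) -> "LongitudinalSample":
        """Copy of the sample with one observation of one subject removed."""
        if len(self.times[subject_index]) <= 1:
            raise ModelError("cannot drop the only observation of a subject")
        out = self.subset(range(self.n_subjects))
        keep = np.ones(len(out.times[subject_index]), dtype=bool)
        keep[obs_index] = False
        out.times[subject_index] = out.times[subject_index][keep]
        out.values[subject_index] = out.values[subject_index][keep]
        return out


@dataclass
class TangentData:
    """Per-observation log-mapped data: ``L_ij = Log_{mu(T_ij)} Y_ij``."""

    subject_index: np.ndarray  # (N,)
    times: np.ndarray  # (N,)
    L: np.ndarray  # (N, 3), tangent at mu(T_ij)
    mu_obs: np.ndarray  # (N, 3), mean evaluated at the observation times


@dataclass(frozen=True)
class RFPCAOptions:
    """Tuning parameters of the sparse Riemannian FPCA fit.

    ``bw_mean`` / ``bw_cov`` are in the units of the time axis (years).
    When ``bw_mean`` is None it is chosen by subject-blocked cross-validation
    on the ambient sphere coordinates; ``bw_cov`` then defaults to
    ``cov_bw_factor * bw_mean``.  ``fve_threshold`` picks the smallest K
    whose cumulative fraction of variance explained reaches the threshold.
    """

    n_grid: int = 51
    bw_mean: float | None = None
    bw_cov: float | None = None
    cov_bw_factor: float = 2.5
    bw_candidates: tuple = DEFAULT_BW_FRACTIONS  # fractions of the domain length
    cv_folds: int = 5
    cv_seed: int = 0
    fve_threshold: float = 0.90
    max_components: int = 10
    assume_noise: bool = True
    refine: bool = True
    n_refine: int = 3
    ridge: float = 1e-10
    domain: tuple | None = None
    max_widen: int = 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bw_candidates"] = list(self.bw_candidates)
        d["domain"] = None if self.domain is None else list(self.domain)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RFPCAOptions":
        d = dict(d)
        d["bw_candidates"] = tuple(d.get("bw_candidates", DEFAULT_BW_FRACTIONS))
        if d.get("domain") is not None:
            d["domain"] = tuple(d["domain"])
        return cls(**d)


@dataclass
class FittedRFPCA:
    """Result of :func:`fit_rfpca`.

    Invariants (enforced by construction, checked in the test suite):
    eigenfunctions have unit quadrature L² norm and are mutually orthogonal;
    ``phis[k, t] . mu[t] = 0`` at every grid age; eigenvalues are
    nonincreasing and nonnegative.
    """

    grid: np.ndarray  # (G,)
    mu: np.ndarray  # (G, 3)
    gamma: np.ndarray  # (G, G, 3, 3)
    lambdas: np.ndarray  # (M,) nonincreasing, >= 0
    phis: np.ndarray  # (M, G, 3)
    sigma2: float
    total_variance: float
    fve: np.ndarray  # (M,) cumulative fraction of variance explained
    K: int
    scores: np.ndarray  # (n_subjects, K)
    subject_ids: list
    bw_mean: float
    bw_cov: float
    options: RFPCAOptions = field(default_factory=RFPCAOptions)

    @property
    def n_components(self) -> int:
        return len(self.lambdas)

    def mean_at(self, times) -> np.ndarray:
        """Mean function at arbitrary times: coordinatewise linear interpolation
        of the grid values, renormalized to the sphere."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        _check_in_domain(times, self.grid)
        return _interp_mean(self.grid, self.mu, times)

    def phi_at(self, times, K: int | None = None) -> np.ndarray:
        """Eigenfunctions at arbitrary times: coordinatewise linear interpolation
        followed by projection onto the tangent plane of the interpolated mean
        (local projection only; the global L² norm is not recomputed, keeping
        scores continuous in t).  Returns (len(times), K, 3)."""
        K = self.K if K is None else K
        times = np.atleast_1d(np.asarray(times, dtype=float))
        _check_in_domain(times, self.grid)
        return evaluate_phi(self.grid, self.mu, self.phis, times, K)

    def save(self, path) -> None:
        save_fit(self, path)

    @classmethod
    def load(cls, path) -> "FittedRFPCA":
        return load_fit(path)


def _check_in_domain(times: np.ndarray, grid: np.ndarray) -> None:
    lo, hi = grid[0], grid[-1]
    eps = 1e-9 * max(1.0, abs(hi - lo))
    if np.any(times < lo - eps) or np.any(times > hi + eps):
        raise ModelError(
            f"requested times outside the fitted grid range [{lo:.4g}, {hi:.4g}]; "
            "no extrapolation"
        )


def _interp_mean(grid: np.ndarray, mu: np.ndarray, times: np.ndarray) -> np.ndarray:
    out = np.column_stack([np.interp(times, grid, mu[:, d]) for d in range(3)])
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def evaluate_phi(
    grid: np.ndarray, mu: np.ndarray, phis: np.ndarray, times: np.ndarray, K: int
) -> np.ndarray:
    """Interpolate eigenfunctions to off-grid times, (len(times), K, 3)."""
    mu_t = _interp_mean(grid, mu, times)
    out = np.empty((len(times), K, 3))
    for k in range(K):
        raw = np.column_stack([np.interp(times, grid, phis[k, :, d]) for d in range(3)])
        out[:, k, :] = geo.tangent_projection(mu_t, raw)
    return out


# ---------------------------------------------------------------------------
# estimation stages


def _kernel_weight_matrix(
    obs_times: np.ndarray,
    targets: np.ndarray,
    bandwidth: float,
    max_widen: int = 3,
) -> np.ndarray:
    """Epanechnikov weight rows K_h(T - t) for each target t, with adaptive
    per-row widening of empty windows."""
    if bandwidth <= 0:
        raise BandwidthError("bandwidth must be positive")
    W = epanechnikov((targets[:, None] - obs_times[None, :]) / bandwidth)
    empty = np.where((W > 0).sum(axis=1) == 0)[0]
    for g in empty:
        h = bandwidth
        for _ in range(max_widen):
            h *= 2.0
            row = epanechnikov((targets[g] - obs_times) / h)
            if (row > 0).any():
                W[g] = row
                break
        else:
            raise BandwidthError(
                f"no observations within the kernel window at t = {targets[g]:.4g} "
                f"even after {max_widen} doublings of bandwidth {bandwidth:.4g}"
            )
    return W


def mean_at_times(
    sample: LongitudinalSample,
    targets,
    bandwidth: float,
    tol: float = 1e-10,
    max_iter: int = 200,
    max_widen: int = 3,
) -> np.ndarray:
    """Kernel-localized Fréchet mean at each target time.

    At time t this solves ``argmin_p sum_ij K_h(T_ij - t) d²(p, Y_ij)`` by
    the iterative intrinsic mean.  Duplicate targets are solved once; target
    batches are chunked to bound memory.
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    _, T, Y = sample.stacked()
    uniq, inv = np.unique(targets, return_inverse=True)
    W = _kernel_weight_matrix(T, uniq, bandwidth, max_widen=max_widen)
    out = np.empty((len(uniq), 3))
    chunk = max(1, int(2_000_000 // max(len(T), 1)))
    for lo in range(0, len(uniq), chunk):
        hi = min(lo + chunk, len(uniq))
        out[lo:hi] = geo.frechet_mean_batch(Y, W[lo:hi], tol=tol, max_iter=max_iter)
    return out[inv]


def estimate_mean_function(
    sample: LongitudinalSample,
    bandwidth: float,
    grid,
    **kwargs,
) -> np.ndarray:
    """Mean function mu(t) on the grid (see :func:`mean_at_times`)."""
    return mean_at_times(sample, grid, bandwidth, **kwargs)


def compute_log_data(sample: LongitudinalSample, mu_obs: np.ndarray) -> TangentData:
    """Log-map every observation into the tangent plane of the mean at its time.

    ``mu_obs`` must hold the mean evaluated at each pooled observation time
    (exact-time localized Fréchet solutions, so tangency is exact)."""
    idx, T, Y = sample.stacked()
    mu_obs = np.asarray(mu_obs, dtype=float)
    if mu_obs.shape != Y.shape:
        raise ModelError("mu_obs must match the pooled observations, one mean per row")
    try:
        L = geo.log_map(mu_obs, Y)
    except GeometryError as e:
        d = geo.geodesic_distance(mu_obs, Y)
        j = int(np.argmax(d))
        raise GeometryError(
            f"{e} (worst offender: subject {sample.ids[idx[j]]!r} at t = {T[j]:.4g})"
        ) from e
    return TangentData(subject_index=idx, times=T, L=L, mu_obs=mu_obs)


def _within_subject_pairs(tangent: TangentData):
    """Ordered pairs (j != l) of observation indices within each subject."""
    s_idx, t_idx = [], []
    idx = tangent.subject_index
    for i in np.unique(idx):
        rows = np.where(idx == i)[0]
        if len(rows) < 2:
            continue
        a, b = np.meshgrid(rows, rows, indexing="ij")
        off = a != b
        s_idx.append(a[off])
        t_idx.append(b[off])
    if not s_idx:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(s_idx), np.concatenate(t_idx)


def estimate_covariance(
    tangent: TangentData,
    bandwidth: float,
    grid,
    max_widen: int = 3,
) -> np.ndarray:
    """Tangent covariance surface Gamma(s, t) = E[L(s) L(t)ᵀ] on grid x grid.

    Raw entries are the within-subject cross products ``L_ij L_ilᵀ`` for
    j != l only; same-time products are excluded because the intrinsic noise
    inflates them by sigma².  The nine component surfaces are smoothed
    jointly with the local-plane smoother, then symmetrized so that
    ``Gamma(s, t) = Gamma(t, s)ᵀ``.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    a, b = _within_subject_pairs(tangent)
    if len(a) == 0:
        raise ModelError(
            "no subject has two or more visits: the design cannot identify "
            "the covariance surface"
        )
    raw = np.einsum("pd,pe->pde", tangent.L[a], tangent.L[b]).reshape(len(a), 9)
    surf = local_linear_2d(
        tangent.times[a], tangent.times[b], raw, grid, bandwidth, max_widen=max_widen
    )
    gamma = surf.reshape(len(grid), len(grid), 3, 3)
    return 0.5 * (gamma + np.transpose(gamma, (1, 0, 3, 2)))


def eigendecompose(
    gamma: np.ndarray,
    grid,
    mu: np.ndarray | None = None,
    max_components: int | None = None,
):
    """Eigenpairs (lambda_k, phi_k) of the discretized covariance operator.

    The (G·3) x (G·3) matrix is scaled by the grid spacing (rectangle-rule
    quadrature).  When ``mu`` is given, the operator is first projected
    blockwise with P(t) = I - mu(t) mu(t)ᵀ, so every eigenfunction with a
    nonzero eigenvalue is exactly tangent to the mean, and orthonormality
    is exact.  Negative eigenvalues (possible after smoothing) are truncated
    to zero.  Sign convention: the coordinate with the largest |integral| is
    made positive.

    Returns ``(lambdas, phis, total_variance)`` with ``lambdas`` the first
    ``max_components`` positive eigenvalues (nonincreasing), ``phis`` of
    shape (M, G, 3) and ``total_variance`` the sum of all positive
    eigenvalues.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    G = len(grid)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (G, G, 3, 3):
        raise ModelError(f"gamma must have shape ({G}, {G}, 3, 3)")
    if not np.allclose(gamma, np.transpose(gamma, (1, 0, 3, 2)), atol=1e-8):
        raise ModelError("covariance surface is not symmetric: Gamma(s,t) != Gamma(t,s)ᵀ")
    h = float(grid[1] - grid[0])
    if mu is not None:
        P = np.eye(3)[None, :, :] - np.einsum("gd,ge->gde", mu, mu)
        gamma = np.einsum("sde,stef,tfh->stdh", P, gamma, P)
    big = gamma.transpose(0, 2, 1, 3).reshape(3 * G, 3 * G)
    big = 0.5 * (big + big.T)
    w, v = np.linalg.eigh(big)
    lam = w[::-1] * h
    v = v[:, ::-1]
    pos = lam > max(0.0, 1e-12 * max(lam.max(initial=0.0), 0.0))
    total = float(lam[pos].sum())
    m_all = int(pos.sum())
    if max_components is not None:
        m = min(m_all, max_components)
    else:
        m = m_all
    lambdas = lam[:m].copy()
    phis = np.empty((m, G, 3))
    for k in range(m):
        phi = v[:, k].reshape(G, 3) / np.sqrt(h)
        integ = h * phi.sum(axis=0)
        d_star = int(np.argmax(np.abs(integ)))
        if integ[d_star] < 0:
            phi = -phi
        phis[k] = phi
    return lambdas, phis, total


def estimate_noise_variance(
    tangent: TangentData,
    gamma: np.ndarray,
    bandwidth: float,
    grid,
    max_widen: int = 3,
) -> float:
    """Intrinsic noise variance sigma² = E||eps||².

    The smoothed same-time second moment V(t) of ||L_ij||² estimates
    trace Gamma(t, t) + sigma²; sigma² is the average excess over the
    central half of the grid, floored at zero.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    v_raw = np.sum(tangent.L**2, axis=1)
    V = local_linear_1d(tangent.times, v_raw, grid, bandwidth, max_widen=max_widen)
    tr = np.einsum("ttdd->t", np.asarray(gamma, dtype=float))
    G = len(grid)
    lo, hi = G // 4, G - G // 4
    return float(max(0.0, np.mean(V[lo:hi] - tr[lo:hi])))


def refine_eigenstructure(
    tangent: TangentData,
    grid: np.ndarray,
    mu: np.ndarray,
    lambdas: np.ndarray,
    phis: np.ndarray,
    sigma2: float,
    n_refine: int = 3,
):
    """Second-stage marginal-likelihood refinement of the leading eigenpairs.

    The pair-based covariance surface only sees subjects with two or more
    visits, which in very sparse designs is a minority; the resulting
    eigenvalues are noisy and the leading eigenfunctions can mix.  Keeping
    the smoothed eigenbasis as a function dictionary, this stage re-fits by
    Gaussian marginal likelihood over *all* subjects (single-visit subjects
    included):

    * the leading ``J = min(n_refine, M)`` eigenvalues (log scale),
    * the noise variance sigma² (log scale), and
    * a rotation of the leading eigen-subspace (Givens angles), which lets
      the likelihood correct the noisy within-subspace split of variance.

    Rotations preserve orthonormality and tangency exactly.  Returns the
    refined ``(lambdas, phis, sigma2)`` with the untouched tail appended and
    eigenvalues re-sorted nonincreasing.
    """
    from scipy.optimize import minimize

    M = len(lambdas)
    J = int(min(n_refine, M))
    if J < 1:
        return lambdas, phis, sigma2
    idx = tangent.subject_index
    # group subjects by visit count for batched linear algebra
    batches = []
    by_m: dict[int, list] = {}
    for i in np.unique(idx):
        rows = np.where(idx == i)[0]
        phi_obs = evaluate_phi(grid, mu, phis, tangent.times[rows], J)
        Phi = phi_obs.transpose(0, 2, 1).reshape(-1, J)
        by_m.setdefault(len(rows), []).append((Phi, tangent.L[rows].reshape(-1)))
    for m, items in by_m.items():
        P = np.stack([a for a, _ in items])
        V = np.stack([b for _, b in items])
        G = np.einsum("nij,nik->njk", P, P)
        W = np.einsum("nij,ni->nj", P, V)
        VV = np.einsum("ni,ni->n", V, V)
        batches.append((G, W, VV, m))

    angles = [(a, b) for a in range(J) for b in range(a + 1, J)]

    def rotation(thetas: np.ndarray) -> np.ndarray:
        R = np.eye(J)
        for (a, b), th in zip(angles, thetas):
            giv = np.eye(J)
            c0, s0 = np.cos(th), np.sin(th)
            giv[a, a] = giv[b, b] = c0
            giv[a, b] = -s0
            giv[b, a] = s0
            R = R @ giv
        return R

    def nll(x: np.ndarray) -> float:
        lam = np.exp(x[:J])
        c = np.exp(x[J]) / 2.0  # per-direction noise variance
        R = rotation(x[J + 1 :])
        tot = 0.0
        for G, W, VV, m in batches:
            Gr = R.T @ G @ R
            Wr = W @ R
            Minv = np.diag(1.0 / lam) + Gr / c
            _, ld = np.linalg.slogdet(Minv)
            sol = np.linalg.solve(Minv, Wr[:, :, None])[:, :, 0]
            quad = VV / c - np.einsum("nj,nj->n", Wr, sol) / c**2
            # tangent observations have 2m degrees of freedom per subject
            tot += 0.5 * np.sum(ld + np.sum(np.log(lam)) + 2 * m * np.log(c) + quad)
        return float(tot)

    x0 = np.concatenate(
        [
            np.log(np.maximum(lambdas[:J], 1e-7)),
            [np.log(max(sigma2, 1e-6))],
            np.zeros(len(angles)),
        ]
    )
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 2e-3, "fatol": 1e-5, "maxiter": 2000, "maxfev": 2000},
    )
    lam_new = np.exp(res.x[:J])
    sigma2_new = float(np.exp(res.x[J]))
    R = rotation(res.x[J + 1 :])
    phis_head = np.einsum("jk,jgd->kgd", R, phis[:J])
    lam_all = np.concatenate([lam_new, lambdas[J:]])
    phis_all = np.concatenate([phis_head, phis[J:]], axis=0)
    order = np.argsort(lam_all, kind="stable")[::-1]
    lam_all = lam_all[order]
    phis_all = phis_all[order]
    h = float(grid[1] - grid[0])
    for k in range(len(phis_all)):  # re-apply the sign convention after rotation
        integ = h * phis_all[k].sum(axis=0)
        if integ[int(np.argmax(np.abs(integ)))] < 0:
            phis_all[k] = -phis_all[k]
    return lam_all, phis_all, sigma2_new


def select_K(lambdas, fve_threshold: float = 0.90, total: float | None = None) -> int:
    """Smallest K whose cumulative fraction of variance explained reaches the threshold."""
    lambdas = np.asarray(lambdas, dtype=float)
    if total is None:
        total = float(lambdas.sum())
    if total <= 0 or len(lambdas) == 0 or lambdas[0] <= 0:
        raise ModelError("no positive eigenvalues: cannot choose a truncation level")
    fve = np.cumsum(lambdas) / total
    hit = np.where(fve >= fve_threshold - 1e-12)[0]
    return int(hit[0]) + 1 if len(hit) else len(lambdas)


def _blup(
    lambdas: np.ndarray,
    phi_obs: np.ndarray,  # (m, K, 3) eigenfunctions at the subject's times
    sigma2: float,
    L: np.ndarray,  # (m, 3) tangent observations
    ridge: float = 1e-10,
) -> np.ndarray:
    m, K, _ = phi_obs.shape
    # stack observation-major: row (3j + d) = phi_k(t_j)[d]
    Phi = phi_obs.transpose(0, 2, 1).reshape(m * 3, K)
    lam = np.asarray(lambdas[:K], dtype=float)
    c = sigma2 / 2.0
    if c < ridge:
        c = ridge
        warnings.warn(
            "noise variance ~ 0: adding ridge 1e-10 to the BLUP system", stacklevel=2
        )
    Sigma = (Phi * lam[None, :]) @ Phi.T + c * np.eye(3 * m)
    return lam * (Phi.T @ np.linalg.solve(Sigma, L.reshape(3 * m)))


def conditional_scores(
    fitted: FittedRFPCA,
    times,
    points,
    K: int | None = None,
) -> np.ndarray:
    """BLUP scores for one subject's observations under a fitted model.

    This is the PACE conditional-expectation estimator
    ``xi_hat = Lambda Phiᵀ Sigma⁻¹ vec(L)`` with
    ``Sigma = Phi Lambda Phiᵀ + (sigma²/2) I``; for Gaussian scores it is the
    conditional mean given the sparse observations, shrinking toward zero as
    the noise grows or the visits thin out.
    """
    K = fitted.K if K is None else K
    if K > fitted.n_components:
        raise ModelError(f"requested {K} components, model retains {fitted.n_components}")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(times) == 0:
        raise ModelError("subject must have at least one observation")
    mu_t = fitted.mean_at(times)
    L = geo.log_map(mu_t, points)
    phi_obs = fitted.phi_at(times, K=K)
    return _blup(fitted.lambdas, phi_obs, fitted.sigma2, L, ridge=fitted.options.ridge)


def reconstruct_trajectory(
    fitted: FittedRFPCA,
    scores,
    K: int | None = None,
):
    """Truncated Karhunen–Loève reconstruction on the model grid.

    Returns ``(sphere_curve, compositional_curve)``: the sphere curve is
    ``Exp_{mu(t)}(sum_k xi_k phi_k(t))``; the compositional curve is its
    square after projection to the positive segment, so every row sums to 1.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    K = len(scores) if K is None else K
    if K > fitted.n_components:
        raise ModelError(f"requested {K} components, model retains {fitted.n_components}")
    V = np.einsum("k,kgd->gd", scores[:K], fitted.phis[:K])
    V = geo.tangent_projection(fitted.mu, V)
    X = geo.exp_map(fitted.mu, V)
    comp = geo.sphere_to_comp(geo.project_to_positive_segment(X))
    return X, comp


def predict_at_age(
    fitted: FittedRFPCA,
    history_times,
    history_points,
    age: float,
    K: int | None = None,
) -> np.ndarray:
    """Predict the composition at ``age`` from a subject's sparse history.

    Scores come from :func:`conditional_scores`; the tangent sum is linearly
    interpolated between neighboring grid ages before the exponential map;
    out-of-segment predictions are projected back to the positive segment.
    Ages outside the fitted grid range raise (no extrapolation).
    """
    age = float(age)
    _check_in_domain(np.array([age]), fitted.grid)
    K = fitted.K if K is None else K
    xi = conditional_scores(fitted, history_times, history_points, K=K)
    V_grid = np.einsum("k,kgd->gd", xi, fitted.phis[:K])
    V_age = np.array([np.interp(age, fitted.grid, V_grid[:, d]) for d in range(3)])
    mu_age = fitted.mean_at([age])[0]
    V_age = V_age - (V_age @ mu_age) * mu_age
    X = geo.exp_map(mu_age, V_age)
    return geo.sphere_to_comp(geo.project_to_positive_segment(X))


# ---------------------------------------------------------------------------
# orchestration


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SpherePaceError):
                raise exc.__class__(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def default_bandwidths(sample: LongitudinalSample, options: RFPCAOptions):
    """Resolve (bw_mean, bw_cov) for a sample, running CV where needed."""
    lo, hi = options.domain if options.domain is not None else sample.domain
    span = hi - lo
    bw_mean = options.bw_mean
    if bw_mean is None:
        idx, T, Y = sample.stacked()
        candidates = [f * span for f in options.bw_candidates]
        bw_mean = select_bandwidth_cv(
            T,
            Y,
            candidates,
            k_folds=options.cv_folds,
            seed=options.cv_seed,
            groups=idx,
            max_widen=options.max_widen,
        )
    bw_cov = options.bw_cov if options.bw_cov is not None else options.cov_bw_factor * bw_mean
    return float(bw_mean), float(bw_cov)


def fit_rfpca(sample: LongitudinalSample, options: RFPCAOptions | None = None) -> FittedRFPCA:
    """Fit the sparse Riemannian FPCA model end to end.

    Deterministic given the sample and options (cross-validated bandwidth
    selection uses the fixed ``cv_seed``).
    """
    options = options or RFPCAOptions()
    lo, hi = options.domain if options.domain is not None else sample.domain
    if hi <= lo:
        raise ModelError("degenerate time domain")
    grid = np.linspace(lo, hi, options.n_grid)

    with _stage("bandwidth selection"):
        bw_mean, bw_cov = default_bandwidths(sample, options)
    with _stage("mean function"):
        mu = estimate_mean_function(sample, bw_mean, grid, max_widen=options.max_widen)
    with _stage("log data"):
        _, T, _ = sample.stacked()
        mu_obs = mean_at_times(sample, T, bw_mean, max_widen=options.max_widen)
        tangent = compute_log_data(sample, mu_obs)
    with _stage("covariance surface"):
        gamma = estimate_covariance(tangent, bw_cov, grid, max_widen=options.max_widen)
    with _stage("eigendecomposition"):
        lambdas, phis, total = eigendecompose(
            gamma, grid, mu=mu, max_components=options.max_components
        )
    with _stage("noise variance"):
        if options.assume_noise:
            sigma2 = estimate_noise_variance(
                tangent, gamma, bw_mean, grid, max_widen=options.max_widen
            )
        else:
            sigma2 = 0.0
    with _stage("likelihood refinement"):
        if options.refine and options.assume_noise and len(lambdas) > 0:
            tail = float(total - lambdas.sum())
            lambdas, phis, sigma2 = refine_eigenstructure(
                tangent, grid, mu, lambdas, phis, sigma2, n_refine=options.n_refine
            )
            total = float(lambdas.sum() + max(tail, 0.0))
    with _stage("component selection"):
        K = select_K(lambdas, options.fve_threshold, total=total)
    fve = np.cumsum(lambdas) / total

    fitted = FittedRFPCA(
        grid=grid,
        mu=mu,
        gamma=gamma,
        lambdas=lambdas,
        phis=phis,
        sigma2=float(sigma2),
        total_variance=total,
        fve=fve,
        K=K,
        scores=np.zeros((sample.n_subjects, K)),
        subject_ids=list(sample.ids),
        bw_mean=bw_mean,
        bw_cov=bw_cov,
        options=options,
    )
    with _stage("scores"):
        scores = np.empty((sample.n_subjects, K))
        idx = tangent.subject_index
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(sample.n_subjects):
                rows = np.where(idx == i)[0]
                phi_obs = fitted.phi_at(tangent.times[rows], K=K)
                scores[i] = _blup(
                    lambdas, phi_obs, sigma2, tangent.L[rows], ridge=options.ridge
                )
        fitted.scores = scores
    return fitted


# ---------------------------------------------------------------------------
# serialization


def save_fit(fitted: FittedRFPCA, path) -> None:
    """Serialize a fitted model: JSON header + dense numeric blocks (.npz)."""
    header = json.dumps(
        {
            "format": "spherepace-rfpca-fit",
            "version": 1,
            "sigma2": fitted.sigma2,
            "total_variance": fitted.total_variance,
            "K": fitted.K,
            "bw_mean": fitted.bw_mean,
            "bw_cov": fitted.bw_cov,
            "subject_ids": [str(s) for s in fitted.subject_ids],
            "options": fitted.options.to_dict(),
        },
        sort_keys=True,
    )
    with open(path, "wb") as fh:
        np.savez(
            fh,
            header=np.array(header),
            grid=fitted.grid,
            mu=fitted.mu,
            gamma=fitted.gamma,
            lambdas=fitted.lambdas,
            phis=fitted.phis,
            fve=fitted.fve,
            scores=fitted.scores,
        )


def load_fit(path) -> FittedRFPCA:
    with np.load(path, allow_pickle=False) as f:
        header = json.loads(str(f["header"]))
        if header.get("format") != "spherepace-rfpca-fit":
            raise ModelError(f"{path}: not a spherepace model archive")
        return FittedRFPCA(
            grid=f["grid"],
            mu=f["mu"],
            gamma=f["gamma"],
            lambdas=f["lambdas"],
            phis=f["phis"],
            sigma2=float(header["sigma2"]),
            total_variance=float(header["total_variance"]),
            fve=f["fve"],
            K=int(header["K"]),
            scores=f["scores"],
            subject_ids=list(header["subject_ids"]),
            bw_mean=float(header["bw_mean"]),
            bw_cov=float(header["bw_cov"]),
            options=RFPCAOptions.from_dict(header["options"]),
        )
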