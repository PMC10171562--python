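"""Seeded synthetic cohorts with known Karhunen–Loève ground truth.

The generator emulates a sparse longitudinal neuroimaging study of early
brain development: two groups of children (sizes 227 and 116), one to six
visits per child with the empirical repeat-count distribution pooled over
groups (207, 82, 30, 13, 10, 1 children with 1..6 visits), visit ages
uniform on 1.5–8.0 years, and a smooth nonlinear mean composition of
(pCSF, pGM, pWM) in which white matter grows quickly in early childhood
and then plateaus while grey matter declines.  Subject-level variation
lives in a rank-2 Karhunen–Loève expansion in the tangent bundle of the
mean with eigenvalues (0.012, 0.004); observations carry isotropic
intrinsic noise with total variance sigma² = 0.02².

The optional group contrast is a mean shift: the second group's pWM growth
is reduced by a ramp reaching ``group_offset`` (absolute proportion,
default 0.03) between ages 1.5 and 4.5 and held constant thereafter, with
the mass moved to pGM.  The eigenstructure is shared across groups, so a
two-sample test on principal-component scores targets exactly this mean
shift.

Everything is reproducible bit-for-bit from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import geometry as geo
from .exceptions import ModelError
from .rfpca import LongitudinalSample

__all__ = [
    "ScenarioParams",
    "GroundTruth",
    "default_scenario",
    "single_group_scenario",
    "draw_visit_counts",
    "make_mean_curve",
    "make_eigenfunctions",
    "generate_sample",
]

# pooled repeat-count frequencies for 1..6 visits over 343 children
_VISIT_COUNTS = (207, 82, 30, 13, 10, 1)

_DEFAULT_ANCHORS = (
    (1.5, (0.115, 0.605, 0.280)),
    (3.0, (0.105, 0.565, 0.330)),
    (4.5, (0.100, 0.540, 0.360)),
    (6.0, (0.098, 0.527, 0.375)),
    (8.0, (0.095, 0.520, 0.385)),
)


@dataclass(frozen=True)
class ScenarioParams:
    """Study-design parameters of a synthetic cohort (see module docstring)."""

    n_subjects: tuple = (227, 116)
    visit_probs: tuple = tuple(c / sum(_VISIT_COUNTS) for c in _VISIT_COUNTS)
    age_range: tuple = (1.5, 8.0)
    mean_anchors: tuple = _DEFAULT_ANCHORS
    lambdas: tuple = (0.012, 0.004)
    sigma: float = 0.02
    group_offset: float = 0.03
    offset_range: tuple = (1.5, 4.5)
    seed: int = 0

    def __post_init__(self):
        lam = self.lambdas
        if not (lam[0] >= lam[1] >= 0):
            raise ModelError("eigenvalues must satisfy lambda1 >= lambda2 >= 0")
        if self.sigma < 0:
            raise ModelError("sigma must be nonnegative")
        if abs(sum(self.visit_probs) - 1.0) > 1e-8 or min(self.visit_probs) < 0:
            raise ModelError("visit probabilities must be nonnegative and sum to 1")
        if self.age_range[1] <= self.age_range[0]:
            raise ModelError("age range must have positive length")
        for age, comp in self.mean_anchors:
            geo.validate_composition(comp, tol=1e-8)
            if not self.age_range[0] <= age <= self.age_range[1]:
                raise ModelError(f"anchor age {age} outside the age range")
        # wraparound guard: 5-sigma tangent excursions must stay well inside
        # the injectivity radius of the exponential map
        bound = 5.0 * (np.sqrt(lam[0]) + np.sqrt(lam[1])) + 5.0 * self.sigma
        if bound >= np.pi / 2:
            raise ModelError(
                f"parameters imply tangent norms up to {bound:.2f} rad; "
                "geodesic wraparound risk, refusing"
            )

    @property
    def n_groups(self) -> int:
        return sum(1 for n in self.n_subjects if n > 0)


def default_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """The two-group study-design scenario (sizes 227 and 116)."""
    return replace(ScenarioParams(seed=seed), **overrides)


def single_group_scenario(n_subjects: int = 300, seed: int = 0, **overrides) -> ScenarioParams:
    """One-group variant used for parameter-recovery studies."""
    return replace(ScenarioParams(seed=seed, n_subjects=(int(n_subjects), 0)), **overrides)


def draw_visit_counts(rng: np.random.Generator, n: int, probs) -> np.ndarray:
    """Draw per-subject visit counts from the categorical law over 1..len(probs)."""
    return rng.choice(np.arange(1, len(probs) + 1), size=n, p=np.asarray(probs, dtype=float))


def _anchor_interpolator(anchors):
    ages = np.array([a for a, _ in anchors])
    comps = np.array([c for _, c in anchors])
    return PchipInterpolator(ages, comps, axis=0)


def _mean_composition(params: ScenarioParams, times: np.ndarray, group: int) -> np.ndarray:
    """Smooth mean composition at the given ages for one group (0-based)."""
    interp = _anchor_interpolator(params.mean_anchors)
    comp = interp(np.asarray(times, dtype=float))
    comp = np.clip(comp, 1e-9, None)
    comp = comp / comp.sum(axis=-1, keepdims=True)
    if group == 1 and params.group_offset != 0.0:
        r0, r1 = params.offset_range
        ramp = np.clip((np.asarray(times) - r0) / (r1 - r0), 0.0, 1.0)
        delta = params.group_offset * ramp
        comp = comp.copy()
        comp[..., 2] -= delta  # pWM grows more slowly
        comp[..., 1] += delta  # mass moved to pGM, sum preserved
        if np.any(comp <= 0):
            raise ModelError("group offset pushes the mean outside the simplex")
    return comp


def make_mean_curve(anchors, grid) -> np.ndarray:
    """Smooth sphere-valued mean curve through compositional anchor points.

    Monotone piecewise-cubic (PCHIP) interpolation of the anchors in the
    simplex, renormalized and mapped through the square-root transform.
    Passes through the mapped anchors exactly at the anchor ages.
    """
    for _, comp in anchors:
        geo.validate_composition(comp, tol=1e-8)
    interp = _anchor_interpolator(anchors)
    comp = np.clip(interp(np.asarray(grid, dtype=float)), 0.0, None)
    comp = comp / comp.sum(axis=-1, keepdims=True)
    curve = geo.comp_to_sphere(comp, renormalize=True)
    if np.any(curve < 0.05):
        raise ModelError("mean curve leaves the interior of the positive segment")
    return curve


def _tangent_frame(mu: np.ndarray):
    """Smooth orthonormal frame (e1, e2) of the tangent planes along mu."""
    a = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    e1 = geo.tangent_projection(mu, np.broadcast_to(a, mu.shape))
    n1 = np.linalg.norm(e1, axis=-1, keepdims=True)
    if np.any(n1 < 1e-8):
        raise ModelError("degenerate tangent frame along the mean curve")
    e1 = e1 / n1
    e2 = np.cross(mu, e1)
    return e1, e2


def make_eigenfunctions(mu: np.ndarray, grid, k: int = 2) -> np.ndarray:
    """k smooth orthonormal tangent fields along ``mu`` (quadrature inner product).

    The modes mimic what FPCA of growth curves typically finds: the first is
    a constant loading on the frame direction e1 (a subject-level shift of
    the whole trajectory), the second a centered linear contrast (an
    early-late "tilt") with a constant transverse component so the fields
    are genuinely trivariate; higher modes oscillate.  Gram–Schmidt under
    the grid quadrature makes them exactly orthonormal; tangency is exact
    by construction.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if k < 1 or k > 4:
        raise ModelError("supported number of eigenfunctions: 1..4")
    h = float(grid[1] - grid[0])
    e1, e2 = _tangent_frame(mu)
    z = (grid - grid[0]) / (grid[-1] - grid[0])
    raw = [
        e1,
        (z - 0.5)[:, None] * e1 + 0.4 * e2,
        np.sin(2 * np.pi * z)[:, None] * e2,
        np.cos(2 * np.pi * z)[:, None] * e1,
    ][:k]
    phis = []
    for r in raw:
        v = r.copy()
        for p in phis:
            v = v - h * np.sum(v * p) * p
        nrm = np.sqrt(h * np.sum(v * v))
        if nrm < 1e-10:
            raise ModelError("degenerate frame: eigenfunction candidates are dependent")
        phis.append(v / nrm)
    return np.stack(phis)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery testing.

    ``mu`` and ``phis`` are stored per group on a dense grid; subject-level
    truth is the pair (group, scores).  ``trajectory`` reconstructs the
    noise-free smooth path of any subject at arbitrary ages.
    """

    grid: np.ndarray  # (G,) dense
    mu: np.ndarray  # (n_groups, G, 3)
    phis: np.ndarray  # (n_groups, k, G, 3)
    lambdas: np.ndarray  # (k,)
    sigma: float
    subject_groups: np.ndarray  # (n,) 0-based group index
    scores: np.ndarray  # (n, k)
    params: ScenarioParams = field(repr=False, default=None)

    def mean_at(self, times, group: int = 0) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.column_stack(
            [np.interp(times, self.grid, self.mu[group][:, d]) for d in range(3)]
        )
        return out / np.linalg.norm(out, axis=1, keepdims=True)

    def mean_composition_at(self, times, group: int = 0) -> np.ndarray:
        return geo.sphere_to_comp(self.mean_at(times, group))

    def phi_at(self, times, group: int = 0) -> np.ndarray:
        """Eigenfunctions at arbitrary times, (len(times), k, 3)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        mu_t = self.mean_at(times, group)
        k = self.phis.shape[1]
        out = np.empty((len(times), k, 3))
        for j in range(k):
            raw = np.column_stack(
                [np.interp(times, self.grid, self.phis[group, j, :, d]) for d in range(3)]
            )
            out[:, j, :] = geo.tangent_projection(mu_t, raw)
        return out

    def trajectory(self, subject: int, times) -> np.ndarray:
        """Noise-free sphere trajectory of one subject at the given ages."""
        g = int(self.subject_groups[subject])
        mu_t = self.mean_at(times, g)
        phi_t = self.phi_at(times, g)
        L = np.einsum("k,mkd->md", self.scores[subject], phi_t)
        return geo.exp_map(mu_t, L)


def generate_sample(
    params: ScenarioParams, seed: int | None = None
) -> tuple[LongitudinalSample, GroundTruth]:
    """Draw a full synthetic cohort; returns the sample and its ground truth.

    Per subject: visit count from the categorical law, visit ages i.i.d.
    uniform (sorted), scores xi_k ~ N(0, lambda_k), smooth tangent signal
    ``L_i(t) = sum_k xi_k phi*_k(t)``, isotropic tangent noise with
    ``E||eps||² = sigma²``, and ``Y_ij = Exp_{mu*(T_ij)}(L_i(T_ij) + eps_ij)``
    projected to the positive segment if it strays outside.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.age_range
    dense = np.linspace(lo, hi, 201)
    k = len(params.lambdas)
    n_groups_present = [n for n in params.n_subjects if n > 0]
    mu_all, phi_all = [], []
    for g in range(len(params.n_subjects)):
        comp = _mean_composition(params, dense, g)
        mu_g = geo.comp_to_sphere(comp, renormalize=True)
        mu_all.append(mu_g)
        phi_all.append(make_eigenfunctions(mu_g, dense, k=k))
    truth = GroundTruth(
        grid=dense,
        mu=np.stack(mu_all),
        phis=np.stack(phi_all),
        lambdas=np.asarray(params.lambdas, dtype=float),
        sigma=params.sigma,
        subject_groups=np.empty(0, dtype=int),
        scores=np.empty((0, k)),
        params=params,
    )

    sd = np.sqrt(np.asarray(params.lambdas, dtype=float))
    noise_sd = params.sigma / np.sqrt(2.0)
    ids, times, values, groups = [], [], [], []
    subj_groups, subj_scores = [], []
    counter = 0
    for g, n_g in enumerate(params.n_subjects):
        label = f"group{g + 1}"
        for _ in range(n_g):
            counter += 1
            m = int(draw_visit_counts(rng, 1, params.visit_probs)[0])
            ages = np.sort(rng.uniform(lo, hi, size=m))
            xi = rng.normal(0.0, sd)
            mu_t = truth.mean_at(ages, g)
            phi_t = truth.phi_at(ages, g)
            L = np.einsum("k,mkd->md", xi, phi_t)
            e1, e2 = _tangent_frame(mu_t)
            eps = (
                rng.normal(0.0, noise_sd, size=(m, 1)) * e1
                + rng.normal(0.0, noise_sd, size=(m, 1)) * e2
            )
            tang = L + eps
            norms = np.linalg.norm(tang, axis=1)
            if np.any(norms >= np.pi - 1e-6):
                raise ModelError("generated tangent norm near pi: wraparound")
            Y = geo.exp_map(mu_t, tang)
            if np.any(Y < 0):
                Y = geo.project_to_positive_segment(Y)
            ids.append(f"s{counter:04d}")
            times.append(ages)
            values.append(Y)
            groups.append(label)
            subj_groups.append(g)
            subj_scores.append(xi)

    truth.subject_groups = np.array(subj_groups, dtype=int)
    truth.scores = np.array(subj_scores, dtype=float)
    sample = LongitudinalSample(
        ids=ids,
        times=times,
        values=values,
        groups=groups if len(n_groups_present) > 1 else None,
    )
    return sample, truth
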