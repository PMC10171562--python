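"""Group inference: energy-distance permutation tests and bootstrap regions.

The two-sample comparison works on principal-component score vectors from a
single *pooled* model fit, so both groups share one basis: with the energy
distance

    ED(F, G) = 2 E||V - W|| - E||V - V'|| - E||W - W'||,

the null "both groups have the same score distribution" is tested by
permuting group labels.  The V-statistic convention (within-sample means
over all ordered pairs, self-pairs included) makes the empirical statistic
zero exactly when the two samples coincide as multisets.

Confidence regions for the mean composition at fixed ages are built by a
subject-level bootstrap: resample subjects with replacement, re-estimate
the mean function only, record the mean composition at each requested age,
and at each age take the highest-density region of a bivariate kernel
density estimate (Scott's rule) over the bootstrap points in ternary
coordinates — the smallest region containing at least the requested
fraction of the bootstrap points.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import gaussian_kde

from . import geometry as geo
from .exceptions import ModelError
from .rfpca import (
    FittedRFPCA,
    LongitudinalSample,
    RFPCAOptions,
    conditional_scores,
    default_bandwidths,
    fit_rfpca,
    mean_at_times,
)

__all__ = [
    "EnergyTestResult",
    "ConfidenceRegion",
    "energy_distance",
    "energy_permutation_test",
    "two_sample_score_test",
    "ternary_coords",
    "bootstrap_mean_regions",
]

DEFAULT_REGION_AGES = (2.8, 4.1, 5.4, 6.7)


# ---------------------------------------------------------------------------
# energy distance


@dataclass(frozen=True)
class EnergyTestResult:
    """Two-sample energy test outcome."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_a: int
    n_b: int
    method: str = "permutation"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "method": self.method,
        }


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def energy_distance(a, b) -> float:
    """Energy distance between two samples (V-statistic convention).

    ``2 mean||a_i - b_j|| - mean||a_i - a_i'|| - mean||b_j - b_j'||`` with
    within-sample means over all ordered pairs including self-pairs.
    Nonnegative; zero iff the empirical distributions coincide.
    """
    a, b = _as_2d(a), _as_2d(b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ModelError("both samples must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ModelError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    between = cdist(a, b).mean()
    within_a = squareform(pdist(a)).mean() if len(a) > 1 else 0.0
    within_b = squareform(pdist(b)).mean() if len(b) > 1 else 0.0
    return float(2.0 * between - within_a - within_b)


def _stat_from_labels(D: np.ndarray, Z: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Energy statistics for many labelings at once.

    ``D`` is the pooled (n, n) distance matrix; ``Z`` is (B, n) with 1 for
    group A.  Uses sum_AA = z D zᵀ etc. via one matrix product per batch.
    """
    S = Z @ D  # (B, n)
    sum_aa = np.einsum("bi,bi->b", S, Z)
    row_tot = D.sum()
    sum_ab = S.sum(axis=1) - sum_aa
    sum_bb = row_tot - 2.0 * sum_ab - sum_aa
    return 2.0 * sum_ab / (n_a * n_b) - sum_aa / (n_a * n_a) - sum_bb / (n_b * n_b)


def energy_permutation_test(
    a,
    b,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> EnergyTestResult:
    """Permutation test of equal distributions based on the energy distance.

    ``p = (1 + #{perm stat >= observed}) / (1 + n_perm)`` (add-one
    correction, so p is never zero).  With ``method="exhaustive"`` all
    label assignments of the pooled sample into sizes (n_a, n_b) are
    enumerated and ``p`` is the exact fraction of assignments whose
    statistic reaches the observed one (the identity assignment included).
    """
    a, b = _as_2d(a), _as_2d(b)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ModelError("degenerate group sizes: both groups must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ModelError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    pooled = np.vstack([a, b])
    n = n_a + n_b
    D = squareform(pdist(pooled))
    z_obs = np.zeros((1, n))
    z_obs[0, :n_a] = 1.0
    observed = float(_stat_from_labels(D, z_obs, n_a, n_b)[0])

    if method == "exhaustive":
        combos = list(itertools.combinations(range(n), n_a))
        Z = np.zeros((len(combos), n))
        for r, c in enumerate(combos):
            Z[r, list(c)] = 1.0
        stats = _stat_from_labels(D, Z, n_a, n_b)
        p = float(np.mean(stats >= observed - 1e-12))
        return EnergyTestResult(observed, p, len(combos), seed, n_a, n_b, "exhaustive")
    if method != "permutation":
        raise ModelError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    Z = np.zeros((n_perm, n))
    for r in range(n_perm):
        Z[r, rng.permutation(n)[:n_a]] = 1.0
    stats = _stat_from_labels(D, Z, n_a, n_b)
    p = float((1.0 + np.sum(stats >= observed - 1e-12)) / (1.0 + n_perm))
    return EnergyTestResult(observed, p, n_perm, seed, n_a, n_b, "permutation")


def two_sample_score_test(
    sample: LongitudinalSample,
    n_perm: int = 9999,
    seed: int | None = None,
    n_components: int = 2,
    options: RFPCAOptions | None = None,
    fitted: FittedRFPCA | None = None,
):
    """Fit one pooled model, then energy-test the top score vectors by group.

    The pooled fit guarantees both groups are scored against the same mean
    and eigenbasis; only the top ``n_components`` scores (default 2) enter
    the test.  Returns ``(EnergyTestResult, fitted, scores)``.
    """
    if sample.groups is None:
        raise ModelError("sample has no group labels")
    labels = np.asarray(sample.groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ModelError(f"need exactly two groups, found {list(uniq)}")
    if fitted is None:
        fitted = fit_rfpca(sample, options)
    K = min(n_components, fitted.n_components)
    if fitted.scores.shape[1] >= K:
        scores = fitted.scores[:, :K]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = np.vstack(
                [
                    conditional_scores(fitted, sample.times[i], sample.values[i], K=K)
                    for i in range(sample.n_subjects)
                ]
            )
    res = energy_permutation_test(
        scores[labels == uniq[0]], scores[labels == uniq[1]], n_perm=n_perm, seed=seed
    )
    return res, fitted, scores


# ---------------------------------------------------------------------------
# ternary coordinates


def ternary_coords(c) -> np.ndarray:
    """Map a composition (a, b, c) to 2-D ternary-plot coordinates.

    Vertices map to (0, 0), (1, 0) and (0.5, sqrt(3)/2) for the first,
    second and third part respectively: ``x = b + c/2, y = (sqrt(3)/2) c``.
    """
    c = geo.validate_composition(c)
    x = c[..., 1] + 0.5 * c[..., 2]
    y = (np.sqrt(3.0) / 2.0) * c[..., 2]
    return np.stack([x, y], axis=-1)


# ---------------------------------------------------------------------------
# bootstrap confidence regions


@dataclass
class ConfidenceRegion:
    """Highest-density bootstrap region for the mean composition at one age.

    ``contours`` is a list of closed polylines in ternary coordinates;
    ``contains`` tests membership via the defining density threshold, which
    is also how the region was anchored (smallest KDE region holding at
    least ``level`` of the bootstrap points).
    """

    age: float
    level: float
    contours: list
    bootstrap_points: np.ndarray  # (B, 2) ternary coords
    threshold: float
    area: float
    degenerate: bool = False
    _kde: object = field(default=None, repr=False)
    _center: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ModelError("confidence level must be in (0, 1)")
        for c in self.contours:
            c = np.asarray(c)
            if len(c) >= 2 and not np.allclose(c[0], c[-1], atol=1e-9):
                raise ModelError("region contours must be closed polylines")

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float).ravel()
        if self.degenerate:
            return bool(np.linalg.norm(point - self._center) < 1e-6)
        return bool(self._kde(point[:, None] if point.ndim == 1 else point)[0] >= self.threshold)

    def to_dict(self) -> dict:
        return {
            "age": self.age,
            "level": self.level,
            "threshold": self.threshold,
            "area": self.area,
            "degenerate": self.degenerate,
            "contours": [np.asarray(c).tolist() for c in self.contours],
        }


def _region_from_points(age: float, level: float, pts: np.ndarray, grid_n: int = 200):
    """Build the highest-density region for one age from bootstrap points."""
    spread = pts.std(axis=0).max()
    center = pts.mean(axis=0)
    if spread < 1e-9:
        eps = 1e-6
        ring = center + eps * np.array(
            [[np.cos(t), np.sin(t)] for t in np.linspace(0, 2 * np.pi, 33)]
        )
        return ConfidenceRegion(
            age=age,
            level=level,
            contours=[ring],
            bootstrap_points=pts,
            threshold=np.inf,
            area=0.0,
            degenerate=True,
            _center=center,
        )
    kde = gaussian_kde(pts.T)  # Scott's rule
    dens = kde(pts.T)
    order = np.sort(dens)[::-1]
    k = int(np.ceil(level * len(pts))) - 1
    threshold = float(order[min(k, len(order) - 1)])

    pad = 4.0 * pts.std(axis=0) + 1e-6
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    xs = np.linspace(x0, x1, grid_n)
    ys = np.linspace(y0, y1, grid_n)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    ZZ = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(grid_n, grid_n)
    from skimage import measure

    raw = measure.find_contours(ZZ, threshold)
    contours = []
    for c in raw:
        cx = np.interp(c[:, 0], np.arange(grid_n), xs)
        cy = np.interp(c[:, 1], np.arange(grid_n), ys)
        poly = np.column_stack([cx, cy])
        if not np.allclose(poly[0], poly[-1]):
            poly = np.vstack([poly, poly[0]])
        contours.append(poly)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    area = float(np.count_nonzero(ZZ >= threshold) * cell)
    return ConfidenceRegion(
        age=age,
        level=level,
        contours=contours,
        bootstrap_points=pts,
        threshold=threshold,
        area=area,
        _kde=kde,
        _center=center,
    )


def bootstrap_mean_regions(
    sample: LongitudinalSample,
    ages=DEFAULT_REGION_AGES,
    n_boot: int = 400,
    level: float = 0.95,
    seed: int | None = None,
    bandwidth: float | None = None,
    options: RFPCAOptions | None = None,
    max_failure_rate: float = 0.10,
) -> list[ConfidenceRegion]:
    """Bootstrap confidence regions for the mean composition at fixed ages.

    Subjects are resampled with replacement ``n_boot`` times; each replicate
    re-estimates the mean function only (the regions concern the mean, and
    re-running the full eigenanalysis per replicate would change nothing
    for them), records the mean composition at each age, and the per-age
    point clouds are turned into highest-density KDE regions in ternary
    coordinates.  Failed replicates are skipped with a warning; more than
    ``max_failure_rate`` failures aborts.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = sample.domain
    if np.any(ages < lo) or np.any(ages > hi):
        raise ModelError(f"requested ages outside the data range [{lo:.3g}, {hi:.3g}]")
    options = options or RFPCAOptions()
    if bandwidth is None:
        # deliberate undersmoothing (half the CV bandwidth): smoothing bias
        # recenters bootstrap regions away from the truth, so inference-grade
        # mean estimates trade a little variance for much less bias
        bw_cv, _ = default_bandwidths(sample, options)
        bandwidth = 0.5 * bw_cv
    rng = np.random.default_rng(seed)
    n = sample.n_subjects

    points = np.empty((n_boot, len(ages), 3))
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot = sample.subset(idx)
            mu_b = mean_at_times(boot, ages, bandwidth, max_widen=options.max_widen)
            points[b] = geo.sphere_to_comp(geo.project_to_positive_segment(mu_b))
        except Exception as e:  # noqa: BLE001 - replicate-level resilience
            failures += 1
            points[b] = np.nan
            warnings.warn(f"bootstrap replicate {b} failed: {e}", stacklevel=2)
    if failures > max_failure_rate * n_boot:
        raise ModelError(
            f"{failures}/{n_boot} bootstrap replicates failed "
            f"(> {max_failure_rate:.0%}); aborting"
        )

    regions = []
    for j, age in enumerate(ages):
        comp = points[:, j, :]
        comp = comp[~np.isnan(comp).any(axis=1)]
        pts = ternary_coords(comp)
        regions.append(_region_from_points(float(age), level, pts))
    return regions
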