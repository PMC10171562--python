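"""Random-intercept linear mixed model baseline and the holdout benchmark.

The comparison baseline fits, for each tissue separately, the standard
random-intercept model

    y_ij = a0 + a1 t_ij + b_i + e_ij,      b_i ~ (0, sigma_b²),  e_ij ~ (0, sigma_e²),

by maximum likelihood: the variance ratio r = sigma_b² / sigma_e² is
profiled out with a 1-D bounded optimization, with GLS fixed effects and a
closed-form residual variance at each ratio.  Random slopes are deliberately
excluded — with mostly one or two visits per subject they are not
identifiable.  Subject-level prediction uses the shrinkage BLUP
``b_i = [sigma_b² m / (sigma_b² m + sigma_e²)] * mean(history residuals)``.

The holdout benchmark mirrors an out-of-sample forecasting task: for every
subject with at least three scans, the latest observation is dropped, both
the sphere FPCA model and the per-tissue LMMs are refitted on the remaining
data, and the dropped composition is predicted.  Errors are Fisher–Rao
distances, averaged per method and scaled by the maximum pairwise
Fisher–Rao distance among all observed compositions (a scale-free number
comparable across datasets).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from . import geometry as geo
from .exceptions import ModelError
from .rfpca import (
    LongitudinalSample,
    RFPCAOptions,
    default_bandwidths,
    fit_rfpca,
    predict_at_age,
)

__all__ = [
    "LMMFit",
    "PredictionBenchmark",
    "fit_random_intercept_lmm",
    "lmm_predict",
    "random_intercept_loglik",
    "holdout_benchmark",
]


@dataclass
class LMMFit:
    """Maximum-likelihood random-intercept fit for one response."""

    intercept: float
    slope: float
    var_intercept: float  # sigma_b^2
    var_resid: float  # sigma_e^2
    blups: dict  # subject id -> shrunk random intercept
    loglik: float

    def fixed_prediction(self, age) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def _group_stats(times, values, subject_ids):
    times = np.asarray(times, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    subject_ids = np.asarray(subject_ids)
    if not (len(times) == len(values) == len(subject_ids)):
        raise ModelError("times, values, subject_ids must have equal length")
    uniq, inv = np.unique(subject_ids, return_inverse=True)
    groups = [np.where(inv == g)[0] for g in range(len(uniq))]
    return times, values, uniq, groups


def random_intercept_loglik(
    intercept, slope, var_intercept, var_resid, times, values, subject_ids
) -> float:
    """Gaussian log-likelihood of the random-intercept model at given parameters."""
    times, values, uniq, groups = _group_stats(times, values, subject_ids)
    if var_resid <= 0:
        raise ModelError("var_resid must be positive")
    ll = 0.0
    for rows in groups:
        r = values[rows] - intercept - slope * times[rows]
        m = len(rows)
        # V = var_resid I + var_intercept J; Woodbury inverse and determinant
        c = var_intercept / (var_resid + m * var_intercept)
        quad = (r @ r - c * r.sum() ** 2) / var_resid
        logdet = m * np.log(var_resid) + np.log1p(m * var_intercept / var_resid)
        ll += -0.5 * (m * np.log(2 * np.pi) + logdet + quad)
    return float(ll)


def fit_random_intercept_lmm(times, values, subject_ids) -> LMMFit:
    """Profile-likelihood ML fit of ``y = a0 + a1 t + b_i + e``.

    For a fixed variance ratio ``r`` the fixed effects are GLS and the
    residual variance has a closed form, leaving a smooth 1-D criterion in
    ``r`` that is minimized on a log scale (plus the r = 0 boundary).
    """
    times, values, uniq, groups = _group_stats(times, values, subject_ids)
    n_obs = len(times)
    if len(uniq) < 2:
        raise ModelError("need at least two subjects")
    if n_obs < 3:
        raise ModelError("need at least three observations")
    if np.ptp(times) <= 0:
        raise ModelError("all observation times identical: slope not identifiable")

    X = np.column_stack([np.ones(n_obs), times])
    # per-subject sufficient statistics
    XtX_i = [X[rows].T @ X[rows] for rows in groups]
    Xty_i = [X[rows].T @ values[rows] for rows in groups]
    Sx_i = [X[rows].sum(axis=0) for rows in groups]
    Sy_i = [values[rows].sum() for rows in groups]
    yy_i = [values[rows] @ values[rows] for rows in groups]
    m_i = np.array([len(rows) for rows in groups])

    def profile(r: float):
        """GLS fit at variance ratio r; returns (negative loglik, beta, s2e)."""
        A = np.zeros((2, 2))
        b = np.zeros(2)
        yy = 0.0
        for XtX, Xty, Sx, Sy, yy_s, m in zip(XtX_i, Xty_i, Sx_i, Sy_i, yy_i, m_i):
            c = r / (1.0 + m * r)
            A += XtX - c * np.outer(Sx, Sx)
            b += Xty - c * Sy * Sx
            yy += yy_s - c * Sy * Sy
        beta = np.linalg.solve(A, b)
        rss = yy - 2.0 * beta @ b + beta @ A @ beta
        rss = max(rss, 0.0)
        s2e = rss / n_obs
        if s2e <= 0:
            return -np.inf, beta, 0.0
        logdet = float(np.sum(np.log1p(m_i * r)))
        nll = 0.5 * (n_obs * np.log(s2e) + logdet + n_obs * (1.0 + np.log(2 * np.pi)))
        return nll, beta, s2e

    # degenerate exact-fit shortcut: data exactly on a line
    beta_ols, rss_ols, *_ = np.linalg.lstsq(X, values, rcond=None)
    scale = float(np.var(values)) + 1e-300
    rss0 = float(rss_ols[0]) if len(rss_ols) else float(
        np.sum((values - X @ beta_ols) ** 2)
    )
    if rss0 / n_obs <= 1e-12 * scale + 1e-300:
        blups = {u: 0.0 for u in uniq}
        return LMMFit(float(beta_ols[0]), float(beta_ols[1]), 0.0, rss0 / n_obs, blups, np.inf)

    res = minimize_scalar(
        lambda u: profile(np.exp(u))[0],
        bounds=(-14.0, 10.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise ModelError(f"profile-likelihood optimization failed: {res.message}")
    cand = [(profile(0.0)[0], 0.0), (res.fun, float(np.exp(res.x)))]
    nll_best, r_best = min(cand, key=lambda t: t[0])
    _, beta, s2e = profile(r_best)
    s2b = r_best * s2e

    blups = {}
    for u, rows in zip(uniq, groups):
        resid = values[rows] - beta[0] - beta[1] * times[rows]
        m = len(rows)
        shrink = s2b * m / (s2b * m + s2e) if (s2b * m + s2e) > 0 else 0.0
        blups[u] = float(shrink * resid.mean())
    return LMMFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        var_intercept=float(s2b),
        var_resid=float(s2e),
        blups=blups,
        loglik=float(-nll_best),
    )


def lmm_predict(fit: LMMFit, history_times, history_values, age: float) -> float:
    """BLUP prediction at ``age`` given a subject's history.

    Empty history falls back to the population line; otherwise the random
    intercept is the shrunk mean residual of the history.
    """
    history_times = np.asarray(history_times, dtype=float).ravel()
    history_values = np.asarray(history_values, dtype=float).ravel()
    pred = fit.intercept + fit.slope * float(age)
    m = len(history_times)
    if m == 0 or fit.var_intercept <= 0:
        return float(pred)
    resid = history_values - fit.intercept - fit.slope * history_times
    shrink = fit.var_intercept * m / (fit.var_intercept * m + fit.var_resid)
    return float(pred + shrink * resid.mean())


# ---------------------------------------------------------------------------
# holdout benchmark


@dataclass
class PredictionBenchmark:
    """Drop-latest-scan benchmark results for both prediction methods.

    Scaled averages divide the mean Fisher–Rao error by the maximum pairwise
    Fisher–Rao distance among *all* observed compositions of the full
    sample.  The same subjects (those with >= 3 scans) enter both methods.
    """

    subject_ids: list
    holdout_ages: np.ndarray
    errors_rfpca: np.ndarray
    errors_lmm: np.ndarray
    max_pairwise_distance: float

    @property
    def average_rfpca(self) -> float:
        return float(self.errors_rfpca.mean())

    @property
    def average_lmm(self) -> float:
        return float(self.errors_lmm.mean())

    @property
    def scaled_rfpca(self) -> float:
        return self.average_rfpca / self.max_pairwise_distance

    @property
    def scaled_lmm(self) -> float:
        return self.average_lmm / self.max_pairwise_distance

    def to_dict(self) -> dict:
        return {
            "subjects": [
                {
                    "subject_id": str(s),
                    "holdout_age": float(a),
                    "error_rfpca": float(er),
                    "error_lmm": float(el),
                }
                for s, a, er, el in zip(
                    self.subject_ids, self.holdout_ages, self.errors_rfpca, self.errors_lmm
                )
            ],
            "n_subjects": len(self.subject_ids),
            "average_rfpca": self.average_rfpca,
            "average_lmm": self.average_lmm,
            "scaled_rfpca": self.scaled_rfpca,
            "scaled_lmm": self.scaled_lmm,
            "max_pairwise_distance": self.max_pairwise_distance,
        }

    def to_table(self) -> str:
        """Tab-delimited report with a summary row."""
        lines = ["subject_id\tholdout_age\terror_rfpca\terror_lmm"]
        for s, a, er, el in zip(
            self.subject_ids, self.holdout_ages, self.errors_rfpca, self.errors_lmm
        ):
            lines.append(f"{s}\t{a:.6g}\t{er:.6g}\t{el:.6g}")
        lines.append(
            f"scaled_average\t-\t{self.scaled_rfpca:.6g}\t{self.scaled_lmm:.6g}"
        )
        return "\n".join(lines) + "\n"


def _fit_lmm_per_tissue(sample: LongitudinalSample, skip: tuple | None = None):
    """Per-tissue random-intercept fits on the proportions of a sample.

    ``skip = (subject_index, obs_index)`` excludes one observation (the
    held-out scan).
    """
    rows_t, rows_y, rows_id = [], [], []
    for i in range(sample.n_subjects):
        mask = np.ones(len(sample.times[i]), dtype=bool)
        if skip is not None and skip[0] == i:
            mask[skip[1]] = False
        if not mask.any():
            continue
        rows_t.append(sample.times[i][mask])
        rows_y.append(geo.sphere_to_comp(sample.values[i][mask]))
        rows_id.extend([sample.ids[i]] * int(mask.sum()))
    t = np.concatenate(rows_t)
    comps = np.vstack(rows_y)
    ids = np.asarray(rows_id)
    return [fit_random_intercept_lmm(t, comps[:, d], ids) for d in range(3)]


def _lmm_composition_prediction(
    fits, history_times, history_comps, age: float
) -> np.ndarray:
    """Per-tissue LMM predictions combined into a composition.

    Predictions are floored at 1e-6 and renormalized to sum to one, the
    minimal repair that keeps the output a valid composition.
    """
    raw = np.array(
        [
            lmm_predict(fits[d], history_times, history_comps[:, d], age)
            for d in range(3)
        ]
    )
    raw = np.maximum(raw, 1e-6)
    return raw / raw.sum()


def holdout_benchmark(
    sample: LongitudinalSample,
    options: RFPCAOptions | None = None,
    min_scans: int = 3,
) -> PredictionBenchmark:
    """Drop-latest-scan prediction benchmark comparing sphere FPCA and LMM.

    For each subject with at least ``min_scans`` scans, the last-in-time
    observation (ties broken by input order) is dropped, both models are
    refitted on everything else, and the dropped composition is predicted
    from the subject's remaining history.  Bandwidths are resolved once on
    the full sample and reused across the leave-one-out refits.
    """
    options = options or RFPCAOptions()
    eligible = [i for i in range(sample.n_subjects) if len(sample.times[i]) >= min_scans]
    if not eligible:
        raise ModelError(f"no subject has >= {min_scans} scans")

    # scale: max pairwise Fisher-Rao distance among all observed compositions
    _, _, Y = sample.stacked()
    max_pair = float(np.arccos(np.clip(1.0 - pdist(Y, "cosine"), -1.0, 1.0)).max())
    if max_pair <= 0:
        raise ModelError("degenerate sample: all observed compositions identical")

    bw_mean, bw_cov = default_bandwidths(sample, options)
    lo, hi = sample.domain
    fixed = dataclasses.replace(
        options, bw_mean=bw_mean, bw_cov=bw_cov, domain=(lo, hi)
    )

    ids_out, ages_out, err_r, err_l = [], [], [], []
    for i in eligible:
        j = int(np.argmax(sample.times[i]))  # latest scan; argmax keeps first on ties
        age = float(sample.times[i][j])
        truth_comp = geo.sphere_to_comp(sample.values[i][j])
        train = sample.drop_observation(i, j)
        hist_t = train.times[i]
        hist_v = train.values[i]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = fit_rfpca(train, fixed)
            pred_r = predict_at_age(fitted, hist_t, hist_v, age)
        fits = _fit_lmm_per_tissue(sample, skip=(i, j))
        pred_l = _lmm_composition_prediction(fits, hist_t, geo.sphere_to_comp(hist_v), age)

        ids_out.append(sample.ids[i])
        ages_out.append(age)
        err_r.append(float(geo.fisher_rao_distance(pred_r, truth_comp)))
        err_l.append(float(geo.fisher_rao_distance(pred_l, truth_comp)))

    return PredictionBenchmark(
        subject_ids=ids_out,
        holdout_ages=np.array(ages_out),
        errors_rfpca=np.array(err_r),
        errors_lmm=np.array(err_l),
        max_pairwise_distance=max_pair,
    )
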