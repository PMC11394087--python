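"""Composition inference: bootstrap goodness-of-fit and presence-length models.

Two questions about a pooled diet are answered here.

*Is consumption even across prey categories?*  A chi-square goodness-of-fit
statistic against uniform expected counts E_i = T/S (S observed categories,
T prey items) is referred to a bootstrap null distribution: each of B
iterations draws T items with replacement from the uniform category
distribution and recomputes the statistic.  The p value uses the
add-one convention p = (1 + #{chi2_rep >= chi2_obs}) / (1 + B), so it is
never exactly zero.  Per-category standardized residuals
r_i = (O_i - E_i) / sqrt(E_i) localise the departure; |r| > 1.96 flags a
category at the 0.05 level.

*Does a prey item's presence shift with body size?*  Per category, presence
(0/1 per stomach) is regressed on total length with a logistic model
logit P = b0 + b1 * TL, fitted by iteratively reweighted least squares with
step-halving (monotone deviance).  TL is centred at its sample mean for
conditioning; reported coefficients are on the raw TL scale (b1 per mm).
The fit is compared to the intercept-only model with a 1-df likelihood-ratio
chi-square.  One-level outcomes and (quasi-)complete separation yield a
flagged non-estimable result rather than a forced finite fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, ValidationError

RESIDUAL_THRESHOLD = 1.96


@dataclass(frozen=True)
class GofResult:
    """Bootstrap chi-square goodness-of-fit result on pooled prey counts."""

    categories: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    residuals: np.ndarray
    chi2: float
    p: float
    iterations: int
    seed: int | None

    def to_dict(self) -> dict:
        """JSON-ready representation with per-category accounting."""
        return {
            "chi2_obs": self.chi2,
            "p": self.p,
            "iterations": self.iterations,
            "seed": self.seed,
            "categories": [
                {
                    "category": c,
                    "observed": float(o),
                    "expected": float(e),
                    "residual": float(r),
                    "flag": f,
                }
                for c, o, e, r, f in zip(
                    self.categories,
                    self.observed,
                    self.expected,
                    self.residuals,
                    residual_flags(self).values(),
                )
            ],
        }


def _chi2_stat(obs: np.ndarray, expected: np.ndarray) -> np.ndarray:
    return np.sum((obs - expected) ** 2 / expected, axis=-1)


def bootstrap_gof(
    counts: Sequence[int] | Mapping[str, int] | pd.Series,
    iterations: int = 1000,
    *,
    expected_proportions: Sequence[float] | None = None,
    seed: int | None = None,
) -> GofResult:
    """Bootstrap chi-square goodness-of-fit test on pooled category counts.

    The null is uniform consumption over the S observed categories unless
    ``expected_proportions`` supplies other expected shares.  The resampling
    unit is the individual prey item (a multinomial draw of T items per
    iteration); see :func:`bootstrap_gof_stomach` for stomach-level
    resampling.  Bit-for-bit reproducible given ``seed``.
    """
    if isinstance(counts, Mapping):
        counts = pd.Series(counts)
    if isinstance(counts, pd.Series):
        categories = tuple(str(c) for c in counts.index)
        obs = counts.to_numpy(dtype=float)
    else:
        obs = np.asarray(counts, dtype=float)
        categories = tuple(f"cat{i + 1}" for i in range(obs.size))
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    n_cat = obs.size
    if n_cat < 2:
        raise DegenerateTestError("goodness-of-fit needs >= 2 categories")
    total = obs.sum()
    if total <= 0:
        raise DegenerateTestError("goodness-of-fit needs at least one prey item")
    if iterations < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    if expected_proportions is None:
        probs = np.full(n_cat, 1.0 / n_cat)
    else:
        probs = np.asarray(expected_proportions, dtype=float)
        if probs.size != n_cat or (probs <= 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("expected_proportions must be positive and sum to 1")
    expected = total * probs
    chi2_obs = float(_chi2_stat(obs, expected))
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(int(total), probs, size=iterations).astype(float)
    chi2_rep = _chi2_stat(reps, expected)
    p = (1 + int(np.sum(chi2_rep >= chi2_obs))) / (1 + iterations)
    residuals = (obs - expected) / np.sqrt(expected)
    return GofResult(
        categories=categories,
        observed=obs,
        expected=expected,
        residuals=residuals,
        chi2=chi2_obs,
        p=float(p),
        iterations=iterations,
        seed=seed,
    )


def bootstrap_gof_stomach(
    stomach_counts: pd.DataFrame,
    iterations: int = 1000,
    *,
    expected_proportions: Sequence[float] | None = None,
    seed: int | None = None,
) -> GofResult:
    """Goodness-of-fit variant resampling whole stomachs with replacement.

    Respects within-stomach prey clustering; each replicate resamples the
    stomach rows, pools counts and recomputes the statistic against expected
    shares applied to the replicate's own total.
    """
    mat = np.asarray(stomach_counts, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise DegenerateTestError("need >= 2 stomachs for stomach-level resampling")
    categories = tuple(str(c) for c in stomach_counts.columns)
    obs = mat.sum(axis=0)
    n_cat = obs.size
    if n_cat < 2:
        raise DegenerateTestError("goodness-of-fit needs >= 2 categories")
    total = obs.sum()
    if total <= 0:
        raise DegenerateTestError("goodness-of-fit needs at least one prey item")
    if expected_proportions is None:
        probs = np.full(n_cat, 1.0 / n_cat)
    else:
        probs = np.asarray(expected_proportions, dtype=float)
    expected = total * probs
    chi2_obs = float(_chi2_stat(obs, expected))
    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    idx = rng.integers(0, n, size=(iterations, n))
    pooled = mat[idx].sum(axis=1)  # (iterations, S)
    rep_totals = pooled.sum(axis=1)
    ok = rep_totals > 0
    rep_expected = rep_totals[ok, None] * probs
    chi2_rep = _chi2_stat(pooled[ok], rep_expected)
    p = (1 + int(np.sum(chi2_rep >= chi2_obs))) / (1 + chi2_rep.size)
    residuals = (obs - expected) / np.sqrt(expected)
    return GofResult(
        categories=categories,
        observed=obs,
        expected=expected,
        residuals=residuals,
        chi2=chi2_obs,
        p=float(p),
        iterations=iterations,
        seed=seed,
    )


def residual_flags(gof: GofResult, threshold: float = RESIDUAL_THRESHOLD) -> dict[str, str]:
    """Per-category departure flags from standardized residuals.

    ``over`` for r > threshold, ``under`` for r < -threshold, else ``none``.
    """
    flags = {}
    for cat, r in zip(gof.categories, gof.residuals):
        if r > threshold:
            flags[cat] = "over"
        elif r < -threshold:
            flags[cat] = "under"
        else:
            flags[cat] = "none"
    return flags


def rii_filter(metrics: pd.DataFrame, threshold: float = 1.0) -> list[str]:
    """Categories whose RII reaches ``threshold`` in at least one size class.

    The comparison is inclusive (RII == threshold passes), matching the
    convention of retaining items of at least marginal importance for
    presence-length modelling.  Order of first appearance is preserved.
    """
    out: list[str] = []
    for cat in metrics["category"].drop_duplicates():
        if (metrics.loc[metrics["category"] == cat, "rii"] >= threshold).any():
            out.append(cat)
    return out


@dataclass(frozen=True)
class LogisticFit:
    """Logistic presence-length fit for one prey category.

    Coefficients are on the raw TL scale (``beta1`` per mm); ``cov`` is the
    2x2 observed-information covariance on the centred scale used internally,
    with ``tl_mean`` recording the centring constant.  ``chi2``/``p`` are the
    1-df likelihood-ratio test against the intercept-only model.
    """

    category: str | None
    n: int
    estimable: bool
    beta0: float = float("nan")
    beta1: float = float("nan")
    se_beta0: float = float("nan")
    se_beta1: float = float("nan")
    ll_full: float = float("nan")
    ll_null: float = float("nan")
    chi2: float = float("nan")
    p: float = float("nan")
    converged: bool = False
    n_iter: int = 0
    tl_mean: float = float("nan")
    cov: np.ndarray | None = None
    reason: str | None = None


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log-likelihood via log1p(exp) with sign trick for numerical range
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_presence(
    presence: Sequence[int] | np.ndarray,
    tl_mm: Sequence[float] | np.ndarray,
    category: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of presence against total length.

    IRLS with step-halving: the deviance never increases across iterations;
    convergence when the relative log-likelihood change drops below ``tol``.
    Returns a non-estimable flagged result (no finite fit forced) when the
    outcome has one level or the presence/absence TL ranges are separable.
    """
    y = np.asarray(presence, dtype=float)
    x_raw = np.asarray(tl_mm, dtype=float)
    if y.shape != x_raw.shape or y.ndim != 1:
        raise ValueError("presence and tl_mm must be equal-length 1-d sequences")
    if y.size < 2:
        raise DegenerateTestError("need at least 2 stomachs")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("presence must be coded 0/1")
    n = y.size
    if y.min() == y.max():
        return LogisticFit(
            category=category, n=n, estimable=False, reason="one-level outcome"
        )
    # quasi-/complete separation in one covariate: ordered outcome groups
    if x_raw[y == 0].max() <= x_raw[y == 1].min() or x_raw[y == 1].max() <= x_raw[y == 0].min():
        return LogisticFit(
            category=category, n=n, estimable=False, reason="separation"
        )
    mean = float(x_raw.mean())
    x = x_raw - mean
    X = np.column_stack([np.ones(n), x])
    ybar = y.mean()
    beta = np.array([np.log(ybar / (1 - ybar)), 0.0])
    ll = _bernoulli_ll(y, X @ beta)
    ll_null = ll  # intercept-only MLE is logit(ybar) when slope = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        step = np.linalg.solve(X.T @ wx, X.T @ (w * z)) - beta
        # step-halving keeps the deviance monotone non-increasing
        scale = 1.0
        new_ll = _bernoulli_ll(y, X @ (beta + step))
        while new_ll < ll and scale > 1e-8:
            scale /= 2.0
            new_ll = _bernoulli_ll(y, X @ (beta + scale * step))
        beta = beta + scale * step
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov_centred = np.linalg.inv(X.T @ (X * w[:, None]))
    # back-transform to raw TL scale: b0_raw = b0c - b1 * mean
    jac = np.array([[1.0, -mean], [0.0, 1.0]])
    cov_raw = jac @ cov_centred @ jac.T
    chi2 = max(0.0, 2.0 * (ll - ll_null))
    return LogisticFit(
        category=category,
        n=n,
        estimable=True,
        beta0=float(beta[0] - beta[1] * mean),
        beta1=float(beta[1]),
        se_beta0=float(np.sqrt(cov_raw[0, 0])),
        se_beta1=float(np.sqrt(cov_raw[1, 1])),
        ll_full=float(ll),
        ll_null=float(ll_null),
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df=1)),
        converged=converged,
        n_iter=it,
        tl_mean=mean,
        cov=cov_centred,
    )


def presence_curve(
    fit: LogisticFit,
    tl_grid: Sequence[float] | np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fitted presence-probability curve with a pointwise Wald band.

    The interval is computed on the linear predictor and mapped through the
    inverse logit, so the band stays inside (0, 1).
    """
    if not fit.estimable:
        raise ValueError("cannot build a curve from a non-estimable fit")
    tl = np.asarray(tl_grid, dtype=float)
    x = tl - fit.tl_mean
    b0c = fit.beta0 + fit.beta1 * fit.tl_mean
    eta = b0c + fit.beta1 * x
    v = (
        fit.cov[0, 0]
        + 2.0 * x * fit.cov[0, 1]
        + x**2 * fit.cov[1, 1]
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(v)
    expit = lambda e: 1.0 / (1.0 + np.exp(-e))
    return pd.DataFrame(
        {
            "tl_mm": tl,
            "probability": expit(eta),
            "lower": expit(eta - half),
            "upper": expit(eta + half),
        }
    )


def logistic_screen(
    presence_matrix: pd.DataFrame,
    tl_mm: Sequence[float] | np.ndarray,
    categories: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, LogisticFit]]:
    """Fit presence-vs-TL per category; returns a tidy summary and the fits.

    ``presence_matrix`` is stomach-by-category (counts or 0/1; any count > 0
    is presence), row-aligned with ``tl_mm``.
    """
    tl = np.asarray(tl_mm, dtype=float)
    cats = list(categories) if categories is not None else list(presence_matrix.columns)
    rows = []
    fits: dict[str, LogisticFit] = {}
    for cat in cats:
        y = (presence_matrix[cat].to_numpy() > 0).astype(float)
        fit = fit_logistic_presence(y, tl, category=cat)
        fits[cat] = fit
        rows.append(
            {
                "category": cat,
                "n": fit.n,
                "estimable": fit.estimable,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "se_beta1": fit.se_beta1,
                "chi2": fit.chi2,
                "p": fit.p,
            }
        )
    return pd.DataFrame(rows), fits
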