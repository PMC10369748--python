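"""Summary-data MR estimators.

All estimators operate on a :class:`~mviv.instruments.HarmonisedSet` of
variant-exposure (``b_x``), variant-outcome (``b_y``) and optionally
variant-covariate (``b_p``) associations.

Univariable suite
-----------------
* :func:`ivw` — intercept-free weighted regression of ``b_y`` on ``b_x`` with
  weights ``1/se_y^2``; algebraically the inverse-variance meta-analysis of
  the per-variant Wald ratios ``b_y/b_x``.
* :func:`mr_egger` — the same regression *with* an intercept after orienting
  every ``b_x >= 0``; the intercept estimates directional pleiotropy.
* :func:`weighted_median` / :func:`weighted_mode` — pleiotropy-robust
  order/mode statistics of the Wald ratios, bootstrap SEs.
* :func:`cochran_q` — heterogeneity of the Wald ratios about a value.

Multivariable suite
-------------------
* :func:`mv_ivw` — intercept-free weighted regression of ``b_y`` on
  ``(b_x, b_p)``; the exposure coefficient is the direct effect of the
  exposure conditional on the covariate.
* :func:`mv_egger`, :func:`mv_median`, :func:`mv_mode` — multivariable
  extensions (median/mode act on conditional Wald ratios obtained by
  weighted residualisation on the other exposure column).
* :func:`conditional_f` — instrument strength for one exposure given the
  others.

Conventions (documented defaults, see docs/methods.md): multiplicative
overdispersion (random-effects) scaling of regression SEs floored at 1;
first-order Wald-ratio SEs; normal 95% intervals (estimate ∓ 1.96·se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, EmptyResultError
from .instruments import HarmonisedSet

__all__ = [
    "MRResult",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "mv_ivw",
    "mv_egger",
    "mv_median",
    "mv_mode",
    "conditional_f",
    "results_to_frame",
]

_Z95 = 1.959963984540054  # Phi^-1(0.975)

EXPOSURE_LABELS = ("exposure", "covariate")


@dataclass
class MRResult:
    """One estimator's output for one exposure."""

    method: str
    exposure: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_statistic: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    conditional_f: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _result(method, exposure, est, se, n_snps, **extra) -> MRResult:
    z = est / se if se > 0 else np.inf * np.sign(est)
    return MRResult(
        method=method,
        exposure=exposure,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - _Z95 * se),
        ci_high=float(est + _Z95 * se),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        n_snps=int(n_snps),
        **extra,
    )


def results_to_frame(results: Sequence[MRResult]) -> pd.DataFrame:
    """Tidy one-row-per-result table mirroring the usual MR report layout."""
    return pd.DataFrame([r.to_dict() for r in results])


# ------------------------------------------------------------------ wald ratios
def wald_ratios(h: HarmonisedSet, min_abs_beta: float = 0.0):
    """Per-variant ratio estimates ``b_y/b_x`` with first-order SEs.

    Variants with ``|b_x| <= min_abs_beta`` (default: exactly zero) are
    dropped; the number dropped is returned alongside.

    Returns
    -------
    (ratios, ratio_se, kept_mask)
    """
    bx = np.asarray(h.exposure_beta, float)
    by = np.asarray(h.outcome_beta, float)
    sey = np.asarray(h.outcome_se, float)
    keep = np.abs(bx) > min_abs_beta
    ratios = by[keep] / bx[keep]
    se = sey[keep] / np.abs(bx[keep])
    return ratios, se, keep


def _weighted_no_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                           cond_limit: float = 1e8):
    """WLS with weights ``w``.

    Identically-zero columns carry no information: they get coefficient 0 and
    an infinite SE rather than poisoning the solve (this is what makes the
    exact multivariable-to-univariable reduction hold). Collinearity among
    the informative columns raises :class:`CollinearityError` naming the
    condition number.

    Returns ``(coef, cov_unscaled, rss, n_fitted)``.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    k = X.shape[1]
    live = np.any(Xw != 0.0, axis=0)
    Xl = Xw[:, live]
    cond = np.linalg.cond(Xl) if live.any() else np.inf
    if not np.isfinite(cond) or cond > cond_limit:
        raise CollinearityError(cond)
    xtx = Xl.T @ Xl
    coef_l = np.linalg.solve(xtx, Xl.T @ yw)
    resid = yw - Xl @ coef_l
    rss = float(resid @ resid)
    cov_l = np.linalg.inv(xtx)
    coef = np.zeros(k)
    coef[live] = coef_l
    cov_unscaled = np.full((k, k), 0.0)
    np.fill_diagonal(cov_unscaled, np.inf)
    cov_unscaled[np.ix_(live, live)] = cov_l
    return coef, cov_unscaled, rss, int(live.sum())


def _overdispersion(rss: float, dof: int) -> float:
    """Multiplicative random-effects scale, floored at 1."""
    if dof <= 0:
        return 1.0
    return max(1.0, rss / dof)


# -------------------------------------------------------------------- univariable
def ivw(h: HarmonisedSet) -> MRResult:
    """Inverse-variance-weighted estimate (intercept-free WLS of b_y on b_x).

    Closed form ``sum(w b_x b_y) / sum(w b_x^2)`` with ``w = 1/se_y^2``;
    equals the fixed-effect meta-analysis of the Wald ratios. The SE carries
    the multiplicative overdispersion factor ``max(1, Q/(n-1))``.
    """
    if len(h) < 1:
        raise EmptyResultError("IVW needs at least one variant")
    bx = np.asarray(h.exposure_beta, float)
    by = np.asarray(h.outcome_beta, float)
    w = 1.0 / np.asarray(h.outcome_se, float) ** 2
    denom = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by)) / denom
    n = len(h)
    q = float(np.sum(w * (by - est * bx) ** 2))
    phi = _overdispersion(q, n - 1)
    se = math.sqrt(phi / denom)
    q_p = float(stats.chi2.sf(q, n - 1)) if n > 1 else float("nan")
    return _result("IVW", "exposure", est, se, n, q_statistic=q, q_pvalue=q_p)


def mr_egger(h: HarmonisedSet) -> MRResult:
    """MR-Egger regression: weighted regression of b_y on b_x with intercept.

    All variants are oriented so that ``b_x >= 0`` (flipping the paired
    ``b_y`` signs), making the fit invariant to arbitrary per-variant sign
    conventions. The slope is the causal estimate; the intercept is the
    directional-pleiotropy test.
    """
    n = len(h)
    if n < 3:
        raise EmptyResultError(f"MR-Egger needs >= 3 variants, got {n}")
    s = np.where(np.asarray(h.exposure_beta) < 0, -1.0, 1.0)
    bx = s * np.asarray(h.exposure_beta, float)
    by = s * np.asarray(h.outcome_beta, float)
    w = 1.0 / np.asarray(h.outcome_se, float) ** 2
    X = np.column_stack([np.ones(n), bx])
    coef, cov_u, rss, _ = _weighted_no_intercept(X, by, w)
    phi = _overdispersion(rss, n - 2)
    se = np.sqrt(phi * np.diag(cov_u))
    q_p = float(stats.chi2.sf(rss, n - 2))
    return _result(
        "MR-Egger", "exposure", coef[1], se[1], n,
        q_statistic=float(rss), q_pvalue=q_p,
        egger_intercept=float(coef[0]), egger_intercept_se=float(se[0]),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios``."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(h: HarmonisedSet, statistic, n_boot: int, seed) -> float:
    """Parametric bootstrap: redraw (b_x, b_p, b_y) from their normal
    sampling distributions and recompute ``statistic``."""
    rng = np.random.default_rng(seed)
    bx = np.asarray(h.exposure_beta, float)
    sex = np.asarray(h.exposure_se, float)
    by = np.asarray(h.outcome_beta, float)
    sey = np.asarray(h.outcome_se, float)
    bp = None if h.covariate_beta is None else np.asarray(h.covariate_beta, float)
    sep = None if h.covariate_se is None else np.asarray(h.covariate_se, float)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        hx = bx + sex * rng.standard_normal(len(bx))
        hy = by + sey * rng.standard_normal(len(by))
        hp = None if bp is None else bp + sep * rng.standard_normal(len(bp))
        vals[b] = statistic(hx, hy, hp, sey)
    return float(np.std(vals, ddof=1))


def weighted_median(h: HarmonisedSet, n_boot: int = 1000,
                    seed: int | None = 0) -> MRResult:
    """Weighted median of the Wald ratios (inverse-variance weights).

    Consistent when variants carrying at least half the weight are valid
    instruments. SE by parametric bootstrap of the betas.
    """
    if len(h) < 3:
        raise EmptyResultError("weighted median needs >= 3 variants")
    ratios, se_r, _ = wald_ratios(h)
    est = _weighted_median_point(ratios, 1.0 / se_r**2)

    def stat(hx, hy, hp, sey):
        keep = hx != 0
        r = hy[keep] / hx[keep]
        sr = sey[keep] / np.abs(hx[keep])
        return _weighted_median_point(r, 1.0 / sr**2)

    se = _bootstrap_se(h, stat, n_boot, seed)
    return _result("Weighted median", "exposure", est, se, len(h))


def _silverman_bandwidth(r: np.ndarray) -> float:
    """Modified Silverman rule on the ratio distribution (robust scale)."""
    n = len(r)
    sd = float(np.std(r, ddof=1)) if n > 1 else 0.0
    mad = float(np.median(np.abs(r - np.median(r)))) * 1.4826
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return 0.9 * s * n ** (-0.2)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth_factor: float, grid_size: int = 10_000) -> float:
    h = bandwidth_factor * _silverman_bandwidth(ratios)
    if h == 0.0 or not np.isfinite(h):
        # degenerate spread: the (weighted) mode is the most-weighted value
        vals, inv = np.unique(ratios, return_inverse=True)
        return float(vals[np.argmax(np.bincount(inv, weights=weights))])
    lo = ratios.min() - 3.0 * h
    hi = ratios.max() + 3.0 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonisedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int | None = 0,
                  grid_size: int = 10_000) -> MRResult:
    """Weighted mode of the Wald ratios (kernel-density argmax).

    A Gaussian kernel density over the ratios, weighted by inverse variance,
    with bandwidth ``bandwidth_factor`` times a modified Silverman rule; the
    estimate is the density argmax on a ``grid_size``-point grid padded by
    three bandwidths. Consistent when the largest group of variants sharing a
    ratio are valid (ZEMPA). SE by parametric bootstrap.
    """
    if len(h) < 3:
        raise EmptyResultError("weighted mode needs >= 3 variants")
    ratios, se_r, _ = wald_ratios(h)
    w = 1.0 / se_r**2
    est = _weighted_mode_point(ratios, w / w.sum(), bandwidth_factor, grid_size)

    def stat(hx, hy, hp, sey):
        keep = hx != 0
        r = hy[keep] / hx[keep]
        sr = sey[keep] / np.abs(hx[keep])
        wb = 1.0 / sr**2
        return _weighted_mode_point(r, wb / wb.sum(), bandwidth_factor, grid_size)

    se = _bootstrap_se(h, stat, n_boot, seed)
    return _result("Weighted mode", "exposure", est, se, len(h))


def cochran_q(h: HarmonisedSet, theta: float):
    """Cochran's Q of the Wald ratios about ``theta``.

    Returns ``(q, df, p)`` with ``q = sum w_j (ratio_j - theta)^2``,
    ``w_j = 1/se(ratio_j)^2`` and ``df = n - 1``.
    """
    ratios, se_r, _ = wald_ratios(h)
    n = len(ratios)
    if n < 2:
        raise EmptyResultError("Cochran's Q needs >= 2 variants")
    w = 1.0 / se_r**2
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = n - 1
    return q, df, float(stats.chi2.sf(q, df))


# ------------------------------------------------------------------ multivariable
def _require_mv(h: HarmonisedSet):
    if h.covariate_beta is None:
        raise EmptyResultError(
            "multivariable estimators need a covariate column in the harmonised set"
        )
    X = h.exposure_matrix()
    if len(h) <= X.shape[1]:
        raise EmptyResultError(
            f"{len(h)} variants cannot identify {X.shape[1]} exposures"
        )
    return X


def mv_ivw(h: HarmonisedSet) -> list[MRResult]:
    """Multivariable IVW: intercept-free WLS of b_y on (b_x, b_p).

    The coefficient on each exposure column is its direct effect conditional
    on the others. Returns one :class:`MRResult` per exposure, each carrying
    the shared multivariable Q and that exposure's conditional F-statistic.
    """
    X = _require_mv(h)
    by = np.asarray(h.outcome_beta, float)
    w = 1.0 / np.asarray(h.outcome_se, float) ** 2
    coef, cov_u, rss, n_fit = _weighted_no_intercept(X, by, w)
    n, k = X.shape
    phi = _overdispersion(rss, n - n_fit)
    ses = np.sqrt(phi * np.diag(cov_u))
    q_p = float(stats.chi2.sf(rss, n - n_fit))
    return [
        _result(
            "MV-IVW", EXPOSURE_LABELS[i], coef[i], ses[i], n,
            q_statistic=float(rss), q_pvalue=q_p,
            conditional_f=conditional_f(h, i),
        )
        for i in range(k)
    ]


def mv_egger(h: HarmonisedSet) -> list[MRResult]:
    """Multivariable MR-Egger: adds an intercept after orienting rows so the
    first exposure's b_x >= 0 (each row's betas share the flip)."""
    X = _require_mv(h)
    n, k = X.shape
    if n <= k + 1:
        raise EmptyResultError("MV-Egger needs more variants than exposures + 1")
    s = np.where(X[:, 0] < 0, -1.0, 1.0)
    Xo = X * s[:, None]
    by = s * np.asarray(h.outcome_beta, float)
    w = 1.0 / np.asarray(h.outcome_se, float) ** 2
    design = np.column_stack([np.ones(n), Xo])
    coef, cov_u, rss, n_fit = _weighted_no_intercept(design, by, w)
    phi = _overdispersion(rss, n - n_fit)
    ses = np.sqrt(phi * np.diag(cov_u))
    q_p = float(stats.chi2.sf(rss, n - n_fit))
    return [
        _result(
            "MV-Egger", EXPOSURE_LABELS[i], coef[i + 1], ses[i + 1], n,
            q_statistic=float(rss), q_pvalue=q_p,
            egger_intercept=float(coef[0]), egger_intercept_se=float(ses[0]),
        )
        for i in range(k)
    ]


def _conditional_ratios(X, by, sey, w, target: int):
    """Residualise b_y and the target column on the other exposure columns
    (weighted), returning conditional Wald ratios and first-order SEs."""
    n, k = X.shape
    others = np.delete(X, target, axis=1)
    sw = np.sqrt(w)
    if others.size:
        Zw = others * sw[:, None]
        # lstsq tolerates all-zero other columns (pinv solution: coef 0)
        coef_y, *_ = np.linalg.lstsq(Zw, by * sw, rcond=None)
        coef_x, *_ = np.linalg.lstsq(Zw, X[:, target] * sw, rcond=None)
        ry = by - others @ coef_y
        rx = X[:, target] - others @ coef_x
    else:
        ry, rx = by, X[:, target]
    keep = rx != 0
    return ry[keep] / rx[keep], sey[keep] / np.abs(rx[keep]), keep


def mv_median(h: HarmonisedSet, n_boot: int = 1000,
              seed: int | None = 0) -> list[MRResult]:
    """Multivariable weighted median via conditional Wald ratios.

    For each exposure, b_y and that exposure's betas are residualised on the
    other exposure columns (weights ``1/se_y^2``); the univariable weighted
    median machinery then runs on the conditional ratios.
    """
    X = _require_mv(h)
    by = np.asarray(h.outcome_beta, float)
    sey = np.asarray(h.outcome_se, float)
    w = 1.0 / sey**2
    out = []
    for i in range(X.shape[1]):
        r, sr, _ = _conditional_ratios(X, by, sey, w, i)
        if len(r) == 0:  # zero-information column: coefficient 0, no precision
            out.append(_result("MV-median", EXPOSURE_LABELS[i], 0.0,
                               float("inf"), len(h)))
            continue
        est = _weighted_median_point(r, 1.0 / sr**2)

        def stat(hx, hy, hp, sey_, _i=i):
            Xb = np.column_stack([hx, hp])
            rb, srb, _ = _conditional_ratios(Xb, hy, sey_, 1.0 / sey_**2, _i)
            return _weighted_median_point(rb, 1.0 / srb**2)

        se = _bootstrap_se(h, stat, n_boot, seed)
        out.append(_result("MV-median", EXPOSURE_LABELS[i], est, se, len(h)))
    return out


def mv_mode(h: HarmonisedSet, bandwidth_factor: float = 1.0,
            n_boot: int = 1000, seed: int | None = 0,
            grid_size: int = 10_000) -> list[MRResult]:
    """Multivariable weighted mode via conditional Wald ratios."""
    X = _require_mv(h)
    by = np.asarray(h.outcome_beta, float)
    sey = np.asarray(h.outcome_se, float)
    w = 1.0 / sey**2
    out = []
    for i in range(X.shape[1]):
        r, sr, _ = _conditional_ratios(X, by, sey, w, i)
        if len(r) == 0:
            out.append(_result("MV-mode", EXPOSURE_LABELS[i], 0.0,
                               float("inf"), len(h)))
            continue
        wi = 1.0 / sr**2
        est = _weighted_mode_point(r, wi / wi.sum(), bandwidth_factor, grid_size)

        def stat(hx, hy, hp, sey_, _i=i):
            Xb = np.column_stack([hx, hp])
            rb, srb, _ = _conditional_ratios(Xb, hy, sey_, 1.0 / sey_**2, _i)
            wb = 1.0 / srb**2
            return _weighted_mode_point(rb, wb / wb.sum(), bandwidth_factor, grid_size)

        se = _bootstrap_se(h, stat, n_boot, seed)
        out.append(_result("MV-mode", EXPOSURE_LABELS[i], est, se, len(h)))
    return out


def conditional_f(h: HarmonisedSet, exposure_index: int = 0) -> float:
    """Conditional instrument strength for one exposure given the others.

    The target exposure's betas are weighted-regressed on the other exposure
    columns (weights ``1/se_target^2``); the heterogeneity statistic of the
    residuals against zero, divided by ``n_snps`` minus the number of fitted
    parameters, is the conditional F. With a single exposure this reduces to
    the mean univariable F, ``mean((b_x/se_x)^2)``; perfectly collinear
    exposure columns give a conditional F of ~0.
    """
    X = h.exposure_matrix()
    n, k = X.shape
    if not 0 <= exposure_index < k:
        raise IndexError(f"exposure_index {exposure_index} out of range for {k} exposures")
    se_t = np.asarray(
        h.exposure_se if exposure_index == 0 else h.covariate_se, float
    )
    target = X[:, exposure_index]
    others = np.delete(X, exposure_index, axis=1)
    w = 1.0 / se_t**2
    p = others.shape[1]
    if p:
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(others * sw[:, None], target * sw, rcond=None)
        resid = target - others @ coef
    else:
        resid = target
    q = float(np.sum((resid / se_t) ** 2))
    dof = n - p
    if dof <= 0:
        raise EmptyResultError("too few variants for conditional F")
    return q / dof
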