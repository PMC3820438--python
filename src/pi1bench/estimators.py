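"""Estimators of pi0 (the proportion of non-differentially-expressed genes).

Three estimator classes are implemented:

* :func:`estimate_pi0_storey` — the smoother mixture-model method: the
  plug-in pi0(lambda) = #{p > lambda} / ((1 - lambda) G) evaluated on a
  lambda grid, smoothed with a natural cubic smoothing spline and read off
  at the largest lambda.
* :func:`estimate_pi0_convest` — the nonparametric MLE of a convex,
  decreasing P-value density: a mixture of the uniform density and
  triangular densities f_theta(p) = 2 (theta - p) / theta^2 on (0, theta),
  fitted by iterative component addition with a golden-section line search.
  pi0-hat is the fitted density at p = 1.
* :func:`estimate_pi0_empirical_null` — an empirical-null method that works
  directly on test statistics: the null scale is fitted by truncated
  maximum likelihood on the central bulk of |statistics| (half-normal null
  for a z input specification, scaled-t null for a t input), statistics are
  converted to two-sided null P-values, and pi0-hat is the Grenander
  density of those P-values read off near p = 1.

:func:`fdr_hat` assembles the mixture-model FDR estimate
FDR(alpha) = alpha * pi0 / F(alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize_scalar

from .perm_null import PValueVector
from .stats_core import TestStatisticVector

__all__ = [
    "Pi1Estimate",
    "ConvexDensityFit",
    "EmpiricalNullFit",
    "GrenanderDensity",
    "FdrEstimate",
    "estimate_pi0_storey",
    "estimate_pi0_convest",
    "grenander_density",
    "estimate_pi0_empirical_null",
    "fdr_hat",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.95, 0.05), 10)


@dataclass
class Pi1Estimate:
    """An estimate of pi0 / pi1 with method identifier and diagnostics."""

    pi0: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


@dataclass
class FdrEstimate:
    alpha: float
    pi0: float
    F_hat: float
    fdr: float | None
    no_discoveries: bool = False


def _extract_pvalues(pvals) -> np.ndarray:
    p = pvals.values if isinstance(pvals, PValueVector) else np.asarray(pvals, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite P-values")
    if p.min() <= 0 or p.max() > 1:
        raise ValueError("P-values must lie in (0, 1]")
    return p


# ---------------------------------------------------------------------------
# Storey smoother method


def _spline_with_df(x: np.ndarray, y: np.ndarray, df: float):
    """Natural cubic smoothing spline with effective degrees of freedom df.

    The smoothing parameter is calibrated by bisection on the trace of the
    smoother matrix (sum over basis responses evaluated at the data points).
    """
    n = len(x)

    def trace_df(lam: float) -> float:
        tr = 0.0
        eye = np.eye(n)
        for j in range(n):
            spl = make_smoothing_spline(x, eye[j], lam=lam)
            tr += float(spl(x[j]))
        return tr

    lo, hi = -10.0, 10.0  # log10(lam) bracket; df decreases with lam
    if trace_df(10.0**lo) < df:
        lam = 10.0**lo
    elif trace_df(10.0**hi) > df:
        lam = 10.0**hi
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if trace_df(10.0**mid) > df:
                lo = mid
            else:
                hi = mid
        lam = 10.0 ** (0.5 * (lo + hi))
    return make_smoothing_spline(x, y, lam=lam), lam


def estimate_pi0_storey(
    pvals,
    lambda_grid: np.ndarray | None = None,
    spline_df: int = 3,
) -> Pi1Estimate:
    """Smoother mixture-model estimate of pi0.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) G) is computed on the grid,
    a natural cubic smoothing spline with ``spline_df`` effective degrees of
    freedom is fitted to (lambda, pi0(lambda)), and pi0-hat is the spline
    value at max(lambda), clipped to [0, 1].
    """
    p = _extract_pvalues(pvals)
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.sort(np.asarray(lambda_grid, float))
    if lam.size and (lam.min() < 0 or lam.max() >= 1):
        raise ValueError("lambda grid must lie in [0, 1)")
    G = p.size
    pi0_lam = np.array([(p > l).sum() / ((1.0 - l) * G) for l in lam])
    if lam.size == 1:
        # single lambda: no smoothing, the plain plug-in estimator
        pi0 = float(np.clip(pi0_lam[0], 0.0, 1.0))
        return Pi1Estimate(
            pi0=pi0,
            method="storey_smoother",
            diagnostics={"lambda": lam, "pi0_lambda": pi0_lam, "spline_lam": None},
        )
    if lam.size < spline_df + 1:
        raise ValueError(
            f"lambda grid has {lam.size} points; need > spline_df={spline_df}"
        )
    if pi0_lam[-1] == 0:
        warnings.warn(
            "no P-values exceed max(lambda); pi0-hat is 0", RuntimeWarning, stacklevel=2
        )
        return Pi1Estimate(
            pi0=0.0,
            method="storey_smoother",
            diagnostics={"lambda": lam, "pi0_lambda": pi0_lam, "spline_lam": None},
        )
    spl, smooth_lam = _spline_with_df(lam, pi0_lam, float(spline_df))
    pi0 = float(np.clip(spl(lam[-1]), 0.0, 1.0))
    return Pi1Estimate(
        pi0=pi0,
        method="storey_smoother",
        diagnostics={
            "lambda": lam,
            "pi0_lambda": pi0_lam,
            "spline_values": np.asarray(spl(lam), float),
            "spline_lam": smooth_lam,
        },
    )


# ---------------------------------------------------------------------------
# Convex decreasing density NPMLE ("convest" class)


@dataclass
class ConvexDensityFit:
    """Mixture of the uniform density and triangular densities f_theta.

    f(p) = w0 * 1 + sum_j w_j * f_theta_j(p), with
    f_theta(p) = 2 (theta - p) / theta^2 for p < theta, else 0.
    Any such mixture is a convex, nonincreasing density on [0, 1] with unit
    mass, and f(1) = w0.
    """

    support_points: np.ndarray
    weights: np.ndarray
    w_uniform: float
    log_likelihood: float = np.nan

    def density_at(self, p) -> np.ndarray:
        p = np.atleast_1d(np.asarray(p, float))
        out = np.full(p.shape, self.w_uniform)
        for th, w in zip(self.support_points, self.weights):
            tri = np.where(p < th, 2.0 * (th - p) / th**2, 0.0)
            out = out + w * tri
        return out


def _triangle_matrix(thetas: np.ndarray, p: np.ndarray) -> np.ndarray:
    """f_theta(p) for all candidate thetas (rows) at all p (columns)."""
    th = thetas[:, None]
    return np.where(p[None, :] < th, 2.0 * (th - p[None, :]) / th**2, 0.0)


def _golden_section_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def _candidate_thetas(p: np.ndarray, max_candidates: int = 300) -> np.ndarray:
    uniq = np.unique(p)
    if uniq.size > max_candidates:
        qs = np.linspace(0.0, 1.0, max_candidates)
        uniq = np.unique(np.quantile(p, qs))
    return np.unique(np.concatenate([uniq, [1.0]]))


def estimate_pi0_convest(
    pvals, max_iter: int = 100
) -> tuple[Pi1Estimate, ConvexDensityFit]:
    """NPMLE of pi0 under a convex, decreasing P-value density.

    Starting from the uniform density, each iteration selects the triangular
    component theta* maximizing the mean ratio sum_i f_theta(p_i)/f(p_i)
    (ties broken toward the smaller theta), then mixes it in with weight
    epsilon chosen by golden-section line search on the log-likelihood.
    After at most ``max_iter`` iterations pi0-hat = f-hat(1), the weight on
    the uniform component.
    """
    p = _extract_pvalues(pvals)
    G = p.size
    thetas = _candidate_thetas(p)
    # the uniform density is itself a candidate direction (last row, so the
    # smaller-theta tie-break of argmax is unaffected): without it the
    # uniform weight w0 = f(1) can only shrink along the greedy path and
    # pi0-hat undershoots the NPMLE value
    F = np.vstack([_triangle_matrix(thetas, p), np.ones(G)])

    f = np.ones(G)  # current density at the data points
    w_uniform = 1.0
    weights: dict[float, float] = {}
    ll = 0.0
    ll_trace = [0.0]
    for _ in range(max_iter):
        ratios = F @ (1.0 / f) / G
        j = int(np.argmax(ratios))  # argmax returns the first (smallest theta) tie
        if ratios[j] <= 1.0 + 1e-12:
            break  # no component improves the likelihood to first order
        ftheta = F[j]

        def ll_eps(eps: float) -> float:
            mix = (1.0 - eps) * f + eps * ftheta
            return float(np.sum(np.log(np.maximum(mix, 1e-300))))

        eps = _golden_section_max(ll_eps, 0.0, 1.0)
        new_ll = ll_eps(eps)
        if new_ll <= ll + 1e-12 and weights:
            break
        f = (1.0 - eps) * f + eps * ftheta
        w_uniform *= 1.0 - eps
        for th in weights:
            weights[th] *= 1.0 - eps
        if j == len(thetas):  # the uniform direction
            w_uniform += eps
        else:
            th_star = float(thetas[j])
            weights[th_star] = weights.get(th_star, 0.0) + eps
        ll = new_ll
        ll_trace.append(ll)

    support = np.array(sorted(weights))
    w = np.array([weights[t] for t in support])
    fit = ConvexDensityFit(
        support_points=support, weights=w, w_uniform=w_uniform, log_likelihood=ll
    )
    pi0 = float(np.clip(w_uniform, 0.0, 1.0))
    est = Pi1Estimate(
        pi0=pi0,
        method="convest",
        diagnostics={
            "n_support": len(support),
            "log_likelihood": ll,
            "ll_trace": np.asarray(ll_trace),
        },
    )
    return est, fit


# ---------------------------------------------------------------------------
# Grenander density of P-values


@dataclass
class GrenanderDensity:
    """Nonincreasing step density: the left derivative of the least concave
    majorant of the empirical CDF on [0, 1].

    ``breakpoints`` is increasing from 0 to 1; ``heights[i]`` is the density
    on (breakpoints[i], breakpoints[i+1]].
    """

    breakpoints: np.ndarray
    heights: np.ndarray

    def density_at(self, p) -> np.ndarray:
        p = np.atleast_1d(np.asarray(p, float))
        idx = np.searchsorted(self.breakpoints, p, side="left") - 1
        idx = np.clip(idx, 0, len(self.heights) - 1)
        return self.heights[idx]

    @property
    def terminal_height(self) -> float:
        """Density on the last segment, i.e. f-hat at p -> 1."""
        return float(self.heights[-1])

    @property
    def terminal_positive_height(self) -> float:
        """Height of the last segment carrying mass.

        With continuous data the largest observation p_max is < 1 almost
        surely, so the literal final segment (p_max, 1] always has slope 0;
        the density of the null component near 1 is the step ending at
        p_max, the smallest positive step height.
        """
        pos = self.heights[self.heights > 0]
        return float(pos[-1])

    def integral(self) -> float:
        return float(np.sum(self.heights * np.diff(self.breakpoints)))


def grenander_density(pvals) -> GrenanderDensity:
    """Grenander estimator of a nonincreasing density on [0, 1]."""
    p = _extract_pvalues(pvals)
    n = p.size
    xs, counts = np.unique(p, return_counts=True)
    cdf = np.cumsum(counts) / n
    # CDF points (0,0), (x_i, F(x_i)), and (1,1) if the largest p < 1
    x = np.concatenate([[0.0], xs])
    y = np.concatenate([[0.0], cdf])
    if xs[-1] < 1.0:
        x = np.concatenate([x, [1.0]])
        y = np.concatenate([y, [1.0]])
    # upper (concave) hull by monotone chain: keep slopes strictly decreasing
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            s_ab = (y[b] - y[a]) / (x[b] - x[a])
            s_bi = (y[i] - y[b]) / (x[i] - x[b])
            if s_bi >= s_ab:  # b lies on/below chord a-i: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    hx = x[hull]
    hy = y[hull]
    heights = np.diff(hy) / np.diff(hx)
    return GrenanderDensity(breakpoints=hx, heights=heights)


# ---------------------------------------------------------------------------
# Empirical-null method on test statistics


@dataclass
class EmpiricalNullFit:
    input_family: str
    df: float | None
    null_scale: float
    censoring_quantile: float
    censoring_point: float
    eta0: float
    self_consistent: bool = True


def _null_absolute_cdf(x, scale: float, family: str, df: float | None):
    z = np.asarray(x, float) / scale
    if family == "z":
        return 2.0 * sps.norm.cdf(z) - 1.0
    return 2.0 * sps.t.cdf(z, df) - 1.0


def _null_log_pdf_abs(x, scale: float, family: str, df: float | None):
    z = np.asarray(x, float) / scale
    if family == "z":
        return np.log(2.0) + sps.norm.logpdf(z) - np.log(scale)
    return np.log(2.0) + sps.t.logpdf(z, df) - np.log(scale)


def _null_abs_ppf(q, scale: float, family: str, df: float | None):
    if family == "z":
        return scale * sps.norm.ppf((1.0 + q) / 2.0)
    return scale * sps.t.ppf((1.0 + q) / 2.0, df)


def _censored_ml_fit(
    abs_stats: np.ndarray, x0: float, family: str, df: float | None
) -> tuple[float, float]:
    """Censored ML fit of the null scale on the central region [0, x0].

    Model: a fraction eta0 of statistics is null with |S| ~ the scaled null;
    the non-null fraction falls outside the central region.  Statistics
    inside contribute their null density, statistics outside only the
    probability 1 - eta0 * F(x0; sigma).  For fixed sigma the optimal eta0
    has the closed form min(1, N0 / (G * F(x0; sigma))); the profile
    likelihood over sigma is then maximized numerically.  The censoring
    term is what makes the scale identifiable when the truncation region is
    narrow (a purely truncated fit degenerates toward a locally-uniform
    null of arbitrary scale).
    """
    y = abs_stats[abs_stats <= x0]
    G = abs_stats.size
    n0 = y.size
    ref = float(np.std(abs_stats)) or 1.0

    def profile_nll(log_scale: float) -> float:
        scale = float(np.exp(log_scale))
        F = float(_null_absolute_cdf(x0, scale, family, df))
        if F <= 0:
            return np.inf
        eta0 = min(1.0, n0 / (G * F))
        inside = np.sum(_null_log_pdf_abs(y, scale, family, df)) + n0 * np.log(eta0)
        tail = 1.0 - eta0 * F
        outside = (G - n0) * (np.log(tail) if tail > 0 else -np.inf)
        return -(inside + outside)

    # coarse global scan then local polish: the profile can be multimodal
    # (a narrow region admits a small-scale "all null mass inside" optimum)
    grid_ls = np.linspace(np.log(ref) - 5.0, np.log(ref) + 3.0, 81)
    vals = np.array([profile_nll(ls) for ls in grid_ls])
    if not np.any(np.isfinite(vals)):
        raise RuntimeError("censored ML scale fit failed: no finite likelihood")
    j = int(np.nanargmin(vals))
    lo = grid_ls[max(j - 1, 0)]
    hi = grid_ls[min(j + 1, len(grid_ls) - 1)]
    res = minimize_scalar(
        profile_nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"censored ML scale fit did not converge: {res.message}")
    scale = float(np.exp(res.x))
    F = float(_null_absolute_cdf(x0, scale, family, df))
    eta0 = min(1.0, n0 / (G * F))
    return scale, eta0


CENSORING_GRID = np.array([0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.99])

#: where the Grenander density is read off as the null-uniform level eta0:
#: far enough right that the signal component has died off, far enough from
#: p = 1 to avoid the Grenander estimator's boundary inconsistency
ETA0_EVAL_POINT = 0.8


def estimate_pi0_empirical_null(
    stats: TestStatisticVector | np.ndarray,
    input_family: str = "t",
    df: float | None = None,
) -> tuple[Pi1Estimate, EmpiricalNullFit]:
    """Empirical-null estimate of pi0 directly from test statistics.

    The null scale sigma-hat is fitted by truncated maximum likelihood on the
    central portion of |statistics| — a half-normal(sigma) null for the z
    input specification, a scaled t(df) null for the t specification.  The
    censoring threshold is the smallest |statistic| quantile on the grid
    10%, 20%, ..., 90%, 99% at which the truncated fit is self-consistent:
    the fitted null must predict, within a 95% binomial band, the observed
    count of statistics inside a distant check region (the 80% quantile).
    Statistics are then converted to two-sided null P-values and pi0-hat is
    the Grenander density of those P-values read off near p = 1 (at the
    step containing p = 0.8, avoiding the estimator's boundary
    inconsistency), capped at 1.
    """
    if input_family not in ("t", "z"):
        raise ValueError("input_family must be 't' or 'z'")
    if input_family == "t":
        if df is None or df <= 0:
            raise ValueError("a positive df is required for the t input family")
    vals = stats.values if isinstance(stats, TestStatisticVector) else np.asarray(stats, float)
    abs_stats = np.abs(vals[np.isfinite(vals)])
    if abs_stats.size < 200:
        raise ValueError(
            f"only {abs_stats.size} finite statistics; empirical-null fitting "
            "needs >= 200"
        )

    G = abs_stats.size
    best = None  # (z-score of check, record) fallback if nothing passes
    chosen = None
    for i, q in enumerate(CENSORING_GRID):
        x0 = float(np.quantile(abs_stats, q))
        if x0 <= 0:
            continue
        scale, eta_fit = _censored_ml_fit(abs_stats, x0, input_family, df)
        n0 = int((abs_stats <= x0).sum())
        # self-consistency: the fitted null (scale, eta0) must predict the
        # observed count inside an expanded truncation region within a 95%
        # binomial band.  The check threshold sits at the 80% quantile —
        # far from x0 where the count was effectively fitted, yet below the
        # extreme tail where signal concentrates: degenerate ridge fits
        # (eta0 ~ scale/true_scale) mimic the truth wherever the null CDF
        # is still near-linear, and only a distant check discriminates.
        # For thresholds at/above 80% the check looks inward instead.
        q_chk = 0.8 if q < 0.8 else q - 0.4
        x_chk = float(np.quantile(abs_stats, q_chk))
        n_chk = int((abs_stats <= x_chk).sum())
        p_chk = eta_fit * float(_null_absolute_cdf(x_chk, scale, input_family, df))
        p_chk = min(max(p_chk, 1e-12), 1.0 - 1e-12)
        lo, hi = sps.binom.ppf([0.025, 0.975], G, p_chk)
        zscore = abs(n_chk - G * p_chk) / max(np.sqrt(G * p_chk * (1 - p_chk)), 1.0)
        record = (q, x0, scale, n0, lo, hi)
        if lo <= n_chk <= hi:
            chosen = record
            break
        if best is None or zscore < best[0]:
            best = (zscore, record)
    self_consistent = chosen is not None
    if chosen is None:
        if best is None:
            raise RuntimeError("empirical-null scale search failed on every threshold")
        warnings.warn(
            "no censoring threshold passed the self-consistency check; using "
            "the least-inconsistent one",
            RuntimeWarning,
            stacklevel=2,
        )
        chosen = best[1]
    q, x0, scale, n0, lo, hi = chosen

    # two-sided null P-values under the fitted null
    if input_family == "z":
        p = 2.0 * sps.norm.sf(abs_stats / scale)
    else:
        p = 2.0 * sps.t.sf(abs_stats / scale, df)
    p = np.clip(p, 1e-300, 1.0)
    gren = grenander_density(p)
    # the Grenander slope on the literal last segment is boundary-
    # inconsistent (biased toward 0); read the null density off the step
    # containing ETA0_EVAL_POINT, where the uniform null component dominates
    eta0 = min(1.0, float(gren.density_at(ETA0_EVAL_POINT)[0]))

    fit = EmpiricalNullFit(
        input_family=input_family,
        df=df,
        null_scale=scale,
        censoring_quantile=float(q),
        censoring_point=x0,
        eta0=eta0,
        self_consistent=self_consistent,
    )
    est = Pi1Estimate(
        pi0=eta0,
        method=f"empirical_null_{input_family}",
        diagnostics={
            "null_scale": scale,
            "censoring_quantile": float(q),
            "censoring_point": x0,
            "self_consistent": self_consistent,
            "grenander_eta0": eta0,
        },
    )
    return est, fit


# ---------------------------------------------------------------------------
# FDR assembly


def fdr_hat(alpha: float, pi0: float, pvals, strict: bool = True) -> FdrEstimate:
    """Mixture-model FDR estimate FDR(alpha) = min(1, alpha * pi0 / F(alpha)).

    F(alpha) is the observed fraction of P-values below alpha (strict "<" by
    default, matching the rule "call genes with P-values less than alpha
    significant"; set ``strict=False`` for "<=").  When no gene is
    significant the result is flagged rather than raising a division error.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    p = _extract_pvalues(pvals)
    count = (p < alpha).sum() if strict else (p <= alpha).sum()
    F = count / p.size
    if F == 0:
        return FdrEstimate(alpha=alpha, pi0=pi0, F_hat=0.0, fdr=None, no_discoveries=True)
    return FdrEstimate(
        alpha=alpha, pi0=pi0, F_hat=float(F), fdr=float(min(1.0, alpha * pi0 / F))
    )
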