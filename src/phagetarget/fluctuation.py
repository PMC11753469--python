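"""Lea-Coulson fluctuation-assay inference with partial plating.

Model
-----
Each culture is founded by a single non-mutant cell and grows to ``Nt`` cells;
mutations to phage resistance occur at rate ``mu`` per cell division, so the
number of mutational events per culture is Poisson with mean ``m = mu*(Nt-1)``
(a culture of ``Nt`` cells is the product of ``Nt - 1`` divisions).  Mutants
and non-mutants grow at the same rate, so a mutation that occurs when the
population has size ``n`` founds a clone of roughly ``Nt/n`` cells;
marginalising over the (growth-weighted) mutation time gives the classic
clone-size law ``P(K = k) = 1/(k*(k+1))``.  The resulting mutant count is
compound-Poisson distributed with probability generating function

    G(z) = exp(m * (1-z) * ln(1-z) / z),

the Lea-Coulson distribution.  When only a fraction ``epsilon`` of each
culture is plated, every mutant cell is observed independently with
probability ``epsilon`` (binomial thinning), i.e. the observed pgf is
``H(z) = G(1 - epsilon + epsilon*z)``; in compound-Poisson form
``log H(z) = m*(psi(z) - 1)`` where ``psi`` is the pgf of the per-clone
*observed* colony count (clone size ~ 1/(k(k+1)), thinned Bin(k, epsilon)).
In particular ``P(0) = exp(m * epsilon * ln(epsilon) / (1 - epsilon))`` for
``epsilon < 1`` and ``exp(-m)`` at full plating.

Estimation is by maximum likelihood in ``m`` with profile-likelihood 95%
confidence intervals (2*dlnL = 3.84); rates are compared between plating
environments with a likelihood-ratio test under a shared per-division rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "RateComparison",
    "lc_pmf",
    "lc_loglik",
    "estimate_rate",
    "compare_rates",
]

_CHI2_95_1DF = 3.8414588206941245  # chi-square 95% quantile, 1 df
_TINY = 1e-300


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class FluctuationExperiment:
    """Resistant-colony counts from one plating environment.

    Parameters
    ----------
    environment_label:
        Name of the plating environment (e.g. ``"phage_CL2"``).
    counts:
        Resistant colonies per countable culture.
    n_total_cells:
        Final number of cells per culture, ``Nt``.
    plating_fraction:
        Fraction ``epsilon`` of each culture spread on the selective plate.
    n_censored_high:
        Number of "burst"/uncountable plates.  These carry no count value; they
        enter the likelihood only when a ``censoring_ceiling`` is given,
        contributing the upper-tail probability beyond the ceiling, and are
        excluded otherwise (the default, matching how uncountable plates were
        dropped in the source assay design).
    censoring_ceiling:
        Largest countable colony number, used for the right-censored mode.
    """

    environment_label: str
    counts: tuple[int, ...]
    n_total_cells: float
    plating_fraction: float = 1.0
    n_censored_high: int = 0
    censoring_ceiling: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.counts) + self.n_censored_high < 1:
            raise ValueError("experiment needs at least one culture")
        if any(c < 0 for c in self.counts):
            raise ValueError("colony counts must be non-negative")
        if not self.n_total_cells > 0:
            raise ValueError("n_total_cells (Nt) must be positive")
        if not 0.0 < self.plating_fraction <= 1.0:
            raise ValueError("plating_fraction (epsilon) must lie in (0, 1]")
        if self.n_censored_high < 0:
            raise ValueError("n_censored_high must be non-negative")
        if self.n_censored_high and self.censoring_ceiling is not None:
            if self.counts and self.censoring_ceiling < max(self.counts):
                raise ValueError("censoring ceiling below the largest observed count")

    @property
    def n_cultures(self) -> int:
        return len(self.counts) + self.n_censored_high


@dataclass(frozen=True)
class RateEstimate:
    """Maximum-likelihood mutation-rate estimate for one experiment."""

    environment_label: str
    m_hat: float
    mu_hat: float
    ci95_m: tuple[float, float]
    ci95_mu: tuple[float, float]
    loglik_at_mle: float
    n_total_cells: float


@dataclass(frozen=True)
class RateComparison:
    """Likelihood-ratio comparison of per-division rates between environments."""

    environment_label: str
    reference_label: str
    ratio: float
    ci95_ratio: tuple[float, float] | None
    lrt_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# pmf machinery


@lru_cache(maxsize=64)
def _thinned_clone_pmf(epsilon: float, k_max: int) -> np.ndarray:
    """P(observed colonies from one mutant clone = k), k = 1..k_max.

    Clone size K has P(K = j) = 1/(j*(j+1)); each of the j cells is plated
    independently with probability epsilon.  Exact term-by-term summation of
    sum_j binom(k; j, epsilon) / (j*(j+1)); at epsilon = 1 this collapses to
    1/(k*(k+1)).
    """
    psi = np.zeros(k_max + 1)
    if k_max == 0:
        return psi
    k = np.arange(1, k_max + 1, dtype=float)
    if epsilon >= 1.0:
        psi[1:] = 1.0 / (k * (k + 1.0))
        return psi
    for kk in range(1, k_max + 1):
        # j-range covering the binomial mass around kk/epsilon generously
        width = 60.0 + 14.0 * math.sqrt((kk + 30.0) * (1.0 - epsilon))
        j_hi = int(math.ceil((kk + width) / epsilon))
        j = np.arange(kk, j_hi + 1, dtype=float)
        terms = stats.binom.pmf(kk, j, epsilon) / (j * (j + 1.0))
        psi[kk] = float(terms.sum())
    psi.setflags(write=False)
    return psi


def _log_p0(m: float, epsilon: float) -> float:
    if epsilon >= 1.0:
        return -m
    return m * epsilon * math.log(epsilon) / (1.0 - epsilon)


def lc_pmf(m: float, epsilon: float, k_max: int) -> np.ndarray:
    """Lea-Coulson pmf under partial plating, P(0..k_max).

    Computed by exponentiating the compound-Poisson log-pgf
    ``log H(z) = m*(psi(z)-1)`` with the standard power-series recursion
    ``p_k = (1/k) * sum_{j=1}^{k} j*q_j*p_{k-j}`` (all terms non-negative, so
    the recursion is numerically stable); entries are exact up to ``k_max``.
    """
    if not math.isfinite(m) or m < 0:
        raise ValueError("m must be a finite non-negative real")
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must lie in (0, 1]")
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    p = np.zeros(k_max + 1)
    if m == 0.0:
        p[0] = 1.0
        return p
    p[0] = math.exp(_log_p0(m, epsilon))
    if k_max == 0:
        return p
    q = m * _thinned_clone_pmf(epsilon, k_max)  # q[0] unused
    jq = q * np.arange(k_max + 1)
    for k in range(1, k_max + 1):
        p[k] = float(np.dot(jq[1 : k + 1], p[k - 1 :: -1])) / k
    return p


# ---------------------------------------------------------------------------
# likelihood


class _LoglikCache:
    """Per-experiment log-likelihood ``m -> lnL`` with preprocessed counts."""

    def __init__(self, experiment: FluctuationExperiment, count_ceiling: int | None = None):
        counts = np.asarray(experiment.counts, dtype=int)
        n_cens = experiment.n_censored_high
        ceiling = experiment.censoring_ceiling
        if count_ceiling is not None:
            # move jackpot counts above the ceiling into the censored tail
            over = counts > count_ceiling
            n_cens += int(over.sum())
            counts = counts[~over]
            ceiling = count_ceiling if n_cens else ceiling
        if n_cens and ceiling is None:
            n_cens = 0  # censored plates excluded by default
        if counts.size == 0 and n_cens == 0:
            raise ValueError("no usable cultures after censoring handling")
        self.epsilon = experiment.plating_fraction
        self.n_censored = n_cens
        self.ceiling = ceiling
        if counts.size:
            self.weights = np.bincount(counts)
            self.observed_k = np.nonzero(self.weights)[0]
            self.observed_w = self.weights[self.observed_k].astype(float)
            self.k_max = int(counts.max())
        else:
            self.observed_k = np.array([], dtype=int)
            self.observed_w = np.array([])
            self.k_max = 0
        if n_cens:
            self.k_max = max(self.k_max, int(ceiling))
        self.all_zero = self.n_censored == 0 and self.k_max == 0

    def __call__(self, m: float) -> float:
        if m < 0:
            return -math.inf
        if self.all_zero:
            n = float(self.observed_w.sum())
            return n * _log_p0(m, self.epsilon)
        if m == 0.0:
            return -math.inf if (self.k_max > 0 or self.n_censored) else 0.0
        p = lc_pmf(m, self.epsilon, self.k_max)
        ll = 0.0
        if self.observed_k.size:
            pk = np.maximum(p[self.observed_k], _TINY)
            ll += float(np.dot(self.observed_w, np.log(pk)))
        if self.n_censored:
            tail = max(1.0 - float(p[: self.ceiling + 1].sum()), _TINY)
            ll += self.n_censored * math.log(tail)
        return ll


def lc_loglik(
    m: float,
    experiment: FluctuationExperiment,
    count_ceiling: int | None = None,
) -> float:
    """Log-likelihood of ``m`` for one experiment.

    Countable plates contribute ``log pmf(count)``; censored ("burst") plates
    contribute the log upper-tail probability beyond the censoring ceiling when
    one is set, and are excluded otherwise.
    """
    if not math.isfinite(m) or m < 0:
        raise ValueError("m must be a finite non-negative real")
    return _LoglikCache(experiment, count_ceiling)(m)


def _maximize_1d(loglik: Callable[[float], float], grid: np.ndarray) -> tuple[float, float]:
    """Coarse grid scan followed by bounded Brent refinement; returns (x, lnL)."""
    vals = np.array([loglik(x) for x in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[i]), float(vals[i])
    res = optimize.minimize_scalar(
        lambda lx: -loglik(math.exp(lx)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    x = math.exp(res.x)
    return x, -float(res.fun)


def _default_m_grid(ll: _LoglikCache) -> np.ndarray:
    if ll.observed_w.size:
        n = float(ll.observed_w.sum())
        mean_count = float(np.dot(ll.observed_k, ll.observed_w)) / n
    else:
        mean_count = float(ll.ceiling or 1)
    hi = max(10.0, 5.0 * (mean_count + 1.0) / ll.epsilon)
    return np.logspace(-5, math.log10(hi), 80)


def estimate_rate(
    experiment: FluctuationExperiment,
    count_ceiling: int | None = None,
    ci: bool = True,
) -> RateEstimate:
    """Maximum-likelihood estimate of m (mutations per culture) and mu = m/Nt.

    95% confidence limits are profile-likelihood bounds at ``2*dlnL = 3.84``;
    the boundary case of all-zero counts yields ``m_hat = 0`` with lower
    limit 0.  ``ci=False`` skips the profile bounds (point estimate only,
    reported as NaN intervals) for simulation studies.
    """
    ll = _LoglikCache(experiment, count_ceiling)
    if ll.all_zero:
        m_hat = 0.0
        l_max = 0.0
    else:
        m_hat, l_max = _maximize_1d(ll, _default_m_grid(ll))
    nt = experiment.n_total_cells
    if not ci:
        nan = float("nan")
        return RateEstimate(
            experiment.environment_label, m_hat, m_hat / nt,
            (nan, nan), (nan, nan), l_max, nt,
        )

    def deficit(m: float) -> float:
        return 2.0 * (l_max - ll(m)) - _CHI2_95_1DF

    # lower bound
    if m_hat <= 0.0:
        lo = 0.0
    else:
        a = m_hat
        while deficit(a) < 0 and a > 1e-12:
            a /= 8.0
        lo = 0.0 if a <= 1e-12 else float(optimize.brentq(deficit, a, m_hat, xtol=1e-12))
    # upper bound
    b = max(m_hat, 1e-6)
    while deficit(b) < 0:
        b *= 2.0
        if b > 1e9:
            raise RuntimeError("failed to bracket upper confidence limit")
    b_lo = max(m_hat, b / 2.0 if b > 1e-6 else 0.0)
    hi = float(optimize.brentq(deficit, b_lo, b, xtol=1e-12))
    return RateEstimate(
        environment_label=experiment.environment_label,
        m_hat=m_hat,
        mu_hat=m_hat / nt,
        ci95_m=(lo, hi),
        ci95_mu=(lo / nt, hi / nt),
        loglik_at_mle=l_max,
        n_total_cells=nt,
    )


def compare_rates(
    experiment_a: FluctuationExperiment,
    experiment_ref: FluctuationExperiment,
    count_ceiling: int | None = None,
    ratio_ci: bool = True,
) -> RateComparison:
    """Likelihood-ratio test of equal per-division rates mu between environments.

    The null model shares one ``mu`` across both experiments (so each has its
    own ``m = mu*Nt`` and epsilon); the alternative fits separate rates.  The
    LRT statistic is referred to chi-square with 1 df.  The reported ratio is
    ``mu_hat_a / mu_hat_ref`` with a profile-likelihood 95% CI.
    """
    ll_a = _LoglikCache(experiment_a, count_ceiling)
    ll_r = _LoglikCache(experiment_ref, count_ceiling)
    est_a = estimate_rate(experiment_a, count_ceiling, ci=False)
    est_r = estimate_rate(experiment_ref, count_ceiling, ci=False)
    if est_a.m_hat <= 0.0 or est_r.m_hat <= 0.0:
        raise ValueError("degenerate experiment: zero mutation-rate MLE; ratio undefined")
    nt_a, nt_r = experiment_a.n_total_cells, experiment_ref.n_total_cells

    def null_loglik(mu: float) -> float:
        return ll_a(mu * nt_a) + ll_r(mu * nt_r)

    mu_lo = min(est_a.mu_hat, est_r.mu_hat)
    mu_hi = max(est_a.mu_hat, est_r.mu_hat)
    grid = np.logspace(math.log10(mu_lo / 4.0), math.log10(mu_hi * 4.0), 60)
    _, l_null = _maximize_1d(null_loglik, grid)
    l_alt = est_a.loglik_at_mle + est_r.loglik_at_mle
    lrt = max(0.0, 2.0 * (l_alt - l_null))
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    ratio = est_a.mu_hat / est_r.mu_hat

    ci: tuple[float, float] | None = None
    if ratio_ci:
        def profile(rho: float) -> float:
            # maximize over the reference rate with the ratio held fixed
            def g(mu_r: float) -> float:
                return ll_a(rho * mu_r * nt_a) + ll_r(mu_r * nt_r)

            g_grid = np.logspace(
                math.log10(est_r.mu_hat / 8.0), math.log10(est_r.mu_hat * 8.0), 40
            )
            return _maximize_1d(g, g_grid)[1]

        def rho_deficit(rho: float) -> float:
            return 2.0 * (l_alt - profile(rho)) - _CHI2_95_1DF

        a = ratio
        while rho_deficit(a) < 0:
            a /= 1.8
            if a < ratio * 1e-6:
                break
        lo_r = 0.0 if rho_deficit(a) < 0 else float(
            optimize.brentq(rho_deficit, a, ratio, xtol=1e-9, rtol=1e-9)
        )
        b = ratio
        while rho_deficit(b) < 0:
            b *= 1.8
            if b > ratio * 1e6:
                raise RuntimeError("failed to bracket ratio upper confidence limit")
        hi_r = float(optimize.brentq(rho_deficit, max(ratio, b / 1.8), b, xtol=1e-9, rtol=1e-9))
        ci = (lo_r, hi_r)

    return RateComparison(
        environment_label=experiment_a.environment_label,
        reference_label=experiment_ref.environment_label,
        ratio=ratio,
        ci95_ratio=ci,
        lrt_statistic=lrt,
        p_value=p,
    )
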