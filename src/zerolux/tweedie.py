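"""Compound Poisson–Gamma (Tweedie, 1 < p < 2) distribution machinery.

For a power parameter ``p`` strictly between 1 and 2 the Tweedie
exponential-dispersion family with mean ``mu`` and dispersion ``phi``
(variance ``phi * mu**p``) is the law of a compound sum

    Y = sum_{i=1..N} G_i,   N ~ Poisson(lambda),   G_i ~ Gamma(alpha, gamma)

with

    lambda = mu**(2 - p) / (phi * (2 - p))
    alpha  = (2 - p) / (p - 1)
    gamma  = phi * (p - 1) * mu**(p - 1)            (scale)

so the distribution has continuous positive support plus a point mass
``exp(-lambda)`` at exactly zero — the shape of zero-inflated illuminance
data.  The boundary cases are classical: ``p = 1`` with ``phi = 1`` is
Poisson(mu), ``p = 2`` is Gamma with shape ``1/phi`` and scale
``phi * mu``.

The density for ``y > 0`` has no closed form; it is the series

    f(y) = sum_{j>=1} e^{-lambda} lambda^j / j! * GammaPDF(y; j*alpha, gamma)

evaluated here in log space, summing outward from the dominant Poisson
index until terms fall below 1e-12 of the maximum (Dunn–Smyth-style
series evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "TweedieParams",
    "CPGParams",
    "to_cpg",
    "rvs",
    "pdf",
    "logpdf",
    "loglik",
    "profile_power",
    "comparison_rvs",
    "DEFAULT_POWER_GRID",
]

#: Default profile grid for the power parameter: 1.01 .. 1.99 step 0.01.
DEFAULT_POWER_GRID = np.round(np.arange(1.01, 1.995, 0.01), 2)

_MAX_TERMS = 200_000  # hard cap on series indices; exceeded -> error


@dataclass(frozen=True)
class TweedieParams:
    """Mean/power/dispersion parameterization of a Tweedie law.

    ``mu > 0`` (lux scale), ``1 <= p <= 2`` (endpoints are the exact
    Poisson / Gamma special cases), ``phi > 0``; variance is
    ``phi * mu**p``.
    """

    mu: float
    p: float
    phi: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not 1.0 <= self.p <= 2.0:
            raise ValueError(f"power p must lie in [1, 2], got {self.p}")
        if not self.phi > 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")

    @property
    def variance(self) -> float:
        return self.phi * self.mu ** self.p


@dataclass(frozen=True)
class CPGParams:
    """Compound Poisson–Gamma parameters (rate, shape, scale)."""

    lam: float
    alpha: float
    gamma_scale: float


def to_cpg(params: TweedieParams) -> CPGParams:
    """Convert (mu, p, phi) to compound Poisson–Gamma (lambda, alpha, gamma).

    Requires ``1 < p < 2``; the endpoints are not compound laws (use the
    Poisson / Gamma special cases directly).  The conversion satisfies
    ``lambda * alpha * gamma = mu`` and
    ``lambda * alpha * (alpha + 1) * gamma**2 = phi * mu**p`` exactly.
    """
    mu, p, phi = params.mu, params.p, params.phi
    if not 1.0 < p < 2.0:
        raise ValueError(
            f"compound Poisson-Gamma form requires 1 < p < 2, got p={p}; "
            "p=1 is Poisson and p=2 is Gamma"
        )
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    gamma_scale = phi * (p - 1.0) * mu ** (p - 1.0)
    return CPGParams(lam=lam, alpha=alpha, gamma_scale=gamma_scale)


def rvs(params: TweedieParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` variates as an explicit compound Poisson–Gamma sum.

    Each draw is ``sum_{i<=N} G_i`` with ``N ~ Poisson(lambda)`` and
    ``G_i ~ Gamma(alpha, gamma)``; ``N = 0`` yields exactly 0.0.  The
    boundary powers fall back to the Poisson (``p=1``, scaled by ``phi``)
    and Gamma (``p=2``) samplers.  Reproducible under ``seed`` (an int or
    a ``numpy.random.Generator``).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    mu, p, phi = params.mu, params.p, params.phi
    if p == 1.0:
        return phi * rng.poisson(mu / phi, size=n).astype(float)
    if p == 2.0:
        return rng.gamma(shape=1.0 / phi, scale=phi * mu, size=n)
    cpg = to_cpg(params)
    counts = rng.poisson(cpg.lam, size=n)
    out = np.zeros(n)
    pos = counts > 0
    # sum of j iid Gamma(alpha, scale) is Gamma(j*alpha, scale)
    out[pos] = rng.gamma(shape=counts[pos] * cpg.alpha, scale=cpg.gamma_scale)
    return out


def _series_logpdf_positive(y: np.ndarray, mu: np.ndarray, p: float,
                            phi: float) -> np.ndarray:
    """Log density at strictly positive y via the CPG series, vectorized.

    The dominant Poisson index is ``j* ~= y**(2-p) / (phi*(2-p))``; terms
    are summed over a window around it, widened until the edge terms are
    below 1e-12 of the peak (hard cap ``_MAX_TERMS``).  ``mu`` may be a
    scalar or an array matched to ``y``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    alpha = (2.0 - p) / (p - 1.0)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    gamma_scale = phi * (p - 1.0) * mu ** (p - 1.0)

    # per-point log of the j-th term, j a 1-D integer array
    def term_logs(jj, yi, lami, gi):
        return (-lami + jj * np.log(lami) - special.gammaln(jj + 1)
                + (jj * alpha - 1.0) * np.log(yi) - yi / gi
                - jj * alpha * np.log(gi) - special.gammaln(jj * alpha))

    jstar = np.maximum(y ** (2.0 - p) / (phi * (2.0 - p)), 1.0)
    out = np.empty_like(y)
    # process in chunks of comparable jstar so the shared window stays tight
    order = np.argsort(jstar)
    chunk = 512
    for s in range(0, len(order), chunk):
        idx = order[s:s + chunk]
        js = jstar[idx]
        width = 12.0 * np.sqrt(js.max() + 1.0) + 40.0
        lo = max(1, int(np.floor(js.min() - width)))
        hi = int(np.ceil(js.max() + width))
        while True:
            if hi - lo + 1 > _MAX_TERMS:
                raise OverflowError(
                    f"Tweedie series needs > {_MAX_TERMS} terms (p={p}, "
                    f"phi={phi}, max y={y[idx].max():g})"
                )
            jj = np.arange(lo, hi + 1, dtype=float)
            logs = term_logs(jj[None, :], y[idx, None], lam[idx, None],
                             gamma_scale[idx, None])
            peak = logs.max(axis=1)
            # widen until both edges are negligible for every point
            lo_ok = lo == 1 or np.all(logs[:, 0] < peak + np.log(1e-12))
            hi_ok = np.all(logs[:, -1] < peak + np.log(1e-12))
            if lo_ok and hi_ok:
                break
            if not lo_ok:
                lo = max(1, lo - (hi - lo + 1))
            if not hi_ok:
                hi = hi + (hi - lo + 1)
        out[idx] = special.logsumexp(logs, axis=1)
    return out


def logpdf(y, params: TweedieParams):
    """Log density (or log point mass at 0) of the Tweedie law.

    ``p = 1`` with ``phi = 1`` evaluates the exact Poisson pmf (zero
    density off the integers); ``p = 2`` the Gamma density; otherwise the
    compound Poisson–Gamma series, with ``logpdf(0) = -lambda``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("Tweedie support is y >= 0")
    mu, p, phi = params.mu, params.p, params.phi
    if p == 1.0:
        counts = y / phi
        near_int = np.isclose(counts, np.round(counts), atol=1e-8)
        out = np.where(near_int,
                       stats.poisson.logpmf(np.round(counts).astype(int), mu / phi),
                       -np.inf)
        return out if out.ndim else float(out)
    if p == 2.0:
        out = stats.gamma.logpdf(y, a=1.0 / phi, scale=phi * mu)
        return out if out.ndim else float(out)
    cpg = to_cpg(params)
    out = np.full(y.shape, -cpg.lam)
    pos = y > 0
    if np.any(pos):
        out[pos] = _series_logpdf_positive(y[pos], mu, p, phi)
    return out if out.ndim else float(out)


def pdf(y, params: TweedieParams):
    """Density for ``y > 0`` and the probability mass ``exp(-lambda)`` at 0."""
    out = np.exp(logpdf(y, params))
    return out if np.ndim(out) else float(out)


def loglik(data, params: TweedieParams, mu=None) -> float:
    """Sum of log densities; zeros contribute the log point mass, never -inf.

    ``mu`` optionally supplies a per-observation mean (e.g. fitted values
    from a regression), overriding ``params.mu``.
    """
    y = np.asarray(data, dtype=float)
    if np.any(y < 0):
        raise ValueError("Tweedie support is y >= 0")
    p, phi = params.p, params.phi
    if mu is None:
        return float(np.sum(logpdf(y, params)))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if not 1.0 < p < 2.0:
        raise ValueError("per-observation means require 1 < p < 2")
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    ll = np.where(y == 0, -lam, 0.0)
    pos = y > 0
    if np.any(pos):
        ll[pos] = _series_logpdf_positive(y[pos], mu[pos], p, phi)
    return float(np.sum(ll))


def pearson_phi(y, mu, p: float, edf: float = 1.0) -> float:
    """Moment (Pearson) dispersion estimate sum((y-mu)^2 / mu^p) / (n - edf)."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    n = y.size
    if n <= edf:
        raise ValueError(f"need n > edf, got n={n}, edf={edf}")
    return float(np.sum((y - mu) ** 2 / mu ** p) / (n - edf))


def profile_power(data, grid=None) -> tuple[float, float, pd.DataFrame]:
    """Profile the Tweedie power parameter over a grid for i.i.d. data.

    For each grid value of ``p`` the mean is the sample mean (the
    maximum-likelihood intercept under a log link), the dispersion is the
    Pearson moment estimate, and the exact series log-likelihood is
    recorded.  Returns ``(p_hat, phi_hat, table)`` where the table has
    columns ``p``, ``phi``, ``loglik`` and the estimates maximize the
    profile.

    Requires at least one zero and one positive observation for an
    interior optimum (all-positive data push the profile toward the Gamma
    boundary; all-zero data leave the mean unidentifiable).
    """
    y = np.asarray(data, dtype=float)
    y = y[~np.isnan(y)]
    if np.any(y < 0):
        raise ValueError("Tweedie support is y >= 0")
    if not np.any(y > 0):
        raise ValueError("all observations are zero; mean not identifiable")
    grid = DEFAULT_POWER_GRID if grid is None else np.asarray(grid, float)
    if np.any((grid <= 1.0) | (grid >= 2.0)):
        raise ValueError("profile grid must lie strictly inside (1, 2)")
    mu_hat = float(np.mean(y))
    rows = []
    for p in grid:
        phi = pearson_phi(y, mu_hat, float(p))
        ll = loglik(y, TweedieParams(mu=mu_hat, p=float(p), phi=phi))
        rows.append((float(p), phi, ll))
    table = pd.DataFrame(rows, columns=["p", "phi", "loglik"])
    best = table["loglik"].idxmax()
    return float(table.loc[best, "p"]), float(table.loc[best, "phi"]), table


def comparison_rvs(family: str, params: dict, n: int, seed) -> np.ndarray:
    """Samplers for the distribution families compared against the CPG law.

    ``zi_poisson`` and ``zi_negbinomial`` are zero-inflated counts: with
    probability ``weight`` the draw is forced to 0, otherwise it comes
    from the base count law — integer-valued, hence gappy on a continuous
    axis.  ``gamma`` is strictly positive with no zero mass.  ``cpg``
    delegates to :func:`rvs`.

    Parameters by family: ``zi_poisson``: weight, mean; ``zi_negbinomial``:
    weight, mean, size; ``gamma``: shape, scale; ``cpg``: mu, p, phi.
    """
    rng = np.random.default_rng(seed)
    if family in ("zi_poisson", "zi_negbinomial"):
        w = params["weight"]
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"zero-inflation weight must be in [0, 1], got {w}")
        if family == "zi_poisson":
            base = rng.poisson(params["mean"], size=n).astype(float)
        else:
            size, mean = params["size"], params["mean"]
            base = rng.negative_binomial(size, size / (size + mean), n).astype(float)
        base[rng.random(n) < w] = 0.0
        return base
    if family == "gamma":
        return rng.gamma(shape=params["shape"], scale=params["scale"], size=n)
    if family == "cpg":
        return rvs(TweedieParams(params["mu"], params["p"], params["phi"]), n, rng)
    raise ValueError(f"unknown family {family!r}")
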