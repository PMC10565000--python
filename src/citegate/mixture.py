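"""Two-component univariate normal mixture EM and positivity thresholds.

CITE-seq antibody signal on the CLR-log2 scale is modeled as two
overlapping normals: an ambient/negative component and a shifted positive
component.  The positivity threshold for an antibody is the point between
the component means where the posterior probability of the positive
component crosses 0.5, i.e. where the weighted component densities are
equal:  pi1 * phi(t; mu1, s1) = pi2 * phi(t; mu2, s2).

EM is initialized deterministically from the 25th/75th percentiles so fits
are reproducible without a seed; a per-iteration log-likelihood assertion
guards the EM monotonicity property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError

SIGMA_MIN_DEFAULT = 0.05
MIN_VALUES = 50


@dataclass
class MixtureFit:
    """Parameters of a fitted two-component normal mixture (mu1 < mu2)."""

    pi1: float
    pi2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    log_likelihood: float
    n_iter: int
    converged: bool
    ill_separated: bool = False   # component means within one SD of each other

    def __post_init__(self) -> None:
        if not (0.0 < self.pi1 < 1.0 and abs(self.pi1 + self.pi2 - 1.0) < 1e-9):
            raise ValueError("component weights must lie in (0,1) and sum to 1")
        if self.mu1 > self.mu2:
            raise ValueError("components must be ordered so mu1 <= mu2")

    @property
    def separation_sd(self) -> float:
        """Distance between means in units of the larger component SD."""
        return (self.mu2 - self.mu1) / max(self.sigma1, self.sigma2)


def fit_two_component_mixture(
    values,
    sigma_min: float = SIGMA_MIN_DEFAULT,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    n_restarts: int = 0,
) -> MixtureFit:
    """EM fit of a two-component univariate normal mixture.

    Deterministic quartile initialization; optional random restarts (off by
    default) are the only use of ``seed``.  Raises :class:`FitError` on
    degenerate input (fewer than 50 finite values, or ~zero variance), in
    which case callers fall back to a negative-reference threshold.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_VALUES:
        raise FitError(f"need >= {MIN_VALUES} finite values, got {x.size}")
    if x.std() < 1e-12:
        raise FitError("degenerate input: variance ~ 0")

    def run(mu_init: tuple[float, float]) -> MixtureFit:
        mu = np.array(mu_init, dtype=float)
        if mu[0] == mu[1]:
            mu[1] = mu[0] + max(x.std(), sigma_min)
        sigma = np.full(2, max(x.std() / 2.0, sigma_min))
        pi = np.array([0.5, 0.5])
        prev_ll = -np.inf
        ll = prev_ll
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: responsibilities from weighted normal densities
            logp = np.stack([
                np.log(pi[k]) + stats.norm.logpdf(x, mu[k], sigma[k]) for k in (0, 1)
            ])
            lse = np.logaddexp(logp[0], logp[1])
            ll = float(lse.sum())
            # EM guarantee: the observed-data log-likelihood never decreases
            assert ll >= prev_ll - 1e-6, "EM log-likelihood decreased"
            resp = np.exp(logp - lse)
            if ll - prev_ll < tol and it > 1:
                converged = True
                break
            prev_ll = ll
            # M-step: weighted means, SDs (floored), weights
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-10)
            mu = (resp * x).sum(axis=1) / nk
            var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
            sigma = np.maximum(np.sqrt(var), sigma_min)
            pi = np.clip(nk / x.size, 1e-10, 1 - 1e-10)
            pi = pi / pi.sum()
        order = np.argsort(mu)
        mu, sigma, pi = mu[order], sigma[order], pi[order]
        fit = MixtureFit(
            pi1=float(pi[0]), pi2=float(pi[1]),
            mu1=float(mu[0]), mu2=float(mu[1]),
            sigma1=float(sigma[0]), sigma2=float(sigma[1]),
            log_likelihood=ll, n_iter=it, converged=converged,
        )
        fit.ill_separated = (fit.mu2 - fit.mu1) < max(fit.sigma1, fit.sigma2)
        return fit

    q25, q75 = np.percentile(x, [25, 75])
    best = run((q25, q75))
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        lo, hi = x.min(), x.max()
        for _ in range(n_restarts):
            m = np.sort(rng.uniform(lo, hi, size=2))
            cand = run((m[0], m[1]))
            if cand.log_likelihood > best.log_likelihood:
                best = cand
    return best


def threshold_from_mixture(fit: MixtureFit, tol: float = 1e-9) -> float:
    """Posterior-0.5 crossing between the component means, by bisection.

    Solves pi1*phi(t; mu1, s1) = pi2*phi(t; mu2, s2) on (mu1, mu2); if the
    weighted densities do not cross inside the interval (pathological
    weight/SD imbalance) the midpoint is returned.
    """
    if not fit.converged:
        raise FitError("cannot derive a threshold from a non-converged fit")

    def g(t: float) -> float:
        return (np.log(fit.pi2) + stats.norm.logpdf(t, fit.mu2, fit.sigma2)
                - np.log(fit.pi1) - stats.norm.logpdf(t, fit.mu1, fit.sigma1))

    lo, hi = fit.mu1, fit.mu2
    if hi - lo < 1e-12:
        return (lo + hi) / 2.0
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:   # no crossing inside (mu1, mu2)
        return (lo + hi) / 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        gm = g(mid)
        if gm == 0.0:
            return mid
        if glo * gm <= 0:
            hi, ghi = mid, gm
        else:
            lo, glo = mid, gm
    return (lo + hi) / 2.0


def threshold_from_negative_reference(values_negative_cells, quantile: float = 0.99) -> float:
    """Upper quantile of a known-negative reference CLR distribution."""
    x = np.asarray(values_negative_cells, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_VALUES:
        raise FitError(
            f"negative reference needs >= {MIN_VALUES} cells, got {x.size}; "
            "threshold undetermined")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(x, quantile))
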