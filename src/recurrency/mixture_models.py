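"""Gamma-Poisson and two-process mixture models for site recurrence spectra.

Two generative models for the per-site SNV count x over l sites of one
triplet context, both allowing the rate to vary between sites:

* **Gamma-Poisson** (models 1a/1b): the per-site rate is mu * alpha with
  alpha drawn from a gamma law of mean 1 and shape k.  Marginally x is
  negative binomial with mean mu and size k; the zero class is
  (k / (k + mu))**k.

* **Two-process** (models 2a/2b): SNVs arise from a constant process
  contributing a fraction eps of the rate and a gamma-variable process
  contributing the rest, so the per-site rate is mu * (eps + (1 - eps) *
  alpha).  Marginally x is the convolution of Poisson(mu * eps) with the
  negative binomial of mean mu * (1 - eps) and size k.  eps = 1 recovers
  pure Poisson, eps = 0 the gamma-Poisson model.

The 'a' variants share one parameter set across all triplet contexts
(2 resp. 3 parameters); the 'b' variants give every context its own
(mu_i, k_i[, eps_i]) and the likelihood factorises over contexts, so each
context is fitted independently.

Given model expectations P(x) = l * pmf(x), the likelihood of observing n_x
sites with x SNVs treats each spectrum cell as Poisson:

    log L = sum_x [ -P(x) + n_x * log P(x) - log n_x! ],

summed over contexts.  Parameters are estimated by Nelder-Mead in
transformed space (log mu, log k, logit eps) from multiple jittered
moment-based starts, and nested models are compared by likelihood-ratio
tests.  Note that eps on [0, 1] and k > 0 put some null hypotheses on the
parameter boundary, where the chi-square reference for the LRT is
conservative; p-values are reported as computed, with this caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .recurrence import RecurrenceSpectrum

__all__ = [
    "MODEL_IDS",
    "NESTED_PAIRS",
    "GammaLaw",
    "MixtureModelFit",
    "gamma_poisson_pmf",
    "gamma_poisson_log_pmf",
    "two_process_pmf",
    "two_process_log_pmf",
    "spectrum_log_likelihood",
    "fit_model",
    "likelihood_ratio_test",
    "model_comparison_table",
]

MODEL_IDS = ("1a", "1b", "2a", "2b")
#: (null, alternative) pairs for which the LRT is defined.
NESTED_PAIRS = (("1a", "1b"), ("1a", "2a"), ("1a", "2b"), ("1b", "2b"), ("2a", "2b"))

#: Floor on expected counts inside the log-likelihood; avoids -inf from
#: numerical underflow while leaving genuinely impossible cells fatal.
EXPECTED_FLOOR = 1e-300


@dataclass(frozen=True)
class GammaLaw:
    """A gamma law constrained to mean 1: shape k, scale 1/k, variance 1/k."""

    shape: float

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError("gamma shape must be positive")

    @property
    def variance(self) -> float:
        return 1.0 / self.shape

    def density(self, alpha: np.ndarray) -> np.ndarray:
        return stats.gamma.pdf(alpha, a=self.shape, scale=1.0 / self.shape)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, 1.0 / self.shape, size=size)


# ---------------------------------------------------------------------------
# pmfs


def gamma_poisson_log_pmf(x, mu: float, shape: float) -> np.ndarray:
    """log pmf of the gamma-Poisson mixture = negative binomial.

    Size (dispersion) ``shape`` and mean ``mu``; the success probability of
    the NB parameterisation is k / (k + mu).  Evaluated in log space so it is
    stable down to shape ~ 1e-8 and far into the tail.
    """
    x = np.asarray(x)
    if mu < 0 or shape <= 0:
        raise ValueError("require mu >= 0 and shape > 0")
    if mu == 0:
        return np.where(x == 0, 0.0, -np.inf)
    # log NB(x; size=k, p=k/(k+mu)) written out via gammaln for stability
    k = shape
    log_p = np.log(k) - np.log(k + mu)
    log_q = np.log(mu) - np.log(k + mu)
    return gammaln(x + k) - gammaln(k) - gammaln(x + 1) + k * log_p + x * log_q


def gamma_poisson_pmf(x, mu: float, shape: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) pmf; see :func:`gamma_poisson_log_pmf`."""
    return np.exp(gamma_poisson_log_pmf(x, mu, shape))


def two_process_log_pmf(x, mu: float, shape: float, eps: float) -> np.ndarray:
    """log pmf of the two-process count model.

    The count is the sum of a Poisson(mu * eps) constant-process component
    and a gamma-Poisson(mu * (1 - eps), shape) variable-process component,
    computed as their convolution in log space.
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must lie in [0, 1]")
    x = np.atleast_1d(np.asarray(x, dtype=np.int64))
    m_const = mu * eps
    m_var = mu * (1.0 - eps)
    if m_var == 0.0:
        out = stats.poisson.logpmf(x, m_const)
    elif m_const == 0.0:
        out = gamma_poisson_log_pmf(x, m_var, shape)
    else:
        x_top = int(x.max())
        js = np.arange(x_top + 1)
        log_pois = js * np.log(m_const) - m_const - gammaln(js + 1.0)
        log_nb = gamma_poisson_log_pmf(js, m_var, shape)
        # terms[i, j] = log_pois[j] + log_nb[i - j] for j <= i, -inf above diagonal
        terms = log_pois[None, :] + log_nb[js[:, None] - js[None, :]]
        terms[js[:, None] < js[None, :]] = -np.inf
        full = logsumexp(terms, axis=1)
        out = full[x]
    return out if out.shape else float(out)


def two_process_pmf(x, mu: float, shape: float, eps: float) -> np.ndarray:
    """Two-process pmf; see :func:`two_process_log_pmf`."""
    return np.exp(two_process_log_pmf(x, mu, shape, eps))


# ---------------------------------------------------------------------------
# spectrum likelihood


def spectrum_log_likelihood(
    observed: RecurrenceSpectrum | np.ndarray,
    expected: np.ndarray,
) -> float:
    """Poisson-cell log-likelihood of an observed spectrum given expectations.

    ``expected`` holds P(x) = l * pmf(x) on the same x grid as the observed
    counts.  Expected values are floored at 1e-300 before taking logs; a cell
    that is structurally zero (expected == 0 exactly) with observed > 0 makes
    the model impossible and returns -inf.
    """
    obs = observed.counts if isinstance(observed, RecurrenceSpectrum) else np.asarray(observed, float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected spectra have different shapes")
    if ((exp == 0.0) & (obs > 0)).any():
        return -np.inf
    exp_f = np.maximum(exp, EXPECTED_FLOOR)
    return float(np.sum(-exp_f + obs * np.log(exp_f) - gammaln(obs + 1.0)))


def _model_log_pmf(xs: np.ndarray, mu: float, shape: float, eps: float | None) -> np.ndarray:
    if eps is None:
        return gamma_poisson_log_pmf(xs, mu, shape)
    return two_process_log_pmf(xs, mu, shape, eps)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MixtureModelFit:
    """A fitted mixture model for one genomic fraction.

    Per-context parameter dicts always cover every context; shared-parameter
    models ('a' variants) replicate the single estimate across contexts.
    ``eps`` is None for the pure gamma-Poisson family.
    """

    model_id: str
    fraction: str
    mu: Dict[str, float]
    shape: Dict[str, float]
    eps: Dict[str, float] | None
    log_likelihood: float
    n_params: int
    converged: bool
    n_contexts: int
    n_starts: int = 0
    messages: Tuple[str, ...] = ()

    @property
    def median_shape(self) -> float:
        return float(np.median(list(self.shape.values())))

    @property
    def median_eps(self) -> float | None:
        if self.eps is None:
            return None
        return float(np.median(list(self.eps.values())))


def n_params_for(model_id: str, n_contexts: int) -> int:
    per = {"1a": 2, "1b": 2 * n_contexts, "2a": 3, "2b": 3 * n_contexts}
    try:
        return per[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}") from None


def _moment_init(spectra: Sequence[RecurrenceSpectrum]) -> Tuple[float, float]:
    """(mu0, k0) from pooled first/second moments of the per-site counts."""
    l = sum(s.l for s in spectra)
    m = sum(s.m for s in spectra)
    mu0 = max(m / l, 1e-12) if l else 1e-12
    ex2 = sum(float((np.arange(s.counts.size) ** 2 * s.counts).sum()) for s in spectra)
    var = ex2 / l - mu0**2 if l else 0.0
    overdisp = var - mu0
    k0 = mu0**2 / overdisp if overdisp > 0 else 10.0
    return mu0, float(np.clip(k0, 1e-6, 1e4))


def _cells_loglik(
    spectra: Sequence[RecurrenceSpectrum], mu: float, shape: float, eps: float | None
) -> float:
    # one pmf evaluation at the widest grid serves every context (shared params)
    xs = np.arange(max(s.counts.size for s in spectra))
    log_pmf = _model_log_pmf(xs, mu, shape, eps)
    total = 0.0
    for s in spectra:
        expected = s.l * np.exp(log_pmf[: s.counts.size])
        total += spectrum_log_likelihood(s, expected)
        if not np.isfinite(total):
            return -np.inf
    return total


def _fit_shared(
    spectra: Sequence[RecurrenceSpectrum],
    with_eps: bool,
    n_starts: int,
    seed: int,
    eps_init: float,
    maxiter: int,
) -> Tuple[float, float, float | None, float, bool]:
    rng = np.random.default_rng(seed)
    mu0, k0 = _moment_init(spectra)
    theta0 = [np.log(mu0), np.log(k0)]
    if with_eps:
        theta0.append(np.log(eps_init / (1 - eps_init)))
    theta0 = np.array(theta0)

    def negloglik(theta: np.ndarray) -> float:
        mu = float(np.exp(np.clip(theta[0], -60, 10)))
        shape = float(np.exp(np.clip(theta[1], -40, 40)))
        eps = float(1.0 / (1.0 + np.exp(-np.clip(theta[2], -40, 40)))) if with_eps else None
        ll = _cells_loglik(spectra, mu, shape, eps)
        return -ll if np.isfinite(ll) else 1e300

    best = None
    converged = False
    for i in range(n_starts):
        start = theta0 if i == 0 else theta0 + rng.normal(0.0, 0.5, size=theta0.size)
        res = optimize.minimize(
            negloglik,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": maxiter, "maxfev": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    mu = float(np.exp(np.clip(best.x[0], -60, 10)))
    shape = float(np.exp(np.clip(best.x[1], -40, 40)))
    eps = float(1.0 / (1.0 + np.exp(-np.clip(best.x[2], -40, 40)))) if with_eps else None
    return mu, shape, eps, -float(best.fun), converged


def fit_model(
    spectra: Mapping[str, RecurrenceSpectrum],
    model_id: str,
    n_starts: int = 5,
    seed: int = 0,
    eps_init: float = 0.95,
    maxiter: int = 4000,
    fraction: str | None = None,
) -> MixtureModelFit:
    """Maximum-likelihood fit of one model to a fraction's per-context spectra.

    Models '1a'/'2a' share parameters across contexts (one joint 2- or
    3-parameter Nelder-Mead optimisation); '1b'/'2b' fit each context
    independently, which is exact because the likelihood factorises.  Every
    optimisation is run from ``n_starts`` jittered moment-based starting
    points and the best is kept; a fit that never reports convergence is
    returned flagged rather than discarded.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if not spectra:
        raise ValueError("no spectra to fit")
    contexts = sorted(spectra)
    frac = fraction if fraction is not None else next(iter(spectra.values())).fraction
    with_eps = model_id.startswith("2")
    shared = model_id.endswith("a")
    messages: list[str] = []

    if shared:
        cells = [spectra[c] for c in contexts]
        mu, shape, eps, ll, conv = _fit_shared(cells, with_eps, n_starts, seed, eps_init, maxiter)
        mu_d = {c: mu for c in contexts}
        k_d = {c: shape for c in contexts}
        e_d = {c: eps for c in contexts} if with_eps else None
    else:
        mu_d, k_d, e_d = {}, {}, ({} if with_eps else None)
        ll = 0.0
        conv = True
        for j, c in enumerate(contexts):
            mu, shape, eps, ll_c, conv_c = _fit_shared(
                [spectra[c]], with_eps, n_starts, seed + 1000 + j, eps_init, maxiter
            )
            mu_d[c], k_d[c] = mu, shape
            if with_eps:
                e_d[c] = eps
            ll += ll_c
            conv = conv and conv_c
            if not conv_c:
                messages.append(f"context {c}: no convergence after {n_starts} starts")
    if not conv:
        warnings.warn(f"model {model_id}: optimiser did not report convergence", stacklevel=2)
    return MixtureModelFit(
        model_id=model_id,
        fraction=frac,
        mu=mu_d,
        shape=k_d,
        eps=e_d,
        log_likelihood=ll,
        n_params=n_params_for(model_id, len(contexts)),
        converged=conv,
        n_contexts=len(contexts),
        n_starts=n_starts,
        messages=tuple(messages),
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    null_model: str
    alt_model: str


def likelihood_ratio_test(null_fit: MixtureModelFit, alt_fit: MixtureModelFit) -> LRTResult:
    """Likelihood-ratio test of a nested model pair.

    statistic = 2 * (logL_alt - logL_null), df = difference in parameter
    count, p from the chi-square upper tail.  A marginally negative
    improvement (optimiser noise) is clipped to 0.  Null parameters on the
    boundary (eps in [0, 1], k > 0) make the chi-square reference
    conservative; see the module docstring.
    """
    if (null_fit.model_id, alt_fit.model_id) not in NESTED_PAIRS:
        raise ValueError(
            f"model {null_fit.model_id} is not nested in {alt_fit.model_id}"
        )
    delta = alt_fit.log_likelihood - null_fit.log_likelihood
    if delta < -1e-4:  # deficits within optimiser tolerance are silently clipped
        warnings.warn(
            "alternative fit has lower likelihood than the null "
            f"({delta:.3g}); statistic clipped at 0 — consider more restarts",
            stacklevel=2,
        )
    stat = max(0.0, 2.0 * delta)
    df = alt_fit.n_params - null_fit.n_params
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)), null_fit.model_id, alt_fit.model_id)


def model_comparison_table(
    spectra: Mapping[str, RecurrenceSpectrum],
    models: Sequence[str] = MODEL_IDS,
    alpha: float = 0.05,
    n_starts: int = 5,
    seed: int = 0,
    fraction: str | None = None,
) -> Tuple[pd.DataFrame, Dict[str, MixtureModelFit]]:
    """Fit the requested models to one fraction and flag the LRT-preferred one.

    Preference walks the nesting lattice: starting from the simplest fitted
    model, a more complex model replaces the incumbent when the LRT between
    them is significant at ``alpha`` (ties broken toward fewer parameters).
    Returns a table with one row per model — parameter count N,
    log-likelihood, median shape and median eps across contexts — and the
    fits themselves.
    """
    fits = {
        mid: fit_model(spectra, mid, n_starts=n_starts, seed=seed, fraction=fraction)
        for mid in models
    }
    order = [m for m in MODEL_IDS if m in fits]
    preferred = order[0]
    for mid in order[1:]:
        if (preferred, mid) in NESTED_PAIRS:
            if likelihood_ratio_test(fits[preferred], fits[mid]).p_value < alpha:
                preferred = mid
    rows = []
    for mid in order:
        f = fits[mid]
        rows.append(
            {
                "model": mid,
                "fraction": f.fraction,
                "N": f.n_params,
                "log_likelihood": f.log_likelihood,
                "median_shape": f.median_shape,
                "median_eps": f.median_eps,
                "converged": f.converged,
                "preferred": mid == preferred,
            }
        )
    return pd.DataFrame(rows), fits
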