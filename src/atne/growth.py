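"""Von Bertalanffy growth: evaluation, fractional age, and Bayesian fitting.

The growth of an individual fish is described by the von Bertalanffy growth
model (VBGM)

.. math:: E[L(a)] = L_\\infty - (L_\\infty - L_0)\\,e^{-k a},

where ``L_inf`` is the asymptotic length (cm), ``k`` Brody's growth
coefficient (1/year) and ``L0`` the length at birth (cm).  Observed lengths at
fractional age ``a_t`` scatter around the curve following a lognormal
distribution whose *mean* equals the VBGM value: the lognormal location is
``mu_t = ln(E[L_t]) - sigma^2/2`` with shape parameter ``sigma``.

The Bayesian fit places independent uniform priors on ``(L_inf, k, L0,
sigma)`` and samples the posterior with an affine-invariant ensemble sampler
(several independent ensembles act as chains; split-Rhat and effective sample
size are computed with arviz).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VBGMParams",
    "PriorBounds",
    "VBGMPosterior",
    "vbgm_length",
    "fractional_age",
    "loglik_lognormal",
    "fit_bvbgm",
    "posterior_summary",
    "read_length_at_age",
]

_PARAM_NAMES = ("l_inf", "k", "l0", "sigma")


@dataclass(frozen=True)
class VBGMParams:
    """Point parameters of the von Bertalanffy growth model.

    Attributes
    ----------
    l_inf : float
        Asymptotic length (cm).  Must exceed ``l0``.
    k : float
        Brody's growth coefficient (1/year), strictly positive.
    l0 : float
        Length at birth (cm), non-negative.
    """

    l_inf: float
    k: float
    l0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.l_inf) and np.isfinite(self.k) and np.isfinite(self.l0)):
            raise ValueError("VBGM parameters must be finite")
        if self.l0 < 0:
            raise ValueError(f"L0 must be >= 0, got {self.l0}")
        if self.l_inf <= self.l0:
            raise ValueError(f"L_inf ({self.l_inf}) must exceed L0 ({self.l0})")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")


def vbgm_length(params: VBGMParams, age):
    """Expected length (cm) at ``age`` (years) under the VBGM.

    ``age`` may be a scalar or array; negative ages raise ``ValueError``.
    The result is strictly increasing in age and bounded above by ``L_inf``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = params.l_inf - (params.l_inf - params.l0) * np.exp(-params.k * age)
    return out if out.ndim else float(out)


_BIRTHDAY = (6, 1)  # June 1, the nominal date of birth


def fractional_age(completed_years: int, capture_date: _dt.date) -> float:
    """Age in years plus the fraction of the current growth year.

    Fish are assigned a nominal birthday of June 1; the fractional part is the
    number of days since the most recent June 1 divided by 365 (leap days are
    ignored).  The result lies in ``[completed_years, completed_years + 1)``.
    """
    if completed_years < 0:
        raise ValueError("completed_years must be >= 0")
    birthday = _dt.date(capture_date.year, *_BIRTHDAY)
    if capture_date < birthday:
        birthday = _dt.date(capture_date.year - 1, *_BIRTHDAY)
    days = (capture_date - birthday).days
    return completed_years + min(days / 365.0, 1.0 - 1e-12)


def _lognormal_mu(params: VBGMParams, ages: np.ndarray, sigma: float) -> np.ndarray:
    # location such that the lognormal mean equals the VBGM expectation
    return np.log(vbgm_length(params, ages)) - 0.5 * sigma**2


def loglik_lognormal(data: pd.DataFrame, params: VBGMParams, sigma: float) -> float:
    """Lognormal log-likelihood of length-at-age records under the VBGM.

    ``data`` must have columns ``fractional_age`` and ``length_cm``.  The
    lognormal location at each age is ``ln(E[L_t]) - sigma^2/2`` so that the
    distribution's mean equals the VBGM expectation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    ages = np.asarray(data["fractional_age"], dtype=float)
    lengths = np.asarray(data["length_cm"], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("all lengths must be > 0")
    mu = _lognormal_mu(params, ages, sigma)
    z = (np.log(lengths) - mu) / sigma
    return float(
        np.sum(-np.log(lengths) - math.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z**2)
    )


@dataclass(frozen=True)
class PriorBounds:
    """Uniform prior bounds for ``(L_inf, k, L0, sigma)``.

    Each entry is a ``(lower, upper)`` pair with ``0 <= lower <= upper``.
    A zero-width pair fixes that parameter at the common value (useful e.g.
    for pinning ``L0`` from the literature).
    """

    l_inf: tuple[float, float] = (5.0, 150.0)
    k: tuple[float, float] = (0.01, 1.5)
    l0: tuple[float, float] = (0.0, 10.0)
    sigma: tuple[float, float] = (0.001, 1.0)

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"bounds for {name} must be finite")
            if lo < 0 or lo > hi:
                raise ValueError(f"require 0 <= lower <= upper for {name}, got ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in _PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in _PARAM_NAMES])


@dataclass
class VBGMPosterior:
    """MCMC posterior over ``(L_inf, k, L0, sigma)``.

    ``draws`` has shape ``(n_chains, n_draws, 4)`` with the parameter order
    ``(l_inf, k, l0, sigma)``.  ``rhat`` and ``ess`` are per-parameter
    split-chain scale-reduction factors and effective sample sizes;
    ``converged`` flags ``max(rhat) <= rhat_threshold``.
    """

    draws: np.ndarray
    prior: PriorBounds
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    rhat_threshold: float = 1.05
    param_names: tuple = _PARAM_NAMES

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def converged(self) -> bool:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(vals) and max(vals) <= self.rhat_threshold

    def flat(self) -> np.ndarray:
        """All draws pooled across chains, shape ``(n_chains*n_draws, 4)``."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flat(), columns=list(self.param_names))
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.draws.shape[1]))
        return df

    def mean_params(self) -> VBGMParams:
        m = self.flat().mean(axis=0)
        return VBGMParams(l_inf=m[0], k=m[1], l0=m[2])


def _log_prob(theta: np.ndarray, ages: np.ndarray, lengths: np.ndarray,
              log_lengths: np.ndarray, lower: np.ndarray, upper: np.ndarray):
    """Vectorised log posterior; ``theta`` is (4,) or (n_walkers, 4)."""
    theta = np.atleast_2d(theta)
    n = theta.shape[0]
    out = np.full(n, -np.inf)
    ok = (np.all(theta >= lower, axis=1) & np.all(theta <= upper, axis=1)
          & (theta[:, 0] > theta[:, 2]) & (theta[:, 1] > 0) & (theta[:, 3] > 0))
    if np.any(ok):
        l_inf, k, l0, sigma = (theta[ok, i][:, None] for i in range(4))
        mean = l_inf - (l_inf - l0) * np.exp(-k * ages[None, :])
        good = np.all(mean > 0, axis=1)
        mu = np.log(np.maximum(mean, 1e-300)) - 0.5 * sigma**2
        z = (log_lengths[None, :] - mu) / sigma
        ll = (np.sum(-0.5 * z**2, axis=1) - len(ages) * np.log(sigma[:, 0])
              - np.sum(log_lengths) - 0.5 * len(ages) * math.log(2 * math.pi))
        ll[~good] = -np.inf
        out[ok] = ll
    return out if out.shape[0] > 1 else float(out[0])


def fit_bvbgm(
    data: pd.DataFrame,
    prior: PriorBounds | None = None,
    n_chains: int = 4,
    warmup: int = 1000,
    draws: int = 4000,
    n_walkers: int = 16,
    seed: int | None = None,
) -> VBGMPosterior:
    """Fit the Bayesian VBGM to length-at-age data.

    Runs ``n_chains`` independent affine-invariant ensembles (emcee), each
    discarding ``warmup`` iterations and recording ``draws`` posterior draws
    (pooled over the ensemble's walkers).  Uniform priors per ``prior``;
    zero-width bounds fix a parameter.  Convergence diagnostics (split-Rhat,
    ESS) are attached to the returned posterior; non-convergence is flagged,
    never silently discarded.
    """
    import emcee

    if len(data) == 0:
        raise ValueError("data must be non-empty")
    if n_chains < 2:
        raise ValueError("need at least 2 chains for split-chain diagnostics")
    prior = prior or PriorBounds()
    ages = np.asarray(data["fractional_age"], dtype=float)
    lengths = np.asarray(data["length_cm"], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("all lengths must be > 0")
    log_lengths = np.log(lengths)
    lower, upper = prior.lower, prior.upper
    widths = upper - lower

    if np.all(widths == 0):
        point = np.tile(lower, (n_chains, draws, 1))
        return VBGMPosterior(draws=point, prior=prior,
                             rhat={n: np.nan for n in _PARAM_NAMES},
                             ess={n: np.nan for n in _PARAM_NAMES})

    rng = np.random.default_rng(seed)
    n_dim = 4
    iters_post = max(1, math.ceil(draws / n_walkers))
    all_chains = []
    for c in range(n_chains):
        # seed walkers uniformly inside the prior box, rejecting -inf starts
        p0 = np.empty((n_walkers, n_dim))
        for w in range(n_walkers):
            for _ in range(1000):
                cand = lower + rng.random(n_dim) * widths
                cand[widths == 0] = lower[widths == 0]
                if np.isfinite(_log_prob(cand, ages, lengths, log_lengths, lower, upper)):
                    p0[w] = cand
                    break
            else:
                raise RuntimeError("could not find a valid starting point inside the prior")
        sampler = emcee.EnsembleSampler(
            n_walkers, n_dim, _log_prob,
            args=(ages, lengths, log_lengths, lower, upper),
            vectorize=True,
        )
        sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
        state = sampler.run_mcmc(p0, warmup + iters_post, progress=False)
        del state
        chain = sampler.get_chain(discard=warmup)  # (iters_post, n_walkers, 4)
        flat = chain.reshape(-1, n_dim)[:draws]
        all_chains.append(flat)
    draws_arr = np.stack(all_chains)  # (n_chains, draws, 4)

    rhat, ess = _diagnostics(draws_arr, widths)
    return VBGMPosterior(draws=draws_arr, prior=prior, rhat=rhat, ess=ess)


def _diagnostics(draws_arr: np.ndarray, widths: np.ndarray) -> tuple[dict, dict]:
    import arviz as az

    rhat, ess = {}, {}
    for i, name in enumerate(_PARAM_NAMES):
        x = draws_arr[:, :, i]
        if widths[i] == 0 or np.allclose(x, x.flat[0]):
            rhat[name], ess[name] = np.nan, np.nan
            continue
        rhat[name] = float(az.rhat(x))
        ess[name] = float(az.ess(x))
    return rhat, ess


def posterior_summary(posterior: VBGMPosterior, ci_mass: float = 0.9) -> pd.DataFrame:
    """Per-parameter posterior mean, sd and central credible interval.

    The interval is the central ``ci_mass`` quantile interval.
    """
    if not 0 < ci_mass <= 1:
        raise ValueError("ci_mass must be in (0, 1]")
    flat = posterior.flat()
    if flat.size == 0:
        raise ValueError("posterior has no draws")
    alpha = (1 - ci_mass) / 2
    rows = []
    for i, name in enumerate(posterior.param_names):
        x = flat[:, i]
        rows.append({
            "param": name,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "ci_lower": float(np.quantile(x, alpha)),
            "ci_upper": float(np.quantile(x, 1 - alpha)),
            "rhat": posterior.rhat.get(name, np.nan),
            "ess": posterior.ess.get(name, np.nan),
        })
    return pd.DataFrame(rows).set_index("param")


def read_length_at_age(path) -> pd.DataFrame:
    """Read a ``fractional_age,length_cm`` CSV of length-at-age records."""
    df = pd.read_csv(path)
    missing = {"fractional_age", "length_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in length-at-age CSV: {sorted(missing)}")
    return df
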