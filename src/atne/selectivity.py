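"""Bell-shaped fishing-gear selectivity.

Gillnets (and, as modelled here, trawl codends) catch fish of intermediate
length preferentially.  Selectivity as a function of length ``L`` is the
scaled Gaussian bell

.. math:: \\hat S(L \\mid \\mu, \\sigma, \\delta)
          = \\frac{\\delta}{\\sqrt{2\\pi}\\,\\sigma}
            e^{-(L-\\mu)^2 / (2\\sigma^2)},

fitted to catch-biomass-by-length-class data by least squares (derivative-free
simplex with multi-start).  Downstream, only the normalised shape
``S(L)/S(mu)`` matters: the per-length instantaneous fishing mortality is the
peak mortality ``E`` times that fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "SelectivityCurve",
    "selectivity_eval",
    "normalized_selectivity",
    "fit_selectivity",
    "aggregate_catch",
    "read_catch_by_length",
]


@dataclass(frozen=True)
class SelectivityCurve:
    """Bell-shaped selectivity: mode ``mu`` (cm), width ``sigma`` (cm),
    scale ``delta`` (catch-biomass units per length class)."""

    mu: float
    sigma: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")


def selectivity_eval(curve: SelectivityCurve, length):
    """Selectivity at ``length`` (cm); symmetric about and maximal at ``mu``."""
    length = np.asarray(length, dtype=float)
    out = (curve.delta / (math.sqrt(2 * math.pi) * curve.sigma)
           * np.exp(-((length - curve.mu) ** 2) / (2 * curve.sigma**2)))
    return out if out.ndim else float(out)


def normalized_selectivity(curve: SelectivityCurve, length):
    """Selectivity as a fraction of its peak value, in ``(0, 1]``.

    Independent of ``delta``; equals 1 at ``L = mu`` and ``exp(-1/2)`` at
    ``L = mu ± sigma``.
    """
    length = np.asarray(length, dtype=float)
    out = np.exp(-((length - curve.mu) ** 2) / (2 * curve.sigma**2))
    return out if out.ndim else float(out)


def aggregate_catch(records) -> pd.DataFrame:
    """Aggregate (length, mass) records into 1-cm length classes.

    Classes are ``[c, c+1)`` keyed by the integer floor ``c`` of the length;
    masses are summed per class.  Returns a DataFrame with columns
    ``class_lower_cm`` and ``biomass_g`` sorted by class.
    """
    records = list(records)
    if not records:
        return pd.DataFrame(columns=["class_lower_cm", "biomass_g"])
    lengths = np.array([r[0] for r in records], dtype=float)
    masses = np.array([r[1] for r in records], dtype=float)
    if np.any(lengths < 0):
        raise ValueError("lengths must be >= 0")
    if np.any(masses < 0):
        raise ValueError("masses must be >= 0")
    lower = np.floor(lengths).astype(int)
    df = (pd.DataFrame({"class_lower_cm": lower, "biomass_g": masses})
          .groupby("class_lower_cm", as_index=False).sum()
          .sort_values("class_lower_cm", ignore_index=True))
    return df


def _class_midpoints(class_lower: np.ndarray, width: float = 1.0) -> np.ndarray:
    # evaluation abscissa for a class [c, c+width): its midpoint c + width/2
    return class_lower + width / 2.0


def _objective(theta: np.ndarray, mid: np.ndarray, biomass: np.ndarray) -> float:
    mu, log_sigma, log_delta = theta
    sigma, delta = math.exp(log_sigma), math.exp(log_delta)
    pred = delta / (math.sqrt(2 * math.pi) * sigma) * np.exp(
        -((mid - mu) ** 2) / (2 * sigma**2))
    return float(np.sum((biomass - pred) ** 2))


def fit_selectivity(
    catch: pd.DataFrame,
    starts=None,
    n_starts: int = 5,
    class_width: float = 1.0,
    seed: int | None = None,
) -> tuple[SelectivityCurve, float]:
    """Least-squares fit of the bell curve to catch-by-length-class data.

    Minimises the sum of squared residuals between observed class biomasses
    and the curve evaluated at class midpoints, with a Nelder-Mead simplex
    from ``n_starts`` starting points seeded at the data moments (the heaviest
    class gives the ``mu`` start, the biomass-weighted SD the ``sigma`` start)
    plus seeded jitter.  Returns the best curve and its residual sum of
    squares.
    """
    if starts is None:
        starts = []
    class_lower = np.asarray(catch["class_lower_cm"], dtype=float)
    biomass = np.asarray(catch["biomass_g"], dtype=float)
    if np.sum(biomass > 0) < 3:
        raise ValueError("need at least 3 classes with positive biomass")
    mid = _class_midpoints(class_lower, class_width)

    total = biomass.sum()
    mu0 = mid[int(np.argmax(biomass))]
    w_mean = float(np.sum(mid * biomass) / total)
    w_sd = float(math.sqrt(max(np.sum((mid - w_mean) ** 2 * biomass) / total, 1e-6)))
    delta0 = float(biomass.max() * math.sqrt(2 * math.pi) * w_sd)

    rng = np.random.default_rng(seed)
    start_list = [(mu0, w_sd, delta0), (w_mean, w_sd, delta0)]
    start_list += [tuple(s) for s in starts]
    while len(start_list) < n_starts:
        start_list.append((
            mu0 + rng.normal(scale=w_sd),
            w_sd * math.exp(rng.normal(scale=0.5)),
            delta0 * math.exp(rng.normal(scale=0.5)),
        ))

    best = None
    for mu_s, sigma_s, delta_s in start_list:
        theta0 = np.array([mu_s, math.log(max(sigma_s, 1e-6)),
                           math.log(max(delta_s, 1e-12))])
        if not np.all(np.isfinite(theta0)):
            continue
        res = minimize(_objective, theta0, args=(mid, biomass),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000, "maxfev": 5000})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all selectivity fit starts produced non-finite objectives")
    mu, log_sigma, log_delta = best.x
    return SelectivityCurve(mu=float(mu), sigma=float(math.exp(log_sigma)),
                            delta=float(math.exp(log_delta))), float(best.fun)


def read_catch_by_length(path) -> pd.DataFrame:
    """Read a ``class_lower_cm,biomass_g`` CSV of catch-by-length-class data."""
    df = pd.read_csv(path)
    missing = {"class_lower_cm", "biomass_g"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in catch CSV: {sorted(missing)}")
    return df
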