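"""Evolving growth traits on a discrete genotype grid.

Two focal fish species carry von Bertalanffy growth traits ``(L_inf, k)``
discretised on a bounded rectangular grid; each cell is a "genotype group"
holding its own biomass within every age guild.  Reproduction mixes the
parental trait distribution through a pair kernel: offspring of a parent pair
``(t1, t2)`` are bivariate-normally distributed around the pair midpoint with
covariance

    Sigma = Omega^{1/2} Lambda Omega^{1/2},
    Omega = Omega_G + Omega_A,
    Omega_G = c_V * diag( (t1-t2)^2 / 2 ),        # genotypic component
    Omega_A = diag( sigma_Linf^2, sigma_k^2 ),    # additive phenotypic component

where ``Lambda`` carries the trait correlation ``rho``.  The larvae trait
distribution is the pair-probability-weighted mixture of these kernels,
discretised cell-by-cell through the bivariate normal CDF and truncated to
the grid (each component renormalised to its in-grid mass, so reproductive
biomass is conserved).

Heritability is tracked as ``H = V_G / V_P`` where ``V_P`` is the marginal
larvae trait variance with the full kernel and ``V_G`` the same with the
additive phenotypic component switched off; truncation at the grid border can
push ``H`` above one.

The mixture has one component per ordered parent-cell pair (up to ``G^2``).
The implementation groups pairs by their trait separation — components in a
group share the same covariance, so the group collapses to a 2-D convolution
of a midpoint-weight array with a single discretised kernel — and optionally
merges groups whose kernel widths differ by less than a relative tolerance.
With ``eps_pair=0`` and ``merge_tol=0`` the result equals the full double sum
to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve as _convolve
from scipy.special import ndtr

from atne._bvn import bvn_cdf, rectangle_masses

__all__ = [
    "TraitGrid",
    "ReproductionParams",
    "TraitDistribution",
    "ReproductionFailure",
    "parent_distribution",
    "pair_kernel",
    "larvae_distribution",
    "spawn",
    "age_guilds",
    "genotype_phenotype_variances",
    "heritability",
    "initial_trait_distribution",
]


class ReproductionFailure(RuntimeError):
    """Raised when there is no reproductive biomass to spawn from."""


@dataclass(frozen=True)
class TraitGrid:
    """Rectangular ``(L_inf, k)`` trait grid with ``n_l * n_k`` cells.

    Axis 0 indexes ``L_inf`` (cm), axis 1 indexes ``k`` (1/year); cells
    partition the rectangle exactly.
    """

    l_inf_bounds: tuple[float, float]
    k_bounds: tuple[float, float]
    n_l: int = 40
    n_k: int = 40

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("l_inf", self.l_inf_bounds), ("k", self.k_bounds)):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} bounds must be finite with low < high")
        if self.n_l < 1 or self.n_k < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_l, self.n_k)

    @property
    def n_cells(self) -> int:
        return self.n_l * self.n_k

    @property
    def h_l(self) -> float:
        return (self.l_inf_bounds[1] - self.l_inf_bounds[0]) / self.n_l

    @property
    def h_k(self) -> float:
        return (self.k_bounds[1] - self.k_bounds[0]) / self.n_k

    @property
    def l_edges(self) -> np.ndarray:
        return self.l_inf_bounds[0] + self.h_l * np.arange(self.n_l + 1)

    @property
    def k_edges(self) -> np.ndarray:
        return self.k_bounds[0] + self.h_k * np.arange(self.n_k + 1)

    @property
    def l_centers(self) -> np.ndarray:
        return self.l_inf_bounds[0] + self.h_l * (np.arange(self.n_l) + 0.5)

    @property
    def k_centers(self) -> np.ndarray:
        return self.k_bounds[0] + self.h_k * (np.arange(self.n_k) + 0.5)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * sum(self.l_inf_bounds), 0.5 * sum(self.k_bounds))

    def contains(self, tp) -> bool:
        l, k = tp
        return (self.l_inf_bounds[0] <= l <= self.l_inf_bounds[1]
                and self.k_bounds[0] <= k <= self.k_bounds[1])


@dataclass(frozen=True)
class ReproductionParams:
    """Parameters of the reproduction (inheritance) model.

    ``c_v`` scales the genotypic variance of a parent pair; ``sigma_l_inf``
    (cm) and ``sigma_k`` (1/year) are the additive phenotypic standard
    deviations; ``rho`` the trait correlation (non-positive for the
    growth-vs-size trade-off); ``u`` the efficiency converting reproductive
    biomass into larvae biomass.
    """

    c_v: float = 0.25
    sigma_l_inf: float = 3.0
    sigma_k: float = 0.03
    rho: float = -0.7
    u: float = 0.8

    def __post_init__(self) -> None:
        if self.c_v < 0:
            raise ValueError("c_v must be >= 0")
        if self.sigma_l_inf < 0 or self.sigma_k < 0:
            raise ValueError("additive phenotypic SDs must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if not 0 < self.u <= 1:
            raise ValueError("u must be in (0, 1]")

    def without_phenotypic(self) -> "ReproductionParams":
        """Same kernel with the additive phenotypic component removed."""
        return ReproductionParams(c_v=self.c_v, sigma_l_inf=0.0, sigma_k=0.0,
                                  rho=self.rho, u=self.u)


@dataclass
class TraitDistribution:
    """Probability mass per grid cell; masses >= 0 and summing to 1."""

    grid: TraitGrid
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != self.grid.shape:
            raise ValueError(f"mass shape {self.mass.shape} != grid {self.grid.shape}")
        if np.any(self.mass < 0):
            raise ValueError("masses must be >= 0")
        if abs(self.mass.sum() - 1.0) > 1e-10:
            raise ValueError(f"masses must sum to 1, got {self.mass.sum()!r}")

    def mean(self) -> tuple[float, float]:
        pl = self.mass.sum(axis=1)
        pk = self.mass.sum(axis=0)
        return (float(pl @ self.grid.l_centers), float(pk @ self.grid.k_centers))

    def marginal_variances(self) -> tuple[float, float]:
        pl = self.mass.sum(axis=1)
        pk = self.mass.sum(axis=0)
        ml = pl @ self.grid.l_centers
        mk = pk @ self.grid.k_centers
        return (float(pl @ (self.grid.l_centers - ml) ** 2),
                float(pk @ (self.grid.k_centers - mk) ** 2))


def parent_distribution(pools: np.ndarray, grid: TraitGrid) -> TraitDistribution:
    """Parent trait distribution from reproductive pools.

    ``pools`` has shape ``(n_age_guilds, n_l, n_k)``; lineage totals are
    summed across age guilds and divided by the grand total.
    """
    pools = np.asarray(pools, dtype=float)
    if pools.ndim == 2:
        pools = pools[None]
    if pools.shape[1:] != grid.shape:
        raise ValueError(f"pool shape {pools.shape[1:]} != grid {grid.shape}")
    lineage = pools.sum(axis=0)
    total = lineage.sum()
    if total <= 0:
        raise ReproductionFailure("no reproductive biomass: zero total pool")
    return TraitDistribution(grid, lineage / total)


def pair_kernel(tp1, tp2, params: ReproductionParams,
                grid: TraitGrid | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Offspring kernel (mean, covariance) for one parent pair.

    The mean is the pair midpoint; the covariance combines the genotypic
    component ``c_v * diag((t1 - t2)^2 / 2)`` with the additive phenotypic
    component and the trait correlation ``rho``.
    """
    tp1 = np.asarray(tp1, dtype=float)
    tp2 = np.asarray(tp2, dtype=float)
    if grid is not None:
        for tp in (tp1, tp2):
            if not grid.contains(tp):
                raise ValueError(f"parent traits {tuple(tp)} outside the trait grid")
    mean = 0.5 * (tp1 + tp2)
    pair_var = 0.5 * (tp1 - tp2) ** 2          # two-point sample variance
    omega = params.c_v * pair_var + np.array(
        [params.sigma_l_inf**2, params.sigma_k**2])
    sq = np.sqrt(omega)
    cov = np.array([
        [omega[0], params.rho * sq[0] * sq[1]],
        [params.rho * sq[0] * sq[1], omega[1]],
    ])
    # PSD by construction for |rho| <= 1
    assert cov[0, 1] ** 2 <= cov[0, 0] * cov[1, 1] + 1e-30
    return mean, cov


# ---------------------------------------------------------------------------
# larvae distribution: grouped-convolution mixture discretisation


def _axis_kernel_1d(n: int, h: float, sd: float, m: int) -> np.ndarray:
    """1-D cell masses at half-step centre offsets d = -m..m."""
    if sd == 0.0:
        k = np.zeros(2 * m + 1)
        k[m] = 1.0               # offset 0: inside the cell
        if m >= 1:
            k[m - 1] = 0.5       # offset +-1: on a shared edge
            k[m + 1] = 0.5
        return k
    edge_offsets = np.arange(-(m + 1), m + 2) * (h / 2.0)
    c = ndtr(edge_offsets / sd)
    return c[2:] - c[:-2]


def _axis_window(n: int, h: float, sd: float, windowed: bool) -> int:
    """Half-width (in half-step units) of the kernel support to evaluate."""
    full = 2 * n - 2
    if not windowed or sd == 0.0:
        return full
    m = int(np.ceil(8.0 * sd / (h / 2.0))) + 2   # +-8 sd covers all but ~1e-15
    return min(m, full)


def _joint_kernel(grid: TraitGrid, sd_l: float, sd_k: float, rho: float,
                  m_l: int, m_k: int) -> np.ndarray:
    """Cell masses at half-step offsets -m..m per axis, shape (2m_l+1, 2m_k+1)."""
    if sd_l == 0.0 or sd_k == 0.0 or rho == 0.0:
        return np.outer(_axis_kernel_1d(grid.n_l, grid.h_l, sd_l, m_l),
                        _axis_kernel_1d(grid.n_k, grid.h_k, sd_k, m_k))
    eo_l = np.arange(-(m_l + 1), m_l + 2) * (grid.h_l / 2.0) / sd_l
    eo_k = np.arange(-(m_k + 1), m_k + 2) * (grid.h_k / 2.0) / sd_k
    corners = bvn_cdf(eo_l[:, None], eo_k[None, :], rho)
    return (corners[2:, 2:] - corners[:-2, 2:]
            - corners[2:, :-2] + corners[:-2, :-2])


def _variance_bins(n: int, h: float, sigma_add: float, c_v: float,
                   merge_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Map absolute cell separation a=0..n-1 to a merged kernel SD.

    Returns (bin index per separation, representative SD per bin).  With
    ``merge_tol=0`` every distinct separation keeps its exact SD.
    """
    seps = np.arange(n)
    sds = np.sqrt(sigma_add**2 + c_v * (seps * h) ** 2 / 2.0)  # non-decreasing
    bin_idx = np.empty(n, dtype=int)
    reps: list[float] = []
    start = 0
    for a in range(1, n + 1):
        if a < n:
            mergeable = (sds[start] == 0.0 and sds[a] == 0.0) or (
                merge_tol > 0 and sds[start] > 0
                and sds[a] <= sds[start] * (1 + merge_tol))
            if mergeable:
                continue
        rep = 0.0 if sds[start] == 0.0 else float(np.sqrt(sds[start] * sds[a - 1]))
        bin_idx[start:a] = len(reps)
        reps.append(rep)
        start = a
    return bin_idx, np.array(reps)


def larvae_distribution(
    parents: TraitDistribution,
    params: ReproductionParams,
    grid: TraitGrid | None = None,
    eps_pair: float = 1e-8,
    merge_tol: float = 0.05,
) -> TraitDistribution:
    """Larvae trait distribution: the pair-kernel mixture over all parent pairs.

    Ordered parent pairs are weighted ``P(t1) P(t2)``; each pair's bivariate
    normal kernel is discretised over the grid cells via the CDF, truncated to
    the grid and renormalised to its in-grid mass.  Pairs with joint weight
    below ``eps_pair`` are pruned (total-variation error at most
    ``eps_pair * G``); kernel widths within a relative tolerance
    ``merge_tol`` share one discretised kernel.  ``eps_pair=0, merge_tol=0``
    reproduces the exact double sum.
    """
    grid = grid or parents.grid
    P = parents.mass
    n_l, n_k = grid.shape
    exact = (eps_pair == 0.0 and merge_tol == 0.0)
    # kernel groups whose cumulative weight is below this fraction are dropped
    # (bounded total-variation error; zero in exact mode)
    group_drop_tol = 0.0 if exact else 1e-6

    bin_l, sd_l_reps = _variance_bins(n_l, grid.h_l, params.sigma_l_inf,
                                      params.c_v, merge_tol)
    bin_k, sd_k_reps = _variance_bins(n_k, grid.h_k, params.sigma_k,
                                      params.c_v, merge_tol)

    # accumulate pair weights onto the half-step midpoint lattice, per kernel bin
    w_mid: dict[tuple[int, int], np.ndarray] = {}
    kept_weight = 0.0
    occ_l = np.flatnonzero(P.sum(axis=1) > 0)
    if occ_l.size == 0:
        raise ReproductionFailure("parent distribution has no mass")
    dl_range = range(-(int(occ_l.max() - occ_l.min())), int(occ_l.max() - occ_l.min()) + 1)
    occ_k = np.flatnonzero(P.sum(axis=0) > 0)
    dk_range = range(-(int(occ_k.max() - occ_k.min())), int(occ_k.max() - occ_k.min()) + 1)
    for dl in dl_range:
        l1_lo, l1_hi = max(0, dl), n_l + min(0, dl)   # t1 rows with valid t2=t1-dl
        if l1_lo >= l1_hi:
            continue
        P1l = P[l1_lo:l1_hi]
        P2l = P[l1_lo - dl:l1_hi - dl]
        for dk in dk_range:
            k1_lo, k1_hi = max(0, dk), n_k + min(0, dk)
            if k1_lo >= k1_hi:
                continue
            A = P1l[:, k1_lo:k1_hi] * P2l[:, k1_lo - dk:k1_hi - dk]
            if eps_pair > 0:
                A = np.where(A >= eps_pair, A, 0.0)
            s = A.sum()
            if s == 0.0:
                continue
            kept_weight += s
            key = (bin_l[abs(dl)], bin_k[abs(dk)])
            W = w_mid.get(key)
            if W is None:
                W = np.zeros((2 * n_l - 1, 2 * n_k - 1))
                w_mid[key] = W
            # midpoint doubled-index j = 2*t1 - d
            W[2 * l1_lo - dl:2 * l1_hi - dl:2,
              2 * k1_lo - dk:2 * k1_hi - dk:2] += A
    if not w_mid:
        raise ReproductionFailure("pair pruning removed all parent pairs")

    if group_drop_tol > 0 and len(w_mid) > 1:
        sums = {key: W.sum() for key, W in w_mid.items()}
        budget = group_drop_tol * kept_weight
        for key in sorted(sums, key=sums.get):
            if sums[key] > budget:
                break
            budget -= sums[key]
            del w_mid[key]

    # Each pair kernel is renormalised to its in-grid (discretised) mass.  In
    # the exact path that mass, per midpoint, is the cross-correlation of the
    # kernel with the cell-centre pattern (so conservation is exact by
    # construction); the fast path uses the separable per-axis form, which
    # differs only through the correlation coupling at grid corners.
    ones_l = np.zeros(2 * n_l - 1)
    ones_l[::2] = 1.0
    ones_k = np.zeros(2 * n_k - 1)
    ones_k[::2] = 1.0

    direct = exact or grid.n_cells <= 256
    out = np.zeros((n_l, n_k))
    for (bl, bk), W in w_mid.items():
        sd_l, sd_k = sd_l_reps[bl], sd_k_reps[bk]
        m_l = _axis_window(n_l, grid.h_l, sd_l, windowed=not exact)
        m_k = _axis_window(n_k, grid.h_k, sd_k, windowed=not exact)
        K = _joint_kernel(grid, sd_l, sd_k, params.rho, m_l, m_k)
        if direct:
            tconv = _convolve(np.outer(ones_l, ones_k), K[::-1, ::-1],
                              mode="full", method="direct")
            totals = tconv[m_l:m_l + 2 * n_l - 1, m_k:m_k + 2 * n_k - 1]
        else:
            t_l = np.convolve(ones_l, K.sum(axis=1)[::-1])[m_l:m_l + 2 * n_l - 1]
            t_k = np.convolve(ones_k, K.sum(axis=0)[::-1])[m_k:m_k + 2 * n_k - 1]
            totals = np.outer(t_l, t_k)
        wt = W / totals
        conv = _convolve(wt, K, mode="full",
                         method="direct" if direct else "auto")
        out += conv[m_l::2, m_k::2][:n_l, :n_k]
    out = np.maximum(out, 0.0)
    out /= out.sum()
    return TraitDistribution(grid, out)


def spawn(
    pools: np.ndarray,
    params: ReproductionParams,
    grid: TraitGrid,
    eps_pair: float = 1e-8,
    merge_tol: float = 0.05,
) -> np.ndarray:
    """Larvae biomass per grid cell from the reproductive pools.

    Total larvae biomass is ``u`` times the summed pools, distributed across
    cells by the larvae trait distribution.  Returns an ``(n_l, n_k)`` array;
    all-zero if there is nothing to spawn from.  Callers clear the pools.
    """
    pools = np.asarray(pools, dtype=float)
    total = pools.sum()
    if total <= 0:
        return np.zeros(grid.shape)
    parents = parent_distribution(pools, grid)
    dist = larvae_distribution(parents, params, grid, eps_pair, merge_tol)
    return params.u * total * dist.mass


def age_guilds(biomass: np.ndarray, larvae: np.ndarray) -> np.ndarray:
    """Advance age guilds by one year, cell by cell.

    ``biomass`` has shape ``(n_ages, ...)`` (age 0 first; the last guild is
    the plus group).  Each guild inherits the previous guild's biomass; the
    plus group accumulates; larvae enter age 0.  Total biomass excluding the
    new larvae is conserved exactly.
    """
    biomass = np.asarray(biomass, dtype=float)
    n_ages = biomass.shape[0]
    new = np.empty_like(biomass)
    new[0] = larvae
    if n_ages > 1:
        new[1:n_ages - 1] = biomass[0:n_ages - 2]
        new[n_ages - 1] = biomass[n_ages - 1] + biomass[n_ages - 2]
    return new


def genotype_phenotype_variances(
    parents: TraitDistribution,
    params: ReproductionParams,
    grid: TraitGrid | None = None,
    eps_pair: float = 1e-8,
    merge_tol: float = 0.05,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Genotypic and phenotypic marginal variances of the larvae distribution.

    ``V_P`` uses the full kernel; ``V_G`` the kernel with the additive
    phenotypic component set to zero.  Returns ``((VG_l, VG_k), (VP_l, VP_k))``.
    """
    grid = grid or parents.grid
    d_p = larvae_distribution(parents, params, grid, eps_pair, merge_tol)
    d_g = larvae_distribution(parents, params.without_phenotypic(), grid,
                              eps_pair, merge_tol)
    return d_g.marginal_variances(), d_p.marginal_variances()


def heritability(v_g, v_p) -> float | np.ndarray:
    """H = V_G / V_P (may exceed 1 near grid borders)."""
    v_g = np.asarray(v_g, dtype=float)
    v_p = np.asarray(v_p, dtype=float)
    if np.any(v_p <= 0):
        raise ValueError("phenotypic variance must be > 0 for heritability")
    out = v_g / v_p
    return out if out.ndim else float(out)


def initial_trait_distribution(
    grid: TraitGrid,
    center: tuple[float, float] | None = None,
    sd_frac: float = 0.15,
    rho: float = 0.0,
) -> TraitDistribution:
    """Truncated bivariate normal start distribution.

    Centred at the grid centre by default, with marginal SDs ``sd_frac`` of
    each axis span, discretised over the cells and renormalised.
    """
    center = center or grid.center
    sd = (sd_frac * (grid.l_inf_bounds[1] - grid.l_inf_bounds[0]),
          sd_frac * (grid.k_bounds[1] - grid.k_bounds[0]))
    mass = rectangle_masses(grid.l_edges, grid.k_edges, center, sd, rho)
    total = mass.sum()
    if total <= 0:
        raise ValueError("initial distribution has no in-grid mass")
    return TraitDistribution(grid, np.maximum(mass, 0.0) / np.maximum(mass, 0.0).sum())
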