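"""Maximum-likelihood fitting and the continuity likelihood-ratio test.

The data log-likelihood is the sum over sites of

    log sum_k W_k(eps) p_{2m,k}(t1, t2; x)

(see :mod:`continuitest.reads` and :mod:`continuitest.moments`).  The
full model frees (t1, t2, eps); the null model of continuity pins
t2 = 0.  Because the null places t2 on the boundary of its parameter
space, the likelihood-ratio statistic is compared both to chi-square(1)
and to the 50:50 mixture of a point mass at 0 and chi-square(1); the
mixture p-value is the recommended decision value.

Optimization runs a deterministic multi-start bounded Nelder-Mead
(robust to the flat ridge at t2 = 0) and polishes the incumbent with
L-BFGS-B.  Sites are grouped by their number of covered individuals so
each distinct moment order costs one pair of matrix exponentials per
likelihood evaluation; individuals with zero reads at a site are dropped,
which is exact (an uncovered individual multiplies the site likelihood
by 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .moments import DriftParams, ExpmCache, NumericalError
from .reads import scaled_weights_t, weight_parts_t

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "FitOptions",
    "FitResult",
    "ContinuityTest",
    "BootstrapResult",
    "OptimizationError",
    "data_log_likelihood",
    "fit_full",
    "fit_null",
    "lrt_continuity",
    "bootstrap_ci",
]


class OptimizationError(RuntimeError):
    """No optimizer start converged to a finite optimum."""


@dataclass
class _Group:
    """Sites sharing the same number m of covered individuals.

    Arrays are count-major (individuals/moment-order first, sites second)
    so the per-individual rows the weight convolution touches are
    contiguous.
    """

    m: int
    site_idx: np.ndarray  # (Lg,) indices into the dataset
    AT: np.ndarray  # (m, Lg) ancestral counts of the covered individuals
    DT: np.ndarray  # (m, Lg) derived counts
    ind_idx: np.ndarray  # (Lg, m) column index of each covered individual
    HT: np.ndarray  # (2m + 1, Lg) seed vectors h_{2m}(x)
    parts: tuple  # precomputed count-only pieces of the weight computation

    @property
    def order(self) -> int:
        return 2 * self.m


class Dataset:
    """Per-site modern frequencies and per-individual read counts.

    Parameters
    ----------
    x : array (L,)
        Modern derived-allele frequency per site, strictly inside (0, 1).
    a, d : int arrays (L, M)
        Ancestral / derived read counts per site and individual.
    individuals : sequence of str, optional
        Individual identifiers (defaults to ind0..ind{M-1}).
    """

    def __init__(self, x, a, d, individuals=None):
        self.x = np.asarray(x, dtype=float)
        self.a = np.asarray(a)
        self.d = np.asarray(d)
        if self.a.shape != self.d.shape or self.a.ndim != 2:
            raise ValueError("a and d must be equal-shape (L, M) arrays")
        if self.x.shape != (self.a.shape[0],):
            raise ValueError("x must have one entry per site")
        if np.any(self.a < 0) or np.any(self.d < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(self.x <= 0.0) or np.any(self.x >= 1.0):
            raise ValueError("modern frequencies must be strictly inside (0, 1)")
        total = self.a + self.d
        if self.n_sites and np.any(total.sum(axis=1) == 0):
            raise ValueError("every site must carry at least one read")
        if individuals is None:
            individuals = [f"ind{i}" for i in range(self.a.shape[1])]
        if len(individuals) != self.a.shape[1]:
            raise ValueError("individuals must match the number of read-count columns")
        self.individuals = list(individuals)
        self._groups: list[_Group] | None = None

    @property
    def n_sites(self) -> int:
        return self.a.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.a.shape[1]

    def subset(self, site_idx) -> "Dataset":
        """New dataset restricted to (possibly repeated) site indices."""
        site_idx = np.asarray(site_idx)
        return Dataset(
            self.x[site_idx], self.a[site_idx], self.d[site_idx], self.individuals
        )

    def groups(self) -> list[_Group]:
        """Sites grouped by covered-individual count; computed lazily once."""
        if self._groups is None:
            covered = (self.a + self.d) > 0
            m_per_site = covered.sum(axis=1)
            groups = []
            for m in np.unique(m_per_site):
                m = int(m)
                rows = np.nonzero(m_per_site == m)[0]
                # stable argsort of ~covered puts the m covered columns first,
                # preserving individual order within each site
                cols = np.argsort(~covered[rows], axis=1, kind="stable")[:, :m]
                rr = rows[:, None]
                n = 2 * m
                xg = self.x[rows]
                k = np.arange(n + 1)[:, None]
                HT = xg[None, :] ** k * (1.0 - xg[None, :]) ** (n - k)
                AT = np.ascontiguousarray(self.a[rr, cols].T.astype(float))
                DT = np.ascontiguousarray(self.d[rr, cols].T.astype(float))
                groups.append(
                    _Group(
                        m=m,
                        site_idx=rows,
                        AT=AT,
                        DT=DT,
                        ind_idx=cols,
                        HT=HT,
                        parts=weight_parts_t(AT, DT),
                    )
                )
            self._groups = groups
        return self._groups


def _eps_matrix(group: _Group, eps) -> np.ndarray | float:
    eps_arr = np.asarray(eps, dtype=float)
    if eps_arr.ndim == 0:
        return float(eps_arr)
    return np.ascontiguousarray(eps_arr[group.ind_idx].T)


def data_log_likelihood(
    data: Dataset,
    params: DriftParams,
    eps,
    cache: ExpmCache | None = None,
) -> float:
    """Total log-likelihood of the dataset at (t1, t2, eps).

    ``eps`` is a shared scalar or a per-individual vector aligned with
    ``data.individuals``.  Sites whose weighted sum vanishes are excluded
    with a logged warning (they carry a likelihood of exactly zero under
    the model, which indicates a data problem rather than a parameter
    choice).
    """
    if cache is None:
        cache = ExpmCache()
    lnl = 0.0
    n_dropped = 0
    for group in data.groups():
        WT, log_scale = scaled_weights_t(
            group.AT, group.DT, _eps_matrix(group, eps), parts=group.parts
        )
        op = cache.operator(group.order, params)
        PT = op @ group.HT
        np.clip(PT, 0.0, None, out=PT)
        s = np.einsum("kl,kl->l", WT, PT)
        good = s > 0.0
        if not np.all(good):
            n_dropped += int((~good).sum())
        lnl += float(np.log(s[good]).sum() + log_scale[good].sum())
    if n_dropped:
        logger.warning("%d sites had zero likelihood and were excluded", n_dropped)
    return lnl


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration.

    The default start grid is deterministic: log-spaced drift times
    {0.005, 0.05, 0.5} for each free t and error starts {0.001, 0.01}
    (3 x 3 x 2 = 18 starts for the full model).  ``fix_eps`` pins the
    error rate; ``per_individual_eps`` frees one error rate per
    individual (shared is the default: with low coverage a single pooled
    rate is the lower-variance choice).
    """

    t1_starts: tuple = (0.005, 0.05, 0.5)
    t2_starts: tuple = (0.005, 0.05, 0.5)
    eps_starts: tuple = (0.001, 0.01)
    t_bounds: tuple = (0.0, 10.0)
    eps_bounds: tuple = (1e-6, 0.5 - 1e-6)
    fix_eps: float | None = None
    per_individual_eps: bool = False
    nm_maxiter: int = 250
    nm_fatol: float = 1e-3  # coarse per-start exploration
    nm_xatol: float = 1e-4
    lnl_tol: float = 1e-6  # final convergence tolerance of the polish stage
    agree_tol: float = 1e-4


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimates for one model fit."""

    t1: float
    t2: float
    eps: float | np.ndarray
    lnl: float
    converged: bool
    n_starts_agreeing: int
    null_model: bool = False

    @property
    def params(self) -> DriftParams:
        return DriftParams(self.t1, self.t2)


def _make_objective(data: Dataset, options: FitOptions, free_t2: bool):
    """Map a free-parameter vector to -lnL; returns (objective, unpack)."""
    n_ind = data.n_individuals

    def unpack(theta):
        t1 = theta[0]
        pos = 1
        if free_t2:
            t2 = theta[1]
            pos = 2
        else:
            t2 = 0.0
        if options.fix_eps is not None:
            eps = options.fix_eps
        elif options.per_individual_eps:
            eps = np.asarray(theta[pos : pos + n_ind])
        else:
            eps = theta[pos]
        return t1, t2, eps

    cache = ExpmCache()

    def objective(theta):
        t1, t2, eps = unpack(theta)
        try:
            lnl = data_log_likelihood(data, DriftParams(t1, t2), eps, cache=cache)
        except NumericalError:
            return np.inf
        return -lnl if np.isfinite(lnl) else np.inf

    return objective, unpack


def _start_points(options: FitOptions, free_t2: bool, n_ind: int):
    t1s = options.t1_starts
    t2s = options.t2_starts if free_t2 else (None,)
    if options.fix_eps is not None:
        epss = (None,)
    else:
        epss = options.eps_starts
    starts = []
    for t1 in t1s:
        for t2 in t2s:
            for eps in epss:
                theta = [t1]
                if free_t2:
                    theta.append(t2)
                if eps is not None:
                    theta.extend([eps] * (n_ind if options.per_individual_eps else 1))
                starts.append(np.array(theta, dtype=float))
    return starts


def _fit(data: Dataset, options: FitOptions, free_t2: bool) -> FitResult:
    n_ind = data.n_individuals
    objective, unpack = _make_objective(data, options, free_t2)
    bounds = [options.t_bounds]
    if free_t2:
        bounds.append(options.t_bounds)
    if options.fix_eps is None:
        n_eps = n_ind if options.per_individual_eps else 1
        bounds.extend([options.eps_bounds] * n_eps)

    candidates = []
    for theta0 in _start_points(options, free_t2, n_ind):
        res = optimize.minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": options.nm_maxiter,
                "fatol": options.nm_fatol,
                "xatol": options.nm_xatol,
            },
        )
        if np.isfinite(res.fun):
            candidates.append(res)
    if not candidates:
        raise OptimizationError("all optimizer starts failed to reach a finite optimum")

    best_fun = min(c.fun for c in candidates)
    agreeing = [c for c in candidates if c.fun <= best_fun + options.agree_tol]
    # parsimony tie-break among agreeing starts: smallest total drift, then eps
    incumbent = min(agreeing, key=lambda c: (sum(unpack(c.x)[:2]), np.mean(unpack(c.x)[2])))
    # relative ftol scaled so the absolute lnL tolerance is options.lnl_tol
    ftol = options.lnl_tol / max(abs(best_fun), 1.0)
    polish = optimize.minimize(
        objective, incumbent.x, method="L-BFGS-B", bounds=bounds,
        options={"ftol": ftol, "eps": 1e-7},
    )
    final = polish if polish.fun <= incumbent.fun else incumbent
    t1, t2, eps = unpack(final.x)
    converged = bool(final.success or incumbent.success)
    return FitResult(
        t1=float(t1),
        t2=float(t2),
        eps=eps if isinstance(eps, np.ndarray) else float(eps),
        lnl=float(-final.fun),
        converged=converged,
        n_starts_agreeing=len(agreeing),
        null_model=not free_t2,
    )


def fit_full(data: Dataset, options: FitOptions | None = None) -> FitResult:
    """Maximize the likelihood over (t1, t2) and (unless fixed) eps."""
    options = options or FitOptions()
    if data.n_sites < 100:
        logger.warning(
            "only %d usable sites; estimates will be noisy (>= 100 recommended)",
            data.n_sites,
        )
    return _fit(data, options, free_t2=True)


def fit_null(data: Dataset, options: FitOptions | None = None) -> FitResult:
    """Maximize the likelihood under continuity (t2 pinned to 0)."""
    options = options or FitOptions()
    return _fit(data, options, free_t2=False)


@dataclass(frozen=True)
class ContinuityTest:
    """Likelihood-ratio test of the continuity null (t2 = 0).

    ``p_mixture`` uses the 50:50 mixture of a point mass at zero and
    chi-square(1) appropriate for a null on the parameter boundary and is
    the recommended decision value; ``p_chi2_1df`` is the conventional
    chi-square(1) p-value, which is conservative here.
    """

    full: FitResult
    null: FitResult
    lrt: float
    p_chi2_1df: float
    p_mixture: float

    @property
    def lnl_full(self) -> float:
        return self.full.lnl

    @property
    def lnl_null(self) -> float:
        return self.null.lnl


def lrt_continuity(data: Dataset, options: FitOptions | None = None) -> ContinuityTest:
    """Fit full and null models and form the boundary-corrected LRT."""
    options = options or FitOptions()
    full = fit_full(data, options)
    null = fit_null(data, options)
    lrt = 2.0 * (full.lnl - null.lnl)
    if lrt < -1e-6:
        logger.warning(
            "null likelihood exceeded full by %.3g; treating LRT as 0", -lrt
        )
    lrt = max(lrt, 0.0)
    p_chi2 = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    p_mix = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return ContinuityTest(
        full=full, null=null, lrt=lrt, p_chi2_1df=p_chi2, p_mixture=p_mix
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Nonparametric bootstrap of the full-model MLEs.

    ``samples`` has one row per successful replicate with columns
    (t1, t2, eps); ``intervals`` maps parameter name to the 2.5/97.5
    percentile interval.
    """

    samples: np.ndarray
    intervals: dict
    n_failed: int


def bootstrap_ci(
    data: Dataset,
    B: int,
    seed: int,
    options: FitOptions | None = None,
    block_size: int = 1,
) -> BootstrapResult:
    """Percentile bootstrap intervals for (t1, t2, eps).

    Sites are resampled with replacement (the model treats sites as
    independent); ``block_size`` > 1 resamples blocks of consecutive
    sites instead, for data with residual linkage.  Each replicate refit
    starts from the full-data MLE (plus the default grid's nearest
    neighbors collapses to a single deterministic start), which is the
    standard warm-start for bootstrap refits.  Replicates that fail are
    dropped; more than 10% failures is an error.
    """
    options = options or FitOptions()
    if B < 100:
        logger.warning("B=%d bootstrap replicates; >= 100 recommended", B)
    mle = fit_full(data, options)
    eps_start = float(np.mean(mle.eps))
    warm = replace(
        options,
        t1_starts=(max(mle.t1, 1e-4),),
        t2_starts=(max(mle.t2, 1e-4),),
        eps_starts=(min(max(eps_start, options.eps_bounds[0]), options.eps_bounds[1]),),
    )
    rng = np.random.default_rng(seed)
    L = data.n_sites
    rows = []
    n_failed = 0
    for _ in range(B):
        if block_size <= 1:
            idx = rng.integers(0, L, size=L)
        else:
            n_blocks = int(np.ceil(L / block_size))
            starts = rng.integers(0, max(L - block_size, 1), size=n_blocks)
            idx = (starts[:, None] + np.arange(block_size)[None, :]).ravel()[:L]
        try:
            boot = data.subset(idx)
            fit = fit_full(boot, warm)
            rows.append([fit.t1, fit.t2, float(np.mean(fit.eps))])
        except (OptimizationError, NumericalError, ValueError):
            n_failed += 1
    if n_failed > 0.1 * B:
        raise OptimizationError(
            f"{n_failed}/{B} bootstrap replicates failed to fit"
        )
    samples = np.asarray(rows)
    names = ("t1", "t2", "eps")
    intervals = {
        name: tuple(np.percentile(samples[:, j], [2.5, 97.5]))
        for j, name in enumerate(names)
    }
    return BootstrapResult(samples=samples, intervals=intervals, n_failed=n_failed)
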