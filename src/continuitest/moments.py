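"""Binomial moments of the ancient allele-frequency distribution.

Under a clean split model — a modern population of size ``Ne1`` and an
ancient population of size ``Ne2`` separated ``tau1`` (respectively
``tau2``) generations from their common ancestor — the probability of
drawing ``k`` derived alleles in a sample of ``n`` ancient chromosomes,
conditional on the modern derived frequency ``x``, is determined by the
binomial moments

    p_{n,k} = E[ Y^k (1 - Y)^{n-k} | X = x ]

of the (unobserved) ancient frequency ``Y``.  Measuring time in diffusion
units ``t_i = tau_i / (2 Ne_i)``, the moment vector is obtained by two
matrix exponentials applied to a seed vector in ``x``:

    p(t1, t2) = exp(Q t2) exp(Qd t1) h_n(x)

where ``Q`` evolves moments forward in time along the ancient branch
(pure-drift Wright-Fisher diffusion) and ``Qd`` evolves them backward in
time from the modern population to the common ancestor.  Both are sparse
tridiagonal matrices of order ``n + 1``; ``h_n(x)_k = x^k (1-x)^{n-k}``.

Indexing convention: entry ``k`` of every vector corresponds to the
derived-allele count ``k`` (so ``h_n[0] = (1-x)^n`` and ``h_n[n] = x^n``).
For ``m`` diploid individuals, ``n = 2 m`` chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import comb


class NumericalError(RuntimeError):
    """A matrix exponential or downstream computation lost validity."""


@dataclass(frozen=True)
class DriftParams:
    """Diffusion-scaled drift times of the two branches.

    Attributes
    ----------
    t1 : float
        Drift time on the modern branch, ``tau1 / (2 Ne1)``.
    t2 : float
        Drift time on the ancient branch, ``tau2 / (2 Ne2)``.  ``t2 = 0``
        is the continuity hypothesis: the ancient sample sits directly on
        the modern lineage.
    """

    t1: float
    t2: float

    def __post_init__(self) -> None:
        for name in ("t1", "t2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def _check_order(n) -> int:
    if not float(n).is_integer() or n < 1:
        raise ValueError(f"chromosome count n must be an integer >= 1, got {n!r}")
    return int(n)


def build_forward_generator(n: int) -> np.ndarray:
    """Tridiagonal generator Q of the forward (drift) moment evolution.

    Row ``i`` has sub-diagonal ``i(i-1)/2``, diagonal ``-i(n-i)`` and
    super-diagonal ``(n-i)(n-i-1)/2``.  These are the coefficients picked
    up when the Wright-Fisher diffusion generator acts on the monomial
    ``y^i (1-y)^{n-i}``.
    """
    n = _check_order(n)
    i = np.arange(n + 1, dtype=float)
    lower = i * (i - 1) / 2.0
    diag = -i * (n - i)
    upper = (n - i) * (n - i - 1) / 2.0
    Q = np.diag(diag)
    Q[np.arange(1, n + 1), np.arange(n)] = lower[1:]
    Q[np.arange(n), np.arange(1, n + 1)] = upper[:-1]
    return Q


def build_backward_generator(n: int) -> np.ndarray:
    """Tridiagonal generator Qd of the backward moment evolution.

    Row ``i`` has sub-diagonal ``i(i-1)/2``, diagonal ``-i(n-i+1)`` and
    super-diagonal ``(n-i+1)(n-i)/2``.  Applied for time ``t1`` it carries
    the moment vector from the modern population back to the common
    ancestor; probabilistically it is the moment transform of the
    posterior on the ancestral frequency under a neutral (density
    proportional to ``1/z``) prior on the ancestral derived frequency.
    """
    n = _check_order(n)
    i = np.arange(n + 1, dtype=float)
    lower = i * (i - 1) / 2.0
    diag = -i * (n - i + 1)
    upper = (n - i + 1) * (n - i) / 2.0
    Q = np.diag(diag)
    Q[np.arange(1, n + 1), np.arange(n)] = lower[1:]
    Q[np.arange(n), np.arange(1, n + 1)] = upper[:-1]
    return Q


def seed_moment_vector(n: int, x: float) -> np.ndarray:
    """Seed vector ``h_n(x)``, entry ``k`` equal to ``x^k (1-x)^{n-k}``."""
    n = _check_order(n)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"modern frequency x must lie in [0, 1], got {x!r}")
    k = np.arange(n + 1)
    return x**k * (1.0 - x) ** (n - k)


def _finalize_moments(p: np.ndarray, n: int) -> np.ndarray:
    """Clamp round-off negatives and renormalize; reject broken results."""
    if not np.all(np.isfinite(p)):
        raise NumericalError(f"non-finite moment vector at order n={n}: {p!r}")
    p = np.clip(p, 0.0, 1.0)
    total = float(comb(n, np.arange(n + 1)) @ p)
    if abs(total - 1.0) > 1e-6:
        raise NumericalError(
            f"moment normalization broken at order n={n}: sum C(n,k) p_k = {total!r}"
        )
    return p / total


class ExpmCache:
    """Cache of the combined operator ``exp(Q t2) exp(Qd t1)`` per order.

    The operator depends only on ``(t1, t2, n)``; a dataset of many sites
    sharing a handful of distinct per-site orders re-uses each exponential.
    The cache is invalidated whenever the drift parameters change, so the
    cached and uncached paths are bit-identical.
    """

    def __init__(self) -> None:
        self._params: DriftParams | None = None
        self._ops: dict[int, np.ndarray] = {}
        self.hits = 0
        self.misses = 0

    def operator(self, n: int, params: DriftParams) -> np.ndarray:
        n = _check_order(n)
        if params != self._params:
            self._params = params
            self._ops = {}
        op = self._ops.get(n)
        if op is None:
            self.misses += 1
            fwd = expm(build_forward_generator(n) * params.t2)
            bwd = expm(build_backward_generator(n) * params.t1)
            op = fwd @ bwd
            if not np.all(np.isfinite(op)):
                raise NumericalError(
                    f"matrix exponential produced non-finite entries "
                    f"(n={n}, t1={params.t1}, t2={params.t2})"
                )
            self._ops[n] = op
        else:
            self.hits += 1
        return op

    def prepare(self, params: DriftParams, orders) -> None:
        for n in orders:
            self.operator(n, params)


def binomial_moments(
    n: int, x: float, params: DriftParams, cache: ExpmCache | None = None
) -> np.ndarray:
    """Moment vector ``p_{n,k}(t1, t2)`` for ``k = 0..n`` at modern frequency x.

    Entries are clamped to ``[0, 1]``; the binomial-weighted sum
    ``sum_k C(n,k) p_k`` is checked against 1 (tolerance 1e-6, then
    renormalized) and a :class:`NumericalError` is raised if the
    exponentiation produced an invalid vector.
    """
    h = seed_moment_vector(n, x)
    if cache is None:
        cache = ExpmCache()
    op = cache.operator(n, params)
    return _finalize_moments(op @ h, n)


def sampling_probabilities(
    n: int, x: float, params: DriftParams, cache: ExpmCache | None = None
) -> np.ndarray:
    """Probability ``P_{n,k} = C(n,k) p_{n,k}`` of k derived alleles in n draws."""
    p = binomial_moments(n, x, params, cache=cache)
    return comb(n, np.arange(n + 1)) * p
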