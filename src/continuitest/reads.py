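"""Genotype likelihoods from read counts and per-site allele-count weights.

Each ancient diploid contributes read counts ``(a, d)`` (ancestral,
derived) at a site.  Under the symmetric error model a read from a
truly-derived chromosome is observed ancestral with probability ``eps``
and vice versa, so the read likelihood given genotype ``g`` in {0, 1, 2}
is binomial with derived-read probability ``p_0 = eps``, ``p_1 = 1/2``,
``p_2 = 1 - eps``.

A panel of ``m`` diploids is collapsed into weights

    W_k = sum over genotype vectors g with sum(g) = k of
          prod_i C(2, g_i) P(R_i | g_i),        k = 0..2m,

so the site likelihood is ``sum_k W_k p_{2m,k}``.  No extra C(2m, k)
factor appears: by the Vandermonde identity the C(2, g_i) products summed
over configurations with sum k already total C(2m, k), which is exactly
the binomial coefficient the sampling probability P_{2m,k} requires, and
the moments p_{2m,k} are stored without it.

W is computed by sequential convolution of the per-individual triplets
(P(R|0), 2 P(R|1), P(R|2)) — O(m^2) instead of 3^m enumeration — with the
per-individual maximum factored out so that high-coverage sites do not
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CountWeights",
    "genotype_read_likelihood",
    "site_count_weights",
    "site_log_likelihood",
]


@dataclass(frozen=True)
class CountWeights:
    """Allele-count weights for one site.

    ``values[k] * exp(log_scale)`` is the weight W_k for k derived alleles
    among the 2m chromosomes of the m contributing diploids.  ``values``
    carries the scaled weights (max-factored per individual, safe at high
    coverage); ``log_scale`` restores the absolute scale.
    """

    values: np.ndarray
    log_scale: float = 0.0

    @property
    def m(self) -> int:
        return (len(self.values) - 1) // 2

    def plain(self) -> np.ndarray:
        """Unscaled W_k; may underflow for extremely deep sites."""
        return self.values * np.exp(self.log_scale)


def _validate_counts(a: int, d: int) -> None:
    if a < 0 or d < 0 or not float(a).is_integer() or not float(d).is_integer():
        raise ValueError(f"read counts must be non-negative integers, got a={a!r}, d={d!r}")


def _validate_eps(eps: float) -> None:
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"error rate eps must lie in [0, 0.5), got {eps!r}")


def genotype_read_likelihood(a: int, d: int, g: int, eps: float) -> float:
    """P(reads | genotype): binomial(a + d, p_g) at d derived reads.

    p_0 = eps, p_1 = 1/2, p_2 = 1 - eps.  With no reads the likelihood is
    1 for every genotype (empty product).
    """
    _validate_counts(a, d)
    _validate_eps(eps)
    if g not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")
    p = (eps, 0.5, 1.0 - eps)[g]
    logc = gammaln(a + d + 1) - gammaln(a + 1) - gammaln(d + 1)
    # 0 * log(0) is an empty factor, not NaN
    with np.errstate(divide="ignore"):
        term_d = d * np.log(p) if d else 0.0
        term_a = a * np.log1p(-p) if a else 0.0
    return float(np.exp(logc + term_d + term_a))


def weight_parts_t(AT: np.ndarray, DT: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parameter-independent pieces of the triplet computation.

    Count-major layout: ``AT``/``DT`` have shape (m, L).  The binomial
    coefficient C(a+d, d) is shared by all three genotype likelihoods, so
    it cancels from the max-scaled triplet and only shifts the log scale;
    likewise the heterozygote term depends on the counts alone.  Both are
    precomputed once per dataset.

    Returns ``(s1, logc_site)``: the log of the weighted heterozygote
    term ``2 (1/2)^(a+d)`` per individual (shape (m, L)), and the summed
    log binomial coefficients per site (length L).
    """
    AT = np.asarray(AT, dtype=float)
    DT = np.asarray(DT, dtype=float)
    logc = gammaln(AT + DT + 1) - gammaln(AT + 1) - gammaln(DT + 1)
    s1 = (AT + DT) * np.log(0.5) + np.log(2.0)
    return s1, logc.sum(axis=0)


def scaled_weights_t(
    AT: np.ndarray, DT: np.ndarray, eps, parts=None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized W for a block of sites sharing the same individual count.

    Parameters
    ----------
    AT, DT : arrays of shape (m, L)
        Ancestral/derived read counts of the m covered individuals at each
        of L sites (count-major so per-individual rows are contiguous).
    eps : scalar or array broadcastable to (m, L)
        Per-read error rate(s).
    parts : optional
        Precomputed :func:`weight_parts_t` for these counts.

    Returns
    -------
    WT : array (2m + 1, L)
        Scaled weights, count-major.
    log_scale : array (L,)
        Per-site log scale factors; true W_k(l) = WT[k, l] * exp(log_scale[l]).
    """
    AT = np.asarray(AT, dtype=float)
    DT = np.asarray(DT, dtype=float)
    m, L = AT.shape
    s1, logc_site = weight_parts_t(AT, DT) if parts is None else parts
    with np.errstate(divide="ignore", invalid="ignore"):
        log_eps = np.log(eps)
        log_1me = np.log1p(-eps)
        s0 = np.where(DT > 0, DT * log_eps, 0.0) + AT * log_1me
        s2 = DT * log_1me + np.where(AT > 0, AT * log_eps, 0.0)
    peak = np.maximum(np.maximum(s0, s1), s2)
    t0 = np.exp(s0 - peak)
    t1 = np.exp(s1 - peak)
    t2 = np.exp(s2 - peak)
    # in-place polynomial product over individuals, highest degree first
    WT = np.zeros((2 * m + 1, L))
    WT[0] = 1.0
    for i in range(m):
        w0, w1, w2 = t0[i], t1[i], t2[i]
        hi = 2 * i
        for j in range(hi + 2, -1, -1):
            acc = WT[j] * w0 if j <= hi else 0.0
            if 1 <= j <= hi + 1:
                acc = acc + WT[j - 1] * w1
            if j >= 2:
                acc = acc + WT[j - 2] * w2
            WT[j] = acc
    return WT, peak.sum(axis=0) + logc_site


def scaled_weight_matrix(
    A: np.ndarray, D: np.ndarray, eps
) -> tuple[np.ndarray, np.ndarray]:
    """Site-major wrapper around :func:`scaled_weights_t`.

    ``A``/``D`` have shape (L, m); returns W of shape (L, 2m + 1) and the
    per-site log scale.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    eps_t = np.asarray(eps, dtype=float)
    if eps_t.ndim == 2:
        eps_t = np.ascontiguousarray(eps_t.T)
    WT, log_scale = scaled_weights_t(
        np.ascontiguousarray(A.T), np.ascontiguousarray(D.T), eps_t
    )
    return WT.T.copy(), log_scale


def site_count_weights(reads, eps) -> CountWeights:
    """Collapse one site's per-individual read counts into W_k.

    Parameters
    ----------
    reads : sequence of (a, d) pairs
        One pair per contributing diploid.
    eps : float or sequence of floats
        Shared error rate, or one per individual (lengths must match).
    """
    reads = list(reads)
    m = len(reads)
    if m < 1:
        raise ValueError("need at least one individual")
    A = np.array([[r[0] for r in reads]], dtype=float)
    D = np.array([[r[1] for r in reads]], dtype=float)
    for a, d in reads:
        _validate_counts(a, d)
    eps_arr = np.atleast_1d(np.asarray(eps, dtype=float))
    if eps_arr.ndim != 1 or eps_arr.size not in (1, m):
        raise ValueError(f"eps must be scalar or length {m}, got size {eps_arr.size}")
    for e in eps_arr:
        _validate_eps(float(e))
    W, log_scale = scaled_weight_matrix(A, D, eps_arr[None, :])
    return CountWeights(values=W[0], log_scale=float(log_scale[0]))


def site_log_likelihood(w: CountWeights, p: np.ndarray) -> float:
    """log sum_k W_k p_{2m,k} for one site.

    ``p`` is the binomial-moment vector of order 2m at this site's modern
    frequency.  Returns ``-inf`` when the weighted sum vanishes (the
    caller should flag and exclude such a site).
    """
    p = np.asarray(p, dtype=float)
    if len(w.values) != len(p):
        raise ValueError(
            f"order mismatch: weights of length {len(w.values)}, moments of length {len(p)}"
        )
    s = float(w.values @ p)
    if s <= 0.0:
        return float("-inf")
    return float(np.log(s) + w.log_scale)
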