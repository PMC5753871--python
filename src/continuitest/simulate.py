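"""Synthetic read-count datasets under the split-drift model.

Two generators are provided:

* ``model_exact`` — draws the per-site ancient derived-allele count
  directly from the sampling distribution P_{2m,k}(x) the likelihood
  integrates over, pairs chromosomes into diploids at random, and then
  simulates reads.  This is the distribution-exact sampler.
* ``wright_fisher`` — an independent discrete Wright-Fisher forward
  simulation: an ancestral frequency is drawn from the neutral
  derived-allele spectrum (density proportional to 1/z), evolved by
  binomial resampling down the modern branch (tau1 generations at size
  Ne1) and the ancient branch (tau2 generations at size Ne2), and
  conditioned on the modern population still segregating.  It also
  implements the admixture scenarios (secondary contact from the ancient
  lineage into the modern one, and gene flow from an unsampled "ghost"
  population), which have no closed-form counterpart.

Reads are Poisson in depth with mean the target coverage; each read is a
contaminant with probability ``c`` (in which case it carries the derived
allele with probability x, the modern frequency), otherwise it samples
one of its individual's two chromosomes; the observed allele is flipped
with probability ``eps``.  Sites are unlinked, matching the independence
assumption of the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .inference import Dataset
from .moments import DriftParams, ExpmCache

__all__ = [
    "DemographyConfig",
    "ReadSimConfig",
    "AdmixtureScenario",
    "drift_time",
    "sample_modern_frequencies",
    "sample_ancient_counts_model_exact",
    "wright_fisher_forward",
    "simulate_reads",
    "simulate_dataset",
]


def drift_time(tau: float, ne: float) -> float:
    """Convert a branch length in generations to diffusion units, tau / (2 Ne)."""
    if tau < 0 or ne <= 0:
        raise ValueError(f"need tau >= 0 and Ne > 0, got tau={tau!r}, Ne={ne!r}")
    return tau / (2.0 * ne)


@dataclass(frozen=True)
class DemographyConfig:
    """Split demography in natural units.

    The modern population (size ``ne1``) and the ancient-sample lineage
    (size ``ne2``) split ``tau1`` generations before the present;
    the ancient sample was taken ``tau1 - tau2`` generations ago, i.e.
    ``tau2`` generations after the split along the ancient branch.
    Defaults follow the standard benchmark design: split 400 generations
    ago, Ne1 = 10,000, Ne2 = 1,000, sample age 300 generations, giving
    t1 = 0.02 and t2 = 0.05.
    """

    ne1: float = 10_000.0
    ne2: float = 1_000.0
    tau1: float = 400.0
    tau2: float = 100.0

    def __post_init__(self) -> None:
        if self.ne1 <= 0 or self.ne2 <= 0 or self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("population sizes must be positive, branch lengths >= 0")

    @property
    def t1(self) -> float:
        return drift_time(self.tau1, self.ne1)

    @property
    def t2(self) -> float:
        return drift_time(self.tau2, self.ne2)

    @property
    def params(self) -> DriftParams:
        return DriftParams(self.t1, self.t2)


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing configuration: panel size, coverage, error, contamination."""

    m: int = 5
    coverage: float = 1.0
    eps: float = 0.01
    c: float = 0.0
    L: int = 20_000

    def __post_init__(self) -> None:
        if self.m < 1 or self.L < 1:
            raise ValueError("m and L must be >= 1")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("contamination fraction must lie in [0, 1]")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")


@dataclass(frozen=True)
class AdmixtureScenario:
    """Model violation to simulate (Wright-Fisher engine only).

    ``secondary_contact``: a pulse of fraction ``f`` from the ancient
    lineage into the modern population ``pulse_gens`` generations before
    the present (default 200, i.e. after the default sample's death).
    ``ghost``: the ancient sample is continuous with the modern lineage
    (t2 = 0) but an outgroup that split ``ghost_split_gens`` generations
    ago (default 800, 0.04 diffusion units at Ne 10,000) pulses fraction
    ``f`` into the modern population ``pulse_gens`` generations ago.
    """

    mode: str = "none"
    f: float = 0.0
    pulse_gens: float = 200.0
    ghost_split_gens: float = 800.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "secondary_contact", "ghost"):
            raise ValueError(f"unknown admixture mode {self.mode!r}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("admixture fraction must lie in [0, 1]")


def sample_modern_frequencies(
    L: int,
    spectrum: str = "neutral_1_over_x",
    rng: np.random.Generator | None = None,
    panel_size: int = 100,
) -> np.ndarray:
    """Draw modern derived-allele frequencies of segregating SNPs.

    ``spectrum`` is ``"uniform"`` or ``"neutral_1_over_x"`` (density
    proportional to 1/x, the standing neutral spectrum of derived
    alleles).  Frequencies are truncated to
    (1/(2 panel_size), 1 - 1/(2 panel_size)), emulating segregation in a
    finite modern panel of diploids.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    lo = 1.0 / (2.0 * panel_size)
    hi = 1.0 - lo
    u = rng.random(L)
    if spectrum == "uniform":
        return lo + u * (hi - lo)
    if spectrum == "neutral_1_over_x":
        return lo * (hi / lo) ** u
    raise ValueError(f"unknown spectrum {spectrum!r}")


def sample_ancient_counts_model_exact(
    x: np.ndarray,
    m: int,
    params: DriftParams,
    rng: np.random.Generator,
    cache: ExpmCache | None = None,
) -> np.ndarray:
    """Diploid genotypes for m individuals at each site, exactly from the model.

    For each site the derived count k among n = 2m chromosomes is drawn
    from P_{n,k}(x); the k derived alleles are then placed on the 2m
    chromosome slots uniformly at random and slots are paired into
    diploids.  Returns an int array of shape (L, m) with entries in
    {0, 1, 2}.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    L = x.size
    n = 2 * m
    cache = cache or ExpmCache()
    op = cache.operator(n, params)
    k_idx = np.arange(n + 1)
    H = x[:, None] ** k_idx * (1.0 - x[:, None]) ** (n - k_idx)
    P = (H @ op.T) * comb(n, k_idx)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random(L)
    k = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    # uniform placement of k derived alleles on 2m chromosome slots
    ranks = np.argsort(rng.random((L, n)), axis=1)
    chrom = (ranks < k[:, None]).astype(np.int64)
    return chrom[:, 0::2] + chrom[:, 1::2]


def wright_fisher_forward(
    z0, ne: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve frequencies by tau rounds of binomial(2 Ne) resampling."""
    z = np.atleast_1d(np.asarray(z0, dtype=float))
    if np.any((z < 0) | (z > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    n2 = int(round(2 * ne))
    for _ in range(int(round(tau))):
        z = rng.binomial(n2, z) / n2
    return z


def simulate_reads(
    genotypes: np.ndarray,
    cfg: ReadSimConfig,
    x: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequencing reads for given genotypes.

    Depth per individual per site is Poisson(coverage).  Each read is a
    contaminant with probability ``cfg.c`` (derived with probability the
    modern frequency x of the site), otherwise it samples one of the
    individual's chromosomes; the observed allele is flipped with
    probability ``cfg.eps``.  Returns (a, d) integer arrays of the
    genotype array's shape.
    """
    g = np.asarray(genotypes)
    x = np.broadcast_to(np.asarray(x, dtype=float)[:, None], g.shape)
    depth = rng.poisson(cfg.coverage, size=g.shape)
    n_cont = rng.binomial(depth, cfg.c)
    n_endo = depth - n_cont
    der_true = rng.binomial(n_cont, x) + rng.binomial(n_endo, g / 2.0)
    anc_true = depth - der_true
    d_obs = rng.binomial(der_true, 1.0 - cfg.eps) + rng.binomial(anc_true, cfg.eps)
    return depth - d_obs, d_obs


class _SitePool:
    """Segregating-site pool for the forward simulation.

    Tracks the derived frequency of every site in two lineages at once
    (``za``: the lineage the ancient sample is drawn from, or the ghost;
    ``zm``: the lineage leading to the modern population), injects new
    mutations each generation so the frequency spectrum stays at the
    neutral mutation-drift equilibrium (density proportional to 1/z, the
    distribution the likelihood's backward stage implicitly assumes), and
    compacts away sites lost from both lineages.
    """

    def __init__(self, zm, za):
        self.zm = np.asarray(zm, dtype=float)
        self.za = np.asarray(za, dtype=float)
        self.y: np.ndarray | None = None  # frozen record at sampling time

    def inject(self, n_new: int, freq: float, lineage: str) -> None:
        if n_new <= 0:
            return
        zeros = np.zeros(n_new)
        news = np.full(n_new, freq)
        self.zm = np.concatenate([self.zm, news if lineage == "m" else zeros])
        self.za = np.concatenate([self.za, news if lineage == "a" else zeros])
        if self.y is not None:  # sites born after sampling were absent then
            self.y = np.concatenate([self.y, np.zeros(n_new)])

    def drift(self, rng, ne_m: float | None, ne_a: float | None) -> None:
        if ne_m is not None:
            n2 = int(round(2 * ne_m))
            self.zm = rng.binomial(n2, self.zm) / n2
        if ne_a is not None:
            n2 = int(round(2 * ne_a))
            self.za = rng.binomial(n2, self.za) / n2

    def record_sample(self, lineage: str) -> None:
        self.y = (self.zm if lineage == "m" else self.za).copy()

    def pulse_into_modern(self, f: float, rng, ne_m: float) -> None:
        """One-generation binomial admixture pulse from the other lineage."""
        n2 = int(round(2 * ne_m))
        self.zm = rng.binomial(n2, (1.0 - f) * self.zm + f * self.za) / n2

    def compact(self) -> None:
        # a site lost (or fixed) everywhere can no longer produce data:
        # x would be non-segregating and, if sampled, y is retained only
        # for sites whose modern frequency survives
        lost = (self.zm == 0.0) & (self.za == 0.0)
        fixed = (self.zm == 1.0) & (self.za == 1.0)
        keep = ~(lost | fixed)
        self.zm = self.zm[keep]
        self.za = self.za[keep]
        if self.y is not None:
            self.y = self.y[keep]


_EULER_GAMMA = 0.57721566490153286


def _standing_sites(n_target: float, ne: float, rng) -> np.ndarray:
    """Stationary standing variation: frequencies with density ~ 1/z."""
    lo = 1.0 / (2.0 * ne)
    k = rng.poisson(n_target)
    return lo * ((1.0 - lo) / lo) ** rng.random(k)


def _wf_site_batch(
    L: int,
    demography: DemographyConfig,
    m: int,
    scenario: AdmixtureScenario,
    rng: np.random.Generator,
):
    """One batch of WF-simulated sites conditioned on modern segregation.

    Returns ``(x, genotypes)`` for roughly L sites segregating in the
    modern population.  The mutation intensity is chosen so the expected
    number of modern-segregating sites at the end is about L; standing
    variation at the oldest epoch and per-generation inflow (rate
    proportional to each lineage's Ne) keep every epoch at the neutral
    equilibrium spectrum.
    """
    ne1, ne2 = demography.ne1, demography.ne2
    harmonic = np.log(2.0 * ne1) + _EULER_GAMMA
    inflow_m = L / (2.0 * harmonic)  # new mutations per generation, modern lineage

    if scenario.mode == "ghost":
        # continuity: the ancient sample sits on the modern lineage itself,
        # while za tracks the unsampled ghost lineage
        if scenario.ghost_split_gens < demography.tau1:
            raise ValueError("ghost split must predate the main split/sampling epoch")
        sample_age = demography.tau1 - demography.tau2
        if scenario.pulse_gens > sample_age:
            raise ValueError("ghost pulse must postdate the ancient sample")
        total = int(round(scenario.ghost_split_gens))
        sample_at = total - int(round(sample_age))
        pulse_at = total - int(round(scenario.pulse_gens))
        sample_lineage = "m"
        drift_a_until = pulse_at
        a_inflow_until = pulse_at
        ne_a, inflow_a = ne1, inflow_m  # ghost population at the modern size
    else:
        if scenario.mode == "secondary_contact":
            pulse_at = int(round(demography.tau1 - scenario.pulse_gens))
            if pulse_at < demography.tau2:
                raise ValueError(
                    "secondary contact must postdate the ancient sample's death"
                )
        else:
            pulse_at = None
        total = int(round(demography.tau1))
        sample_at = int(round(demography.tau2))
        sample_lineage = "a"
        # the ancient lineage stays relevant until its variants can no
        # longer reach the data: sampling, or the pulse into the moderns
        drift_a_until = sample_at if pulse_at is None else pulse_at
        a_inflow_until = drift_a_until
        ne_a, inflow_a = ne2, inflow_m * ne2 / ne1

    z0 = _standing_sites(2 * inflow_m * harmonic, ne1, rng)
    pool = _SitePool(z0, z0.copy())
    if sample_at == 0:
        pool.record_sample(sample_lineage)
    for g in range(total):
        pool.drift(rng, ne1, ne_a if g < drift_a_until else None)
        pool.inject(rng.poisson(inflow_m), 1.0 / (2 * ne1), "m")
        if g < a_inflow_until:
            pool.inject(rng.poisson(inflow_a), 1.0 / (2 * ne_a), "a")
        if g + 1 == sample_at:
            pool.record_sample(sample_lineage)
        if pulse_at is not None and g + 1 == pulse_at:
            pool.pulse_into_modern(scenario.f, rng, ne1)
        if g % 16 == 15:
            pool.compact()
    x, y = pool.zm, pool.y

    keep = (x > 0.0) & (x < 1.0)
    x, y = x[keep], y[keep]
    chrom = rng.binomial(1, np.broadcast_to(y[:, None], (y.size, 2 * m)))
    genotypes = chrom[:, 0::2] + chrom[:, 1::2]
    return x, genotypes


def simulate_dataset(
    demography: DemographyConfig,
    read_cfg: ReadSimConfig,
    scenario: AdmixtureScenario | None = None,
    engine: str = "model_exact",
    rng: np.random.Generator | int | None = None,
    spectrum: str = "neutral_1_over_x",
) -> Dataset:
    """End-to-end dataset of ``read_cfg.L`` segregating sites.

    ``engine="model_exact"`` draws ancient genotypes from the likelihood's
    own sampling distribution (admixture scenarios are not expressible
    there); ``engine="wright_fisher"`` runs the independent forward
    simulation and supports all scenarios.  Sites with no reads in any
    individual are dropped and replaced so the returned dataset has
    exactly L usable sites, every one segregating in the modern
    population.
    """
    scenario = scenario or AdmixtureScenario()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if engine not in ("model_exact", "wright_fisher"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "model_exact" and scenario.mode != "none":
        raise ValueError("admixture scenarios require the wright_fisher engine")
    if read_cfg.coverage == 0:
        raise ValueError("coverage 0 yields no usable sites")

    cache = ExpmCache()
    xs, aa, dd = [], [], []
    n_have = 0
    # expected fraction of sites with at least one read across the panel
    p_covered = max(1.0 - np.exp(-read_cfg.coverage * read_cfg.m), 1e-3)
    while n_have < read_cfg.L:
        batch = max(1024, int(1.2 * (read_cfg.L - n_have) / p_covered))
        if engine == "model_exact":
            x = sample_modern_frequencies(batch, spectrum, rng)
            genotypes = sample_ancient_counts_model_exact(
                x, read_cfg.m, demography.params, rng, cache=cache
            )
        else:
            x, genotypes = _wf_site_batch(batch, demography, read_cfg.m, scenario, rng)
            keep = (x > 0.0) & (x < 1.0)
            x, genotypes = x[keep], genotypes[keep]
        a, d = simulate_reads(genotypes, read_cfg, x, rng)
        keep = (a + d).sum(axis=1) > 0
        xs.append(x[keep])
        aa.append(a[keep])
        dd.append(d[keep])
        n_have += int(keep.sum())
    x = np.concatenate(xs)[: read_cfg.L]
    a = np.concatenate(aa)[: read_cfg.L]
    d = np.concatenate(dd)[: read_cfg.L]
    return Dataset(x, a, d)
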