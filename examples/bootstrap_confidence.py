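"""Nonparametric bootstrap confidence intervals.

Resamples sites with replacement and refits the full model to get
percentile intervals for the drift times and the error rate.  The
intervals here use a modest replicate count to stay quick; real
analyses should use B >= 200.
"""

import continuitest as ct

demography = ct.DemographyConfig(ne1=10_000, ne2=1_000, tau1=400, tau2=100)
cfg = ct.ReadSimConfig(m=3, coverage=1.0, eps=0.01, L=5_000)
data = ct.simulate_dataset(demography, cfg, rng=3)

boot = ct.bootstrap_ci(data, B=100, seed=12)
print(f"bootstrap over {data.n_sites} sites, {boot.n_failed} failed refits")
for name in ("t1", "t2", "eps"):
    lo, hi = boot.intervals[name]
    print(f"{name}: 95% CI [{lo:.4f}, {hi:.4f}]")
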