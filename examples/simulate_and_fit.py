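"""Simulate a low-coverage ancient panel and refit the model.

Generates read counts for 3 ancient diploids at 1x mean coverage across
10,000 SNPs under the benchmark demography (t1 = 0.02, t2 = 0.05,
read error 0.01), then maximizes the likelihood over (t1, t2, eps).
The printed estimates should sit near the simulated truth; eps absorbs
sequencing error and postmortem damage jointly.
"""

import continuitest as ct

demography = ct.DemographyConfig(ne1=10_000, ne2=1_000, tau1=400, tau2=100)
cfg = ct.ReadSimConfig(m=3, coverage=1.0, eps=0.01, L=10_000)
data = ct.simulate_dataset(demography, cfg, rng=42)
print(f"simulated {data.n_sites} sites, truth: t1={demography.t1}, t2={demography.t2}")

fit = ct.fit_full(data)
print(f"t1_hat = {fit.t1:.4f}")
print(f"t2_hat = {fit.t2:.4f}")
print(f"eps_hat = {fit.eps:.4f}")
print(f"lnL = {fit.lnl:.1f} ({fit.n_starts_agreeing} optimizer starts agree)")
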