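"""Allele-frequency moments under the split-drift model.

Shows the two drift-time conversions of the benchmark demography, the
binomial moments of the ancient allele frequency conditional on a modern
frequency, and why a site covered by a single read says nothing about
drift in the ancient population.
"""

import numpy as np

import continuitest as ct

# branch lengths in generations -> diffusion units t = tau / (2 Ne)
t1 = ct.drift_time(400, 10_000)  # modern branch: split 400 gen ago
t2 = ct.drift_time(100, 1_000)   # ancient branch: sample died 300 gen ago
print(f"t1 = {t1}, t2 = {t2}")

# moments p_{n,k} = E[Y^k (1-Y)^(n-k) | X = 0.3] for a sample of n=4
# ancient chromosomes (2 diploids)
params = ct.DriftParams(t1, t2)
p = ct.binomial_moments(4, 0.3, params)
P = ct.sampling_probabilities(4, 0.3, params)
print("p_{4,k}:", np.round(p, 4))
print("P(k derived of 4):", np.round(P, 4), " sum:", P.sum().round(10))

# a single sequencing read observes one chromosome; its likelihood
# collapses to eps + (1-2 eps) x e^{-t1}, with no t2 anywhere
x, eps = 0.3, 0.01
w = ct.site_count_weights([(0, 1)], eps)  # one derived read
for t2_try in (0.0, 0.05, 1.0):
    lnl = ct.site_log_likelihood(w, ct.binomial_moments(2, x, ct.DriftParams(t1, t2_try)))
    print(f"single-read site lnL at t2={t2_try}: {lnl:.10f}")
print("closed form:", np.log(eps + (1 - 2 * eps) * x * np.exp(-t1)).round(10))
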