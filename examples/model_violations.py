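"""How admixture and contamination distort the drift estimates.

Secondary contact (gene flow from the ancient lineage into the modern
population after the sample's death) shrinks t2_hat roughly to
(1 - f) t2; contaminating reads with modern DNA pulls the drift times
toward zero, mimicking continuity.  Each setting averages a few
replicate simulations, since single fits at this scale are noisy.
"""

import numpy as np

import continuitest as ct

demo = ct.DemographyConfig()  # t1 = 0.02, t2 = 0.05
options = ct.FitOptions(t1_starts=(0.01, 0.1), t2_starts=(0.01, 0.1),
                        eps_starts=(0.01,))
N_REPS = 4


def mean_fit(scenario=None, c=0.0, tag=0):
    t1s, t2s = [], []
    cfg = ct.ReadSimConfig(m=5, coverage=1.0, eps=0.01, c=c, L=10_000)
    for rep in range(N_REPS):
        data = ct.simulate_dataset(
            demo, cfg, scenario,
            engine="wright_fisher" if scenario else "model_exact",
            rng=np.random.default_rng([tag, rep]),
        )
        fit = ct.fit_full(data, options)
        t1s.append(fit.t1)
        t2s.append(fit.t2)
    return np.mean(t1s), np.mean(t2s)


print(f"secondary contact, mean over {N_REPS} replicates (truth t2 = 0.05):")
for f in (0.0, 0.25, 0.5):
    _, t2 = mean_fit(ct.AdmixtureScenario("secondary_contact", f=f), tag=int(100 * f) + 1)
    print(f"  f={f:.2f}: mean t2_hat = {t2:.4f}  (about (1-f)*0.05 = {(1-f)*0.05:.4f})")

print("contamination by modern DNA:")
for c in (0.0, 0.1, 0.2):
    t1, t2 = mean_fit(c=c, tag=int(100 * c) + 50)
    print(f"  c={c:.2f}: mean t1_hat = {t1:.4f}, mean t2_hat = {t2:.4f}")
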