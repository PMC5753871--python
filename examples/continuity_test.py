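"""Likelihood-ratio test of population continuity.

Fits the full model and the continuity null (t2 = 0) on two simulated
panels: one truly continuous with the modern population, one from a
diverged ancient population.  The boundary-corrected mixture p-value is
the decision value: it should be large for the continuous panel and
vanishing for the diverged one.
"""

import continuitest as ct

cfg = ct.ReadSimConfig(m=3, coverage=1.0, eps=0.01, L=10_000)

for label, tau2 in [("continuous (t2=0)", 0.0), ("diverged (t2=0.05)", 100.0)]:
    demography = ct.DemographyConfig(ne1=10_000, ne2=1_000, tau1=400, tau2=tau2)
    data = ct.simulate_dataset(demography, cfg, rng=7)
    res = ct.lrt_continuity(data)
    verdict = "reject" if res.p_mixture < 0.05 else "retain"
    print(
        f"{label}: LRT = {res.lrt:.2f}, p_mixture = {res.p_mixture:.3g} "
        f"-> {verdict} continuity"
    )
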