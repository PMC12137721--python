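"""Predict noise amplification from dosage-compensated monoallelic expression.

Builds the bi-/monoallelic rate pair for one telegraph gene, verifies the
dosage arithmetic against the ODE steady state, and estimates the noise
change over a small rate ensemble with regulated target genes.
"""

import numpy as np

from allelenoise import telegraph as tg

rates = tg.RateSet(k_on=0.5, k_off=0.5, k_m=10, gamma_m=1, k_p=2,
                   gamma_p=0.5, N=2)
bi, mono = tg.dosage_compensated_pair(rates)
print("ODE protein mean, biallelic:      %.1f" % tg.ode_steady_state(bi)[2])
print("ODE protein mean, mono+doubled:   %.1f" % tg.ode_steady_state(mono)[2])
# identical means by construction: one allele, doubled transcription

targets = tg.default_target_rates()
xi = []
for i, r in enumerate(tg.rate_ensemble(n_sets=10, seed=0)):
    res = tg.network_experiment(r, expressed=targets["expressed"],
                                repressed=targets["repressed"],
                                n_cells=300, seed=10 + i)
    xi.append(res.xi_sim)
xi = np.array(xi)
print("\nmean noise change CV(mono)/CV(bi) over 10 rate sets x 300 cells:")
for g, role in enumerate(["imprinted", "expressed", "repressed"]):
    print(f"  {role:10s} {xi[:, g].mean():.3f}")
# >1 throughout: silencing one allele amplifies the imprinted gene's
# protein noise even at equal mean, and the regulatory links transfer a
# share of that extra noise to both targets.
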