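"""Closed-form oncogenic-risk model and its Monte-Carlo lineage oracle.

Given a per-doubling mutation rate, a CDS depletion factor, a substitution
spectrum and a driver catalog (n_{X->Y} activating positions over CDS length
L), computes expected activating mutations and the probability of at least
one as a function of cells produced, the in vivo equivalent exposure, and
cross-checks against a branching-lineage simulation.
"""

import numpy as np

import mutload as ml

spectrum = {"C>A": 0.0, "C>G": 0.0, "C>T": 0.5, "T>A": 0.0, "T>C": 0.5, "T>G": 0.0}
params = ml.RiskParams(mu=10, dp=1.0, spectrum=spectrum)
catalog = ml.DriverCatalog(L=1000, counts={"C>T": 2})

m = ml.oncogenic_count(1e6, params, catalog)
print(f"expected activating mutations at 1e6 cells: {m:.1f}")
per_event, _ = ml.cells_per_event(params, catalog)
print(f"one oncogenic mutation per {per_event:.0f} cells")

curve = ml.risk_curve(np.logspace(2, 6, 5), params, catalog)
print(curve.to_string(index=False))

# published-scale arithmetic: a per-cell rate of one event per 1.3e7 cells
p = ml.probability_from_per_cell_rate(1 / 1.3e7, 1e8)
print(f"\nP(>=1 oncogenic mutation | 1e8 cells at 1/1.3e7 per cell) = {p:.4f}")

# in vivo equivalence: years of adult life with the same risk
p_vitro = ml.oncogenic_probability(1e4, params, catalog)
t = ml.equivalent_exposure_time(p_vitro, params, catalog,
                                n_stem_cells=1e8, annual_rate=40)
print(f"P at 1e4 cells in vitro = {p_vitro:.4f} "
      f"= in vivo risk over {t * 365.25 * 24:.2f} hours "
      f"(a large resident pool accrues risk fast)")

# independent Monte-Carlo oracle: synchronous doublings, Poisson mutations
res = ml.simulate_lineage_oracle(params, catalog, N_target=2**10,
                                 n_replicates=10_000, seed=5)
closed = ml.oncogenic_count(2**10, params, catalog)
print(f"\noracle mean activating count {res.mean_count:.4f} +- {res.se_count:.4f} "
      f"vs closed form {closed:.4f}")
print(f"oracle P(>=1) {res.p_any:.4f} +- {res.se_p:.4f} "
      f"vs closed form {ml.oncogenic_probability(2**10, params, catalog):.4f}")
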