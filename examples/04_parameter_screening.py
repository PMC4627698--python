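"""Latin-hypercube parameter screening against synthetic blot-style data.

A hidden generating vector theta* (a seeded perturbation of nominal over
the sensitive rates) produces a noise-free observation table; LHS
candidates spanning two decades are screened with the standardized
objective J = (y_obs - y_sim)/sigma and per-dataset thresholds
|J_Erkp| <= 1, |J_IkB| <= 2.
"""

from bcrsignal import recovery_suite

report = recovery_suite(n_candidates=100, seed=5)

print(f"theta* accepted:            {report.theta_star_accepted}")
print(f"theta* max |J|:             {report.theta_star_Jmax:.2e}")
print(f"random-candidate rate:      {report.random_acceptance_rate:.3f}")
print(f"neighborhood rate:          {report.neighborhood_acceptance_rate:.3f}")
print()
print("The generating vector scores J = 0 on its own (noise-free) data, and")
print("candidates within 0.1 decade of theta* pass far more often than")
print("random two-decade candidates: the screen is selective around truth.")
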