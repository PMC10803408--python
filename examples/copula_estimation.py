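"""Gaussian-copula estimation of O-information on planted structure.

Builds two 3-variable Gaussian panels with known population O-information
(closed-form covariance): a common-latent triplet (redundancy-dominated,
Omega > 0) and a sum-node triplet (synergy-dominated, Omega < 0, the
continuous analogue of XOR). The copula estimator rank-transforms each
margin to standard-normal quantiles and evaluates the Gaussian closed form
on the empirical covariance; the estimate should sit within a few
millinats of the population value at T = 10,000.
"""

from oigrad import (CohortSpec, CopulaBackend, gaussian_cohort, o_information,
                    population_o_information)

for structure, param in (("common_latent", {"loading": 0.9}),
                         ("sum_node", {"noise_sd": 0.1})):
    spec = CohortSpec(n_records=1, n_vars=3, T=10_000, structure=structure,
                      seed=2024, **param)
    population = population_o_information(spec)
    panel = gaussian_cohort(spec)[0]
    estimate = o_information(CopulaBackend(panel, units="nats")).value
    print(f"{structure:14s}  population Omega = {population:+.4f} nats, "
          f"copula estimate = {estimate:+.4f} nats "
          f"(bias {estimate - population:+.4f})")
print("Positive Omega: redundancy-dominated; negative: synergy-dominated.")
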