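"""Bayesian comparison: kappa-exponential sum vs kappa-Maxwellian.

Simulates one chromosome from the double-kappa law, builds uniform prior
boxes around each family's best fit, runs nested sampling for both and
prints the Bayes factor with its Jeffreys-scale verdict.
"""

import warnings

from kappalen import (
    DoubleKappaModel,
    bayes_factor,
    empirical_cdf,
    fit,
    generate_chromosome,
    make_loglike,
    nested_sampling_evidence,
    prior_box_from_fit,
)

truth = DoubleKappaModel(kappa=0.35, gamma1=0.006, gamma2=0.007)
sample = generate_chromosome("double", truth, n=3000, outlier_fraction=0.0, seed=11)
ecdf = empirical_cdf(sample)

evidences = {}
for family in ("double", "maxwell"):
    best = fit(ecdf, family, seed=1)
    box = prior_box_from_fit(best, half_width_sigmas=5.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ev = nested_sampling_evidence(make_loglike(family, ecdf), box,
                                      n_live=250, seed=3)
    evidences[family] = ev
    print(f"{family:8s} chi2 = {best.chi2:9.1f}   ln Z = {ev.log_evidence:10.1f} "
          f"+/- {ev.log_evidence_error:.2f}  ({ev.n_iter} iterations)")

cmp = bayes_factor(evidences["maxwell"], evidences["double"],
                   compared_model="maxwell", reference_model="double")
print(f"\nln B (maxwell vs double) = {cmp.log_bayes_factor:.1f} -> {cmp.verdict}, "
      f"favors the {cmp.favored} model")
print("The generating kappa-sum law wins decisively: the Maxwellian cannot")
print("reproduce both the exponential-like body and the power-law tail.")
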