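"""Fit the kappa-exponential-sum law to one synthetic chromosome.

Shows the two pipeline ingredients separately: the box-plot outlier
filter on a contaminated sample, and parameter recovery by chi-square
CDF fitting on a clean sample from the same generating model.
"""

from kappalen import (
    DoubleKappaModel,
    empirical_cdf,
    fit,
    format_estimate,
    generate_chromosome,
    iqr_filter,
)

truth = DoubleKappaModel(kappa=0.35, gamma1=0.006, gamma2=0.007)

# -- outlier filtering on a sample with 1% injected extreme lengths
contaminated = generate_chromosome("double", truth, n=5000,
                                   outlier_fraction=0.01, outlier_scale=50.0,
                                   seed=7)
rep = iqr_filter(contaminated)
print(f"contaminated sample: N = {contaminated.n}, "
      f"Tukey fences [{rep.lower_fence:.1f}, {rep.upper_fence:.1f}] bp, "
      f"removed {rep.removed.size} points ({rep.removed_fraction:.1%})")
print("(the fence removes the 50 injected outliers plus ~8% genuine tail "
      "of this heavy-tailed law)")

# -- parameter recovery on a clean sample
clean = generate_chromosome("double", truth, n=5000, outlier_fraction=0.0,
                            seed=8)
res = fit(empirical_cdf(clean), "double", seed=1)
print(f"\nclean-sample double-kappa fit "
      f"(chi2 = {res.chi2:.1f} on {res.n_points} CDF points):")
for name in ("kappa", "gamma1", "gamma2"):
    est = getattr(res.params, name)
    print(f"  {name:7s} = {format_estimate(est, res.std_errors[name]):>12s}"
          f"   (truth {getattr(truth, name)})")
print("kappa-hat lands within a few 0.01 of the generating value.  With")
print("rates this close the two components are nearly exchangeable, so the")
print("individual gammas are weakly constrained (strong gamma1-gamma2")
print("correlation) while kappa and the effective rate remain sharp.")
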