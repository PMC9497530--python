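"""A complete multi-species synthetic study through the pipeline.

Generates a small three-species study, runs summary -> filter -> fits ->
evidence -> Bayes factors for every chromosome, and prints the per-
chromosome kappa table and the study-level kappa band.
"""

import warnings

from kappalen import (
    AnalysisConfig,
    SpeciesSpec,
    StudyConfig,
    generate_study,
    run_analysis,
)

config = StudyConfig(
    species=tuple(SpeciesSpec(name, n_chromosomes=2, n_per_chromosome=2000)
                  for name in ("C_maxima", "C_moschata", "C_pepo")),
    seed=4,
)
samples, manifest = generate_study(config)
truth = {(m["species"], m["chromosome"]): m["params"]["kappa"]
         for m in manifest["chromosomes"]}

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_analysis(samples, AnalysisConfig(n_live=150, mcmc_steps=20,
                                                  fit_restarts=4, seed=9))

print(f"{'species':12s} {'chrom':7s} {'N':>5s} {'cut%':>5s} "
      f"{'kappa_pre':>9s} {'truth':>6s} {'lnB':>9s} verdict")
for c in report.chromosomes:
    k_pre = c.fits_pre["double"].params.kappa
    print(f"{c.species:12s} {c.chromosome:7s} {c.n_before:5d} "
          f"{100 * c.removed_fraction:5.1f} {k_pre:9.3f} "
          f"{truth[(c.species, c.chromosome)]:6.3f} "
          f"{c.comparison.log_bayes_factor:9.1f} {c.comparison.verdict}")

kappas = [c.fits_pre["double"].params.kappa for c in report.chromosomes]
print(f"\nstudy kappa band (pre-filter fits): ({min(kappas):.3f}, {max(kappas):.3f})")
print("Every chromosome decisively favors the kappa-exponential sum (lnB << 0")
print("for the Maxwellian), and the fitted kappas track the generating band.")
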