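# kappalen

Kaniadakis κ-statistics analysis of DNA exon-length distributions:
box-plot outlier filtering, empirical-CDF χ² fitting of heavy-tailed
κ-deformed length models, and Bayesian model comparison by
nested-sampling evidence.

## The problem

Per-chromosome exon lengths (in base pairs) are strongly right-skewed:
an exponential-looking body with a power-law tail. The κ-exponential

    exp_κ(x) = (√(1 + κ²x²) + κx)^(1/κ),        |κ| < 1,

interpolates between the two regimes — classical exponential decay as
κ → 0 and survival ~ (2κx)^(−1/κ) for large arguments — which makes
κ-deformed laws natural candidates for exon-length distributions, with
κ itself a measure of the correlation between lengths. `kappalen`
implements three families through their closed-form cumulatives Φ(l):

* **single κ-exponential** — p(l) = (1−κ²) β exp_κ(−βl), β = 1/L_κ;
* **κ-exponential sum** — p(l) = (1−κ²) γ₁γ₂/(γ₁+γ₂) ·
  [exp_κ(−γ₁l) + exp_κ(−γ₂l)], the reference model (it reduces to the
  single law when γ₁ = γ₂);
* **κ-Maxwellian** — Φ(l) = 1 − exp_κ(−l²/2σ_κ²)^(1−κ), the
  Rayleigh-like alternative.

The workflow mirrors how such analyses are run on genome annotations
(e.g. the *Cucurbita* species, whose exon fits concentrate in
κ ≈ 0.27–0.43): extract per-chromosome exon lengths from GFF3/GTF/BED,
remove extreme outliers by Tukey's box-plot rule
(Q1 − 1.5·IQR, Q3 + 1.5·IQR), fit each family to the empirical CDF by
χ² = Σ (Φ̂_obs − Φ_model)²/σ_obs², then compare models with the Bayes
factor B_ij = E_i/E_j of nested-sampling evidences on a Jeffreys scale.
A seeded synthetic-data generator reproduces the assumed statistical
structure (κ band, rates 0.004–0.009 bp⁻¹, ~1% far outliers) so every
stage is testable without downloads.

## Worked example

Fitting one synthetic chromosome
(`python examples/02_fit_synthetic_chromosome.py`):

```
contaminated sample: N = 5000, Tukey fences [-310.0, 658.0] bp, removed 424 points (8.5%)
(the fence removes the 50 injected outliers plus ~8% genuine tail of this heavy-tailed law)

clean-sample double-kappa fit (chi2 = 1038.4 on 916 CDF points):
  kappa   =     0.336(2)   (truth 0.35)
  gamma1  = 0.00628(+-2e+03)   (truth 0.006)
  gamma2  = 0.00628(+-2e+03)   (truth 0.007)
```

κ̂ = 0.336 recovers the generating κ = 0.35 to within the typical
seed-to-seed scatter (≈ 0.017 at n = 5000). The two rates are nearly
exchangeable when they are this close, so their individual
uncertainties are huge (the well-known strong γ₁–γ₂ degeneracy) while κ
stays sharp. Note the fence cut on this heavy-tailed law removes ~8%
of genuine tail in addition to the injected outliers — see
`docs/methods.md` for why real annotation data, with their lighter
empirical tails, lose only ~1% instead.

Model comparison on the same kind of data
(`python examples/03_model_comparison.py`):

```
double   chi2 =     124.0   ln Z =      -81.5 +/- 0.27  (6555 iterations)
maxwell  chi2 =   26018.0   ln Z =   -13012.0 +/- 0.09  (2490 iterations)

ln B (maxwell vs double) = -12930.6 -> decisive, favors the double model
```

The κ-exponential sum is decisively preferred over the κ-Maxwellian —
the Maxwellian cannot reproduce an exponential-like body and a
power-law tail at once.

The other examples show the deformed-exponential identities
(`examples/01_kappa_functions.py`) and a complete three-species study
through the pipeline (`examples/04_full_study.py`). For shell use, the
same stages are exposed as a thin CLI:
`kappalen simulate|filter|fit|evidence|compare|run`.

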