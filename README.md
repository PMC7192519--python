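# coloctools

Bayesian pairwise colocalisation of GWAS summary statistics, with principled
prior elicitation, posterior sensitivity analysis, and two strategies —
summary-statistic conditioning and LD-masking — for regions that violate the
single-causal-variant assumption. A haplotype-based simulator provides
ground-truthed regional association data for validation.

Intended users: statistical geneticists integrating pairs of GWAS/QTL
datasets (disease vs eQTL, disease vs disease, eQTL vs pQTL, ...) who want to
know whether two traits share a causal variant in an LD-defined region, how
much that conclusion depends on the priors, and what to do when a region
carries more than one signal per trait.

## The model

For a region of *n* SNPs and two traits, every assignment of causal status
falls under one of five hypotheses:

* **H0** — no association with either trait
* **H1 / H2** — association with trait 1 / trait 2 only
* **H3** — both traits associated, distinct causal variants
* **H4** — both traits associated, one shared causal variant

Evidence per SNP is Wakefield's approximate Bayes factor. With effect
estimate β̂, its variance *V*, and a N(0, *W*) prior on the true effect,

    ABF = sqrt(1 − r) · exp(r z² / 2),    r = W / (V + W),    z = β̂ / √V.

Under at most one causal variant per trait, hypothesis-level Bayes factors
are sums of per-SNP ABF products over configurations, combined with per-SNP
priors *p₁*, *p₂*, *p₁₂* (causal for exactly trait 1, exactly trait 2, or
both) into posterior probabilities PP.H0–PP.H4. Only summary statistics are
needed: β̂ and its standard error, or p-values plus MAF and the study design.

Per-hypothesis priors scale with region size — P(H1) ≈ *np₁* but
P(H3) ≈ *n(n−1)p₁p₂* against P(H4) ≈ *np₁₂* — so the same per-SNP priors can
favour H3 or H4 depending on *n*; the crossing sits at
*n\** = 1 + *p₁₂*/(*p₁p₂*). The `priors` module translates between the
per-SNP and marginal (*q₁* = *p₁* + *p₁₂*) parameterisations, bounds
admissible *p₁₂* from the functional genome fraction *f* and the genetic
correlation *r_g* (*q₁q₂*/*f* < *p₁₂* < min(*q₁*, *q₂*), with
|*r_g*| ≤ *p₁₂*/√(*q₁q₂*)), and the `sensitivity` module reweights
posteriors across a *p₁₂* grid without recomputing Bayes factors.

When a trait has several independent signals, `coloc_signals` discovers lead
SNPs stepwise and runs one colocalisation per lead pair, adjusting each
trait for its other leads either by approximate conditioning (needs signed
effects aligned to an LD matrix) or by masking (sets the per-SNP Bayes
factor to 1 for SNPs in LD with other leads; needs no signs, and is a good
approximation when causal variants are in linkage equilibrium). The two can
be mixed across traits.

## Worked example

`examples/` contains one narrative script per capability. From
`examples/04_conditioning_and_masking.py` — trait 1 has causal variants A
(strong) and B (weaker), trait 2 only B:

```
truth: trait 1 causal at snp0012 (b=1.0) and snp0132 (b=0.5); trait 2 at snp0132

single mode (1 comparison(s)):
  leads snp0012 vs snp0132 [tags snp0012:snp0132]  PP.H0=0.000  PP.H1=0.000  PP.H2=0.000  PP.H3=1.000  PP.H4=0.000
cond mode (2 comparison(s)):
  leads snp0012 vs snp0132 [tags snp0012:snp0132]  PP.H0=0.000  PP.H1=0.000  PP.H2=0.000  PP.H3=1.000  PP.H4=0.000
  leads snp0132 vs snp0132 [tags snp0132:snp0132]  PP.H0=0.000  PP.H1=0.000  PP.H2=0.000  PP.H3=0.000  PP.H4=1.000
```

The single top-signal analysis compares A with B and concludes "distinct
variants" (PP.H3 = 1.000), missing the shared signal; conditioning adds the
B-vs-B comparison where PP.H4 = 1.000 reveals it.

From `examples/03_sensitivity_analysis.py`, a borderline region:

```
posteriors at the analysis prior (p12 = 1e-5):
  PP.H0=0.002  PP.H1=0.026  PP.H2=0.026  PP.H3=0.424  PP.H4=0.522

rule 'H4 > 0.5' holds for p12 in: [9.77e-06, 1.00e-04]
```

so a colocalisation call here stands or falls with believing H4 a priori
about as plausible as H3 — exactly what a reviewer should be shown.

A thin CLI mirrors the library for shell use: `coloc run`, `coloc priors`,
`coloc sensitivity`, `coloc signals`, `coloc simulate` (see `--help`; every
flag can come from a YAML file via `--config`).

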