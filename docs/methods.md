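# Methods

## Model and assumptions

Colocalisation is assessed per region (a set of *n* neighbouring SNPs) and
per trait pair under the assumption of **at most one causal variant per
trait** in the base analysis. Each SNP's evidence is Wakefield's approximate
Bayes factor computed from the effect estimate β̂ and its variance *V*:

    log ABF = ½ log(1 − r) + ½ r z²,   r = W/(V + W),   z = β̂/√V,

which equals the ratio of the marginal likelihood N(β̂; 0, V + W) to the
null N(β̂; 0, V). Hypothesis-level Bayes factors aggregate per-SNP ABFs over
configurations: B1 = Σᵢ L1ᵢ, B2 = Σⱼ L2ⱼ, B4 = Σᵢ L1ᵢL2ᵢ and
B3 = B1·B2 − B4. Posteriors use the ratio-to-H0 weight form
(1, p₁B1, p₂B2, p₁p₂B3, p₁₂B4), normalised in log space. This matches the
convention of the widely used R implementation; the exact multinomial
per-configuration prior differs by O(n·p) and is available from
`hypothesis_priors(..., exact=True)` for cross-checking.

All likelihood arithmetic is in log space with log-sum-exp. The H3
subtraction B3 = B1·B2 − B4 is replaced by the explicit pairwise
log-sum-exp over i ≠ j whenever B4 ≥ 0.99·B1·B2, avoiding catastrophic
cancellation when one SNP dominates both traits. Single-SNP regions have no
H3 configuration; its log BF is −∞ and it drops out of the normalisation.

## Inputs and reconstruction

Effects may be supplied directly (β̂, varβ) or as p-values plus MAF, from
which unsigned effects are reconstructed: varβ = sdY²/(2Nf(1−f)) for
quantitative traits, 1/(2Nf(1−f)s(1−s)) for case-control with case fraction
*s*, and |β̂| = z√varβ with z the two-sided normal quantile. P-values below
1e-300 are floored with a warning. Reconstructed datasets are flagged
unsigned and are refused by conditioning, which needs signs aligned to the
LD matrix. When sdY is unknown it defaults to 1 (with a warning) or can be
estimated by regressing 1/varβ through the origin on 2Nf(1−f).

SNP identity is by id string; positions are annotation only. Harmonisation
restricts all inputs to the shared id set in trait 1's order. No allele
harmonisation or strand flipping is attempted: signed inputs are assumed
pre-aligned to their LD matrix, which is a documented contract, not a
checked one.

## Effect priors

Defaults: prior SD 0.2 (in trait-SD units, scaled by sdY) for quantitative
traits and 0.15 (log-odds) for case-control, i.e. W = 0.04 / 0.0225. These
are surfaced as `EffectPrior` rather than buried, because the headline
single-SNP calibration (posterior ≈ 0.95 at p = 5×10⁻⁸ with q = 10⁻⁴)
depends on them. Note the low-power corner: for a case-control design with
N·f(1−f)·s(1−s) small, V approaches W, the ABF at fixed z shrinks toward 1
and the posterior of association can fall far below the well-powered value —
the posterior-vs-significance curve is design-consistent only where V ≪ W.

## Priors: defaults, translation, bounds

Software defaults p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵. Marginal single-trait priors
q ≈ 10⁻⁴ are supported by three converging arguments (eQTL hit rates,
GWAS-catalog hits per common SNP — `empirical_q` does the arithmetic — and
the significance-calibration argument above). The default p₁₂ can be
liberal for large regions or small samples; simulation (the
`expected_posterior_table` study) shows H3-generated data gaining H4 support
at p₁₂ = 10⁻⁵, less so at 5×10⁻⁶. Rather than moving the default we expose
bounds (q₁q₂/f < p₁₂ < min(q₁, q₂); |r_g|√(q₁q₂) ≤ p₁₂) and recommend the
sensitivity scan for every reported result. The single-SNP posterior
formula uses (1 − π) in the denominator, P = BF·π/(BF·π + 1 − π).

## Sensitivity reweighting

P(Hᵢ | D, π*) ∝ P(Hᵢ | D, π) · P(Hᵢ | π*)/P(Hᵢ | π). The ratios are taken
in the same ratio-to-H0 form as the posterior weights (H0 ratio 1; the
region size cancels), so reweighting is exact — it agrees with full
recomputation from stored log BFs to machine precision, which the tests
assert at 10⁻¹². The displayed prior curves in a sensitivity table use the
normalised linear per-hypothesis priors (H0 as complement), which is a
presentation choice only. During a scan p₁ and p₂ are held fixed and only
p₁₂ moves, on a log-spaced grid restricted to feasible values. The decision
rule is a deliberately tiny expression grammar (H0–H4, numbers, + − × ÷,
one comparison, and/or) evaluated over a whitelisted AST — no code
execution.

## Conditioning

Approximate conditioning reconstructs the joint design cross-products from
summary statistics and LD: per-SNP genotype sums of squares are recovered by
the in-sample identity Sxx = (N−1)·sdY²/(β̂² + (N−2)·varβ) (exact for OLS
summary statistics given sdY), X'X from r·√(SxxᵢSxxⱼ), X'y from Sxx·β̂, and
y'y = (N−1)sdY². For each target SNP j the joint least-squares system on
{j} ∪ S is solved and the j component reported with its variance from the
joint residual. With in-sample LD this reproduces exact joint regression on
raw genotypes to floating-point accuracy; we chose the Sxx identity over
the HWE approximation 2Nf(1−f) precisely because the latter injects
O(N^−1/2) noise that is material relative to conditional standard errors.
With reference-panel LD the usual caveat applies: LD mismatch propagates
into conditional estimates, especially from small panels.

Degenerate cases: conditioning sets with internal r² ≥ 0.9 are an error
naming the offending pair; targets with r² ≥ 0.9 to the set are flagged and
reported with conditional z = 0 (β = 0, marginal varβ kept). Conditioning
on an orthogonal SNP leaves target betas unchanged exactly; their variances
shift at O(1/N) because the joint fit changes the residual degrees of
freedom, which we report honestly rather than patching.

## Stepwise discovery, masking, orchestration

Lead SNPs are found by iteratively taking the smallest p-value among
eligible SNPs (p from z). `cond` recomputes conditional statistics on the
selected set each round; `mask` removes from eligibility all SNPs with
r² ≥ threshold to any selected lead. Defaults: p-threshold 10⁻⁶ (a
conventional stepwise threshold; configurable), r² threshold 0.01 for
masking/eligibility, at most 3 signals per trait (studies here involve ≤ 2
causal variants; one spare). In `coloc_signals`, each lead pair is analysed
after adjusting each trait for *its other* leads; masks are applied per
trait independently. Masking assumes causal variants of a trait are in
linkage equilibrium; when they are in LD, comparisons whose leads tag no
causal variant at r² ≥ 0.8 (labelled "?") concentrate, and secondary H3
conclusions deserve caution. If stepwise finds nothing significant the top
SNP is used as a pseudo-lead so one (typically null) comparison is still
reported.

## Simulator

The synthetic panel draws SNP frequencies uniformly on [0.02, 0.5] and
thresholds block-equicorrelated latent Gaussians (block size 25, latent
correlation 0.7 by default), giving ~10 independent LD blocks per 250-SNP
region — a caricature of real haplotype structure with tunable block LD and
exact independence between blocks. Genotypes are sums of two haplotypes
drawn with replacement; traits are Y = Σ bᵢGᵢ + e with e ~ N(0,1); causal
variants are drawn among SNPs with MAF > 5% and effects from
{0.17, …, 1.50}; summary statistics are marginal OLS per SNP. A plain 0/1
matrix loader accepts real reference panels. What the generator does *not*
emulate: realistic LD decay within/between blocks, allele-frequency spectra,
population structure, case-control ascertainment, or imputation noise — so
passing tests demonstrate correctness of the inferential machinery under
the stated model, not robustness to real-data pathologies.

Problem sizes in the test suite are scaled to desk use: 200–250-SNP regions
from a 1000-haplotype panel, 100 replicates per cell for the truth-recovery
study (N ∈ {1000, 10000}), 40–50 replicates for the multi-signal and
conditional-recovery studies, 200 for the mask-vs-cond agreement property.
These sizes were chosen as the smallest at which the Monte-Carlo noise is
comfortably below the effects being demonstrated.

## Known limitations

- Two traits only; no shared-control adjustment.
- No VCF parsing, no genome arithmetic, no allele/strand harmonisation.
- Case-control data enter through closed-form reconstruction only; the
  simulator generates quantitative traits.
- Conditioning quality is bounded by LD quality; masking trades power for
  robustness to exactly that.
- Meta-analysed summary statistics across populations cannot be conditioned
  correctly with a single-population LD matrix.
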