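"""Per-SNP approximate Bayes factors and per-hypothesis posteriors.

The colocalisation model enumerates every configuration of causal variants
for two traits in a region of n SNPs, under the assumption of at most one
causal variant per trait.  Each configuration falls under exactly one of five
hypotheses:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  both traits associated, distinct causal variants
    H4  both traits associated, one shared causal variant

Evidence per SNP is summarised by Wakefield's approximate Bayes factor (ABF),
computed from the effect estimate, its variance and a normal prior N(0, W) on
the true effect.  Hypothesis-level Bayes factors are sums of per-SNP ABF
products over the configurations of each hypothesis, and posteriors combine
them with per-SNP prior probabilities p1, p2, p12 in the ratio-to-H0 form

    S0 = 1,  S1 = p1 B1,  S2 = p2 B2,  S3 = p1 p2 B3,  S4 = p12 B4,

where B1 = sum_i L1i, B2 = sum_j L2j, B4 = sum_i L1i L2i and
B3 = sum_{i != j} L1i L2j = B1 B2 - B4.  All sums are carried out in log
space with log-sum-exp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .priors import PriorParams, default_priors
from .sumstats import CC, QUANT, LDMatrix, RegionSummary, harmonise, reconstruct_effects

__all__ = [
    "EffectPrior",
    "ColocResult",
    "wakefield_log_abf",
    "region_log_abf",
    "hypothesis_log_bf",
    "coloc_posterior",
    "per_snp_h4",
    "coloc_abf",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

#: when B4 exceeds this fraction of B1*B2, the H3 subtraction identity is
#: abandoned for the explicit pairwise sum (cancellation guard)
_H3_CANCEL_FRAC = 0.99


@dataclass(frozen=True)
class EffectPrior:
    """Prior SD of the true effect at a causal SNP (W = sd**2).

    ``sd_quant`` applies to quantitative traits and is expressed in trait-SD
    units (it is scaled by the trait SD when known); ``sd_cc`` applies to
    case-control traits on the log-odds scale.
    """

    sd_quant: float = 0.2
    sd_cc: float = 0.15

    def __post_init__(self):
        if self.sd_quant <= 0 or self.sd_cc <= 0:
            raise ValueError("effect-prior SDs must be positive")

    def w_for(self, d: RegionSummary) -> float:
        if d.trait_type == CC:
            return self.sd_cc**2
        sdY = d.sd_trait if d.sd_trait is not None else 1.0
        return (self.sd_quant * sdY) ** 2


def wakefield_log_abf(beta, varbeta, W: float):
    """Log of Wakefield's approximate Bayes factor for a single SNP.

    With V = varbeta, z = beta/sqrt(V) and shrinkage r = W/(V+W),

        log ABF = 0.5 * log(1 - r) + r * z**2 / 2.

    The ABF compares the alternative (true effect ~ N(0, W)) with the null of
    no effect; it equals the ratio of normal densities N(beta; 0, V+W) /
    N(beta; 0, V).  Vectorised over ``beta``/``varbeta``.
    """
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if (varbeta <= 0).any():
        raise ValueError("varbeta must be positive")
    if W < 0:
        raise ValueError("prior effect variance W must be nonnegative")
    r = W / (varbeta + W)
    z2 = beta**2 / varbeta
    out = 0.5 * np.log1p(-r) + 0.5 * r * z2
    return out if out.ndim else float(out)


def region_log_abf(d: RegionSummary, effect_prior: EffectPrior | None = None) -> np.ndarray:
    """Per-SNP log ABFs for one trait, reconstructing effects if needed."""
    effect_prior = effect_prior or EffectPrior()
    if d.needs_reconstruction:
        d = reconstruct_effects(d)
    return np.asarray(wakefield_log_abf(d.beta, d.varbeta, effect_prior.w_for(d)))


def hypothesis_log_bf(labf1, labf2) -> np.ndarray:
    """Log Bayes factors for H1..H4 relative to H0.

    For n = 1 there is no two-distinct-SNP configuration, so log BF(H3) is
    reported as -inf (excluded from posterior normalisation downstream).
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("labf1 and labf2 must be equal-length 1-d arrays")
    n = labf1.size
    if n == 0:
        raise ValueError("empty log ABF input")
    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l4 = logsumexp(labf1 + labf2)
    if n == 1:
        return np.array([l1, l2, -np.inf, l4])
    joint = l1 + l2
    # B3 = B1*B2 - B4; guard the log-space subtraction against cancellation
    if l4 - joint > np.log(_H3_CANCEL_FRAC):
        pair = labf1[:, None] + labf2[None, :]
        np.fill_diagonal(pair, -np.inf)
        l3 = logsumexp(pair)
    else:
        l3 = joint + np.log1p(-np.exp(l4 - joint))
    return np.array([l1, l2, l3, l4])


def _posterior_from_logbf(log_bf: np.ndarray, priors: PriorParams) -> np.ndarray:
    lw = np.array(
        [
            0.0,
            np.log(priors.p1) + log_bf[0],
            np.log(priors.p2) + log_bf[1],
            np.log(priors.p1) + np.log(priors.p2) + log_bf[2],
            np.log(priors.p12) + log_bf[3],
        ]
    )
    return np.exp(lw - logsumexp(lw))


@dataclass
class ColocResult:
    """Result of one pairwise colocalisation analysis.

    ``log_bf`` holds log BF(H1..H4) against H0; ``pp`` the posterior
    probabilities of H0..H4 (summing to 1); ``per_snp_h4`` the posterior that
    each SNP is the shared variant, conditional on H4 (summing to 1).
    ``lead1``/``lead2`` are filled by multi-signal analyses.
    """

    nsnps: int
    log_bf: np.ndarray
    pp: np.ndarray
    priors_used: PriorParams
    per_snp_h4: np.ndarray | None = None
    snp_ids: np.ndarray | None = None
    lead1: str | None = None
    lead2: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def pp_dict(self) -> dict:
        return dict(zip(HYPOTHESES, (float(x) for x in self.pp)))

    def best_hypothesis(self) -> str:
        return HYPOTHESES[int(np.argmax(self.pp))]

    def top_shared_snp(self) -> str | None:
        if self.per_snp_h4 is None or self.snp_ids is None:
            return None
        return str(self.snp_ids[int(np.argmax(self.per_snp_h4))])

    def to_dict(self) -> dict:
        out = {
            "nsnps": int(self.nsnps),
            "log_bf": {h: float(v) for h, v in zip(HYPOTHESES[1:], self.log_bf)},
            "pp": self.pp_dict,
            "priors": {
                "p1": self.priors_used.p1,
                "p2": self.priors_used.p2,
                "p12": self.priors_used.p12,
            },
            "lead1": self.lead1,
            "lead2": self.lead2,
        }
        return out

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        lines = [f"nsnps = {self.nsnps}"]
        lines.append(
            "  ".join(f"PP.{h} = {p:.4f}" for h, p in self.pp_dict.items())
        )
        if self.lead1 or self.lead2:
            lines.append(f"leads: trait1={self.lead1}  trait2={self.lead2}")
        top = self.top_shared_snp()
        if top is not None:
            lines.append(
                f"top shared-variant candidate (given H4): {top} "
                f"(P = {float(np.max(self.per_snp_h4)):.3f})"
            )
        return "\n".join(lines)


def coloc_posterior(
    log_bf, priors: PriorParams, nsnps: int, per_snp_h4_vec=None, snp_ids=None
) -> ColocResult:
    """Posterior probabilities of H0..H4 from hypothesis log BFs and priors.

    The per-configuration prior form is used: the configuration counts are
    already inside the hypothesis BF sums, so the weights are S0 = 1,
    S1 = p1 B1, S2 = p2 B2, S3 = p1 p2 B3, S4 = p12 B4, normalised in log
    space.  A -inf log BF(H3) (single-SNP region) drops out of the
    normalisation naturally.
    """
    if nsnps < 1:
        raise ValueError("nsnps must be >= 1")
    log_bf = np.asarray(log_bf, dtype=float)
    if log_bf.shape != (4,):
        raise ValueError("log_bf must have four entries (H1..H4)")
    pp = _posterior_from_logbf(log_bf, priors)
    return ColocResult(
        nsnps=nsnps,
        log_bf=log_bf,
        pp=pp,
        priors_used=priors,
        per_snp_h4=per_snp_h4_vec,
        snp_ids=snp_ids,
    )


def per_snp_h4(labf1, labf2) -> np.ndarray:
    """Posterior that each SNP is THE shared variant, conditional on H4."""
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape:
        raise ValueError("length mismatch between per-SNP log ABF vectors")
    joint = labf1 + labf2
    return np.exp(joint - logsumexp(joint))


def coloc_abf(
    d1: RegionSummary,
    d2: RegionSummary,
    priors: PriorParams | None = None,
    effect_prior: EffectPrior | None = None,
    ld1: LDMatrix | None = None,
    ld2: LDMatrix | None = None,
) -> ColocResult:
    """Full single-signal colocalisation of two harmonised trait datasets.

    Orchestrates effect reconstruction (if the input carries p-values only),
    per-SNP Wakefield ABFs with the trait-appropriate prior variance,
    hypothesis-level Bayes factors and posterior probabilities.  Inputs with
    differing SNP sets are harmonised to their intersection first.
    """
    priors = priors or default_priors()
    effect_prior = effect_prior or EffectPrior()
    if not np.array_equal(d1.snp_ids, d2.snp_ids):
        d1, d2, ld1, ld2 = harmonise(d1, d2, ld1, ld2)
    labf1 = region_log_abf(d1, effect_prior)
    labf2 = region_log_abf(d2, effect_prior)
    log_bf = hypothesis_log_bf(labf1, labf2)
    return coloc_posterior(
        log_bf,
        priors,
        nsnps=d1.nsnps,
        per_snp_h4_vec=per_snp_h4(labf1, labf2),
        snp_ids=d1.snp_ids,
    )
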