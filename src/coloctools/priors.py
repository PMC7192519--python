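"""Prior elicitation and translation for pairwise colocalisation.

Two equivalent parameterisations are supported:

* per-SNP: p1, p2, p12 — the prior probabilities that a random SNP in the
  region is causal for exactly trait 1, exactly trait 2, or both;
* marginal: q1 = p1 + p12, q2 = p2 + p12 — the marginal probabilities that a
  random SNP is causal for each trait, plus optionally the conditional
  q1|2 = P(causal for 1 | causal for 2), with p12 = q1|2 * q2.

Because priors are per SNP while hypotheses are regional, the per-hypothesis
priors scale with region size n: P(H1) ~ n p1, P(H3) ~ n(n-1) p1 p2,
P(H4) ~ n p12.  H3 grows with n^2 while H4 grows with n, so the same per-SNP
priors can favour either hypothesis depending on region size; the crossing
point P(H3) = P(H4) sits at n* = 1 + p12/(p1 p2).

This module also provides admissible bounds on p12 given the marginals, a
functional-fraction argument and the genetic correlation, and the single-SNP
posterior probability of association used to sanity-check q against a
significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PriorParams",
    "MarginalPriors",
    "HypothesisPriors",
    "default_priors",
    "persnp_to_marginal",
    "marginal_to_persnp",
    "p12_from_conditional",
    "hypothesis_priors",
    "h3_h4_crossing",
    "p12_bounds",
    "rg_upper_bound",
    "empirical_q",
    "single_snp_ppa",
]


@dataclass(frozen=True)
class PriorParams:
    """Per-SNP prior probabilities (p1, p2, p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass(frozen=True)
class MarginalPriors:
    """Marginal per-SNP causality probabilities (q1, q2[, q1|2])."""

    q1: float
    q2: float
    q1_given_2: float | None = None

    def __post_init__(self):
        for name in ("q1", "q2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.q1_given_2 is not None and not 0 <= self.q1_given_2 <= 1:
            raise ValueError("q1_given_2 must lie in [0, 1]")


@dataclass(frozen=True)
class HypothesisPriors:
    """Per-hypothesis priors at a given region size n (linear form)."""

    h0: float
    h1: float
    h2: float
    h3: float
    h4: float
    n: int

    def as_array(self) -> np.ndarray:
        return np.array([self.h0, self.h1, self.h2, self.h3, self.h4])

    def normalised(self) -> np.ndarray:
        a = self.as_array()
        return a / a.sum()


def default_priors() -> PriorParams:
    """Software default (p1 = p2 = 1e-4, p12 = 1e-5).

    Simulation evidence suggests p12 = 5e-6 is more robust when regions are
    large or samples small; sensitivity analysis over a p12 grid is strongly
    encouraged (see :mod:`coloctools.sensitivity`).
    """
    return PriorParams()


def persnp_to_marginal(p: PriorParams) -> MarginalPriors:
    """(p1, p2, p12) -> (q1, q2) with q1 = p1 + p12, q2 = p2 + p12."""
    return MarginalPriors(q1=p.p1 + p.p12, q2=p.p2 + p.p12)


def marginal_to_persnp(q1: float, q2: float, p12: float) -> PriorParams:
    """(q1, q2, p12) -> (p1, p2, p12); requires p12 < min(q1, q2)."""
    if p12 >= min(q1, q2):
        raise ValueError(
            f"p12 = {p12} must be below min(q1, q2) = {min(q1, q2)}"
        )
    return PriorParams(p1=q1 - p12, p2=q2 - p12, p12=p12)


def p12_from_conditional(q1_given_2: float, q2: float) -> float:
    """p12 = q1|2 * q2 — joint causality via the conditional route."""
    if not 0 <= q1_given_2 <= 1:
        raise ValueError("q1_given_2 must lie in [0, 1]")
    if not 0 < q2 < 1:
        raise ValueError("q2 must lie in (0, 1)")
    if q1_given_2 == 0:
        warnings.warn("q1_given_2 = 0 gives p12 = 0 (degenerate)", stacklevel=2)
    return q1_given_2 * q2


def hypothesis_priors(n: int, p: PriorParams, exact: bool = False) -> HypothesisPriors:
    """Per-hypothesis priors at region size n.

    The default linear form is P(H1) = n p1, P(H2) = n p2,
    P(H3) = n(n-1) p1 p2, P(H4) = n p12 and P(H0) the complement.  With
    ``exact=True`` the exact multinomial configuration probabilities are
    returned instead (each SNP independently null/trait-1/trait-2/shared;
    configurations with more than one causal variant per trait carry the
    remaining mass, so the five entries sum to slightly less than 1).  The
    two agree to O(n * p).
    """
    if n < 1:
        raise ValueError("region size n must be >= 1")
    if exact:
        p0 = 1.0 - p.p1 - p.p2 - p.p12
        h0 = p0**n
        h1 = n * p.p1 * p0 ** (n - 1)
        h2 = n * p.p2 * p0 ** (n - 1)
        h3 = n * (n - 1) * p.p1 * p.p2 * p0 ** (n - 2)
        h4 = n * p.p12 * p0 ** (n - 1)
        return HypothesisPriors(h0, h1, h2, h3, h4, n)
    h1 = n * p.p1
    h2 = n * p.p2
    h3 = n * (n - 1) * p.p1 * p.p2
    h4 = n * p.p12
    tot = h1 + h2 + h3 + h4
    if tot >= 1:
        raise ValueError(
            f"per-hypothesis priors sum to {tot:.3g} >= 1 at n = {n}; "
            "the region is too large for these per-SNP priors"
        )
    return HypothesisPriors(1.0 - tot, h1, h2, h3, h4, n)


def h3_h4_crossing(p: PriorParams) -> tuple[float, str]:
    """Region size n* at which P(H3) = P(H4), and which side H4 dominates.

    n(n-1) p1 p2 = n p12 gives n* = 1 + p12/(p1 p2).  For n < n* the prior
    favours H4 over H3; for n > n* it favours H3.
    """
    if p.p1 * p.p2 <= 0:
        raise ValueError("p1 * p2 must be positive")
    n_star = 1.0 + p.p12 / (p.p1 * p.p2)
    return n_star, "H4 dominates below n*, H3 above"


def p12_bounds(
    q1: float, q2: float, functional_fraction: float = 1.0, rg: float = 0.0
) -> tuple[float, float]:
    """Admissible interval for p12 given marginals, f and rg.

    Lower bound: joint causality can arise by chance alone among functional
    variants, q1*q2/f; and a nonzero genetic correlation forces
    p12 >= |rg| * sqrt(q1*q2).  Upper bound: p12 <= min(q1, q2).
    """
    if not 0 < functional_fraction <= 1:
        raise ValueError("functional_fraction must lie in (0, 1]")
    if abs(rg) > 1:
        raise ValueError("|rg| must be <= 1")
    lower = max(q1 * q2 / functional_fraction, abs(rg) * np.sqrt(q1 * q2))
    upper = min(q1, q2)
    if lower > upper:
        raise ValueError(
            f"infeasible: lower bound {lower:.3g} exceeds upper bound "
            f"{upper:.3g}; the stated rg/f are inconsistent with the marginals"
        )
    return float(lower), float(upper)


def rg_upper_bound(n1: int, n2: int, n12: int) -> float:
    """Bound |rg| <= n12 / sqrt((n12+n1)(n12+n2)).

    n1, n2 are counts of variants causal for one trait only, n12 the count of
    shared causal variants; the bound assumes shared variants have no
    systematically different frequency/effect distribution.
    """
    if min(n1, n2, n12) < 0:
        raise ValueError("counts must be nonnegative")
    if n12 + n1 == 0 or n12 + n2 == 0:
        raise ValueError("n12+n1 and n12+n2 must be positive")
    return float(n12 / np.sqrt((n12 + n1) * (n12 + n2)))


def empirical_q(n_hits: int, n_snps: int) -> float:
    """Empirical marginal prior: independent hits / SNPs considered.

    E.g. the largest GWAS report ~100-1000 hits among ~2e6 common SNPs,
    giving q in [5e-5, 5e-4].
    """
    if n_hits < 0 or n_snps <= 0:
        raise ValueError("need n_hits >= 0 and n_snps > 0")
    return n_hits / n_snps


def single_snp_ppa(
    p,
    q: float,
    *,
    trait_type: str = "quant",
    n_samples: int,
    maf: float,
    case_fraction: float | None = None,
    sd_trait: float = 1.0,
    effect_prior=None,
):
    """Posterior probability of association at a single SNP.

    Converts the two-sided p-value to z, derives the effect variance V from
    the study design (as in effect reconstruction), computes the Wakefield
    ABF, and returns

        P(associated | data) = ABF * q / (ABF * q + (1 - q)).

    Vectorised over ``p`` to draw the posterior-vs-significance curve.
    """
    from .bayes import EffectPrior, wakefield_log_abf  # local: avoid cycle

    effect_prior = effect_prior or EffectPrior()
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie in (0, 1)")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if not 0 < maf < 1:
        raise ValueError("maf must lie in (0, 1)")
    if trait_type == "quant":
        V = sd_trait**2 / (2.0 * n_samples * maf * (1.0 - maf))
        W = (effect_prior.sd_quant * sd_trait) ** 2
    elif trait_type == "cc":
        s = case_fraction if case_fraction is not None else 0.5
        if not 0 < s < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        V = 1.0 / (2.0 * n_samples * maf * (1.0 - maf) * s * (1.0 - s))
        W = effect_prior.sd_cc**2
    else:
        raise ValueError("trait_type must be 'quant' or 'cc'")
    z = stats.norm.isf(p / 2.0)
    labf = wakefield_log_abf(z * np.sqrt(V), V, W)
    # posterior odds = ABF * q/(1-q); stable in log space
    log_odds = np.asarray(labf) + np.log(q) - np.log1p(-q)
    out = 1.0 / (1.0 + np.exp(-log_odds))
    return out if out.ndim else float(out)
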