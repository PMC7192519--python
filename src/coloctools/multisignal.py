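"""Relaxing the single-causal-variant assumption: conditioning and masking.

The single-signal model effectively colocalises only the strongest signal of
each trait.  When a region carries several independent association signals,
two strategies recover the remaining comparisons:

* conditioning — lead SNPs are found by stepwise selection, re-estimating
  conditional summary statistics from the marginal statistics plus a signed,
  allele-aligned LD matrix; each lead is then colocalised after conditioning
  its trait on all its other leads;
* masking — requires no signed effects: lead SNPs are found by successively
  removing from eligibility every SNP in LD (r2 above a threshold) with the
  leads selected so far; when colocalising one lead, the per-SNP Bayes
  factors of all SNPs in LD with any *other* lead are set to 1.

Masking approximates conditioning when causal variants are mutually in
linkage equilibrium, and the two can be mixed across the two traits (e.g.
conditioning in the dataset with full information, masking in a public one).
With n leads for trait 1 and m for trait 2, n x m colocalisation analyses
are performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .bayes import (
    EffectPrior,
    coloc_posterior,
    hypothesis_log_bf,
    per_snp_h4,
    region_log_abf,
)
from .priors import PriorParams, default_priors
from .sumstats import LDMatrix, RegionSummary, estimate_sd_trait, harmonise

logger = logging.getLogger(__name__)

__all__ = [
    "SignalSet",
    "ComparisonLabel",
    "stepwise_signals",
    "conditional_summary",
    "mask_log_abf",
    "coloc_signals",
    "label_comparison",
]

#: r2 above which a SNP is considered collinear with the conditioning set
COLLINEARITY_R2 = 0.9
#: r2 defining "clearly tags a causal variant" when labelling comparisons
LABEL_R2 = 0.8


@dataclass
class SignalSet:
    """Lead SNPs for the independent association signals of one trait."""

    lead_ids: tuple
    method: str  # "mask" | "cond" | "single"
    p_threshold: float
    r2_threshold: float
    max_signals: int

    def __post_init__(self):
        self.lead_ids = tuple(str(s) for s in self.lead_ids)
        if len(set(self.lead_ids)) != len(self.lead_ids):
            raise ValueError("lead ids must be unique")
        if self.method not in ("mask", "cond", "single"):
            raise ValueError("method must be 'mask', 'cond' or 'single'")

    def __len__(self):
        return len(self.lead_ids)


@dataclass(frozen=True)
class ComparisonLabel:
    """Causal-variant tags for the two leads of one comparison.

    A lead is tagged with the causal variant of maximal r2 when that r2 is at
    least 0.8, and with "?" otherwise.
    """

    trait1_hit: str
    trait2_hit: str


def _pvalues(d: RegionSummary) -> np.ndarray:
    if d.beta is not None and d.varbeta is not None:
        z = d.beta / np.sqrt(d.varbeta)
        return 2.0 * stats.norm.sf(np.abs(z))
    if d.pvalues is not None:
        return np.asarray(d.pvalues, dtype=float)
    raise ValueError("need beta/varbeta or pvalues")


def _check_aligned(d: RegionSummary, ld: LDMatrix):
    if not np.array_equal(d.snp_ids, ld.snp_ids):
        raise ValueError("summary statistics and LD matrix are not harmonised")


# ---------------------------------------------------------------------------
# approximate conditioning from summary statistics + LD
# ---------------------------------------------------------------------------

def _sxx(d: RegionSummary, sd_trait: float) -> np.ndarray:
    """Per-SNP genotype sum of squares, reconstructed from the marginal fit.

    From varbeta = RSS/((N-2) Sxx) and RSS = Syy - beta^2 Sxx with
    Syy = (N-1) sdY^2, we get Sxx = (N-1) sdY^2 / (beta^2 + (N-2) varbeta),
    an in-sample identity.  Falls back to the HWE approximation
    2 N f (1-f) when varbeta is unavailable.
    """
    N = d.n_samples
    if d.varbeta is not None and d.beta is not None:
        return (N - 1) * sd_trait**2 / (d.beta**2 + (N - 2) * d.varbeta)
    if d.maf is None:
        raise ValueError("need varbeta or maf to reconstruct genotype variance")
    return 2.0 * N * d.maf * (1.0 - d.maf)


def conditional_summary(
    d: RegionSummary,
    ld: LDMatrix,
    condition_on,
    sd_trait: float | None = None,
    collinearity_r2: float = COLLINEARITY_R2,
) -> RegionSummary:
    """Association statistics conditional on a set of SNPs.

    Reconstructs X'X from the LD matrix and per-SNP genotype variances, X'y
    from the marginal effects, and solves, for every target SNP j not in the
    conditioning set S, the joint least-squares system on {j} ∪ S, reporting
    the j component and its variance.  Requires signed betas aligned to the
    LD matrix.

    Targets whose r2 with the conditioning set exceeds ``collinearity_r2``
    are flagged: their conditional beta is set to 0 (z = 0) and their
    marginal varbeta retained.  A conditioning set with internal r2 above the
    cap is an error.

    When the LD matrix comes from an external reference panel rather than the
    study sample, conditional estimates inherit any LD mismatch; small
    reference panels can produce unstable conditional statistics.
    """
    _check_aligned(d, ld)
    if not d.signed:
        raise ValueError(
            "conditioning requires signed effect estimates; effects "
            "reconstructed from p-values are unsigned"
        )
    if d.beta is None or d.varbeta is None:
        raise ValueError("conditioning requires beta and varbeta")
    if d.n_samples is None:
        raise ValueError("conditioning requires the sample size")
    condition_on = [str(s) for s in condition_on]
    index = {s: i for i, s in enumerate(d.snp_ids)}
    missing = [s for s in condition_on if s not in index]
    if missing:
        raise KeyError(f"conditioning SNPs not in region: {', '.join(missing)}")
    S = np.array([index[s] for s in condition_on], dtype=int)
    if len(S) == 0:
        return d
    r2_SS = ld.r[np.ix_(S, S)] ** 2
    iu = np.triu_indices(len(S), k=1)
    if len(S) > 1 and (r2_SS[iu] >= collinearity_r2).any():
        k = int(np.argmax(r2_SS[iu]))
        a, b = condition_on[iu[0][k]], condition_on[iu[1][k]]
        raise ValueError(
            f"conditioning set is collinear: r2({a}, {b}) = {r2_SS[iu][k]:.3f} "
            f">= {collinearity_r2}"
        )
    if sd_trait is None:
        sd_trait = d.sd_trait if d.sd_trait is not None else estimate_sd_trait(d)
    N = d.n_samples
    sxx = _sxx(d, sd_trait)
    yty = (N - 1) * sd_trait**2
    scale = np.sqrt(sxx)
    xty = sxx * d.beta

    B_SS = ld.r[np.ix_(S, S)] * np.outer(scale[S], scale[S])
    targets = np.array([i for i in range(d.nsnps) if i not in set(S)], dtype=int)
    B_TS = ld.r[np.ix_(targets, S)] * np.outer(scale[targets], scale[S])

    w = np.linalg.solve(B_SS, xty[S])          # joint fit of S alone
    U = np.linalg.solve(B_SS, B_TS.T).T        # (n_targets, k)
    denom = sxx[targets] - np.einsum("ij,ij->i", B_TS, U)
    num = xty[targets] - B_TS @ w
    k = len(S)
    df = N - k - 2
    if df < 1:
        raise ValueError("not enough samples for the conditioning set size")

    # collinearity of targets with the conditioning set
    r2_T = (ld.r[np.ix_(targets, S)] ** 2).max(axis=1)
    ok = (r2_T < collinearity_r2) & (denom > 0)
    beta_c = np.zeros(len(targets))
    var_c = np.asarray(d.varbeta, dtype=float)[targets].copy()
    if ok.any():
        b = num[ok] / denom[ok]
        # residual SS of the joint fit on {j} ∪ S
        beta_S = w[None, :] - U[ok] * b[:, None]
        fitted = np.einsum("ij,j->i", beta_S, xty[S]) + b * xty[targets][ok]
        rss = np.maximum(yty - fitted, 1e-12)
        beta_c[ok] = b
        var_c[ok] = rss / df / denom[ok]
    n_flag = int((~ok).sum())
    if n_flag:
        logger.warning(
            "conditional_summary: %d SNPs collinear with the conditioning "
            "set (r2 >= %.2f); their conditional z set to 0",
            n_flag,
            collinearity_r2,
        )
    out = d.subset([d.snp_ids[i] for i in targets])
    return replace(out, beta=beta_c, varbeta=var_c, pvalues=None)


# ---------------------------------------------------------------------------
# stepwise lead-SNP discovery
# ---------------------------------------------------------------------------

def stepwise_signals(
    d: RegionSummary,
    ld: LDMatrix,
    method: str = "mask",
    p_threshold: float = 1e-6,
    r2_threshold: float = 0.01,
    max_signals: int = 3,
) -> SignalSet:
    """Iterative discovery of independent lead SNPs for one trait.

    Each round selects the smallest-p SNP among those still eligible.  With
    ``method="cond"`` the statistics are re-estimated conditional on the
    selected set each round (signed betas and LD required); with
    ``method="mask"`` every SNP with r2 >= ``r2_threshold`` to any selected
    lead is removed from eligibility.  Stops when the smallest eligible
    p-value exceeds ``p_threshold``, eligibility empties, or ``max_signals``
    is reached.
    """
    if method not in ("mask", "cond"):
        raise ValueError("method must be 'mask' or 'cond'")
    _check_aligned(d, ld)
    if method == "cond" and not d.signed:
        raise ValueError("stepwise conditioning requires signed betas")
    leads: list[str] = []
    r2 = ld.r2()
    index = {s: i for i, s in enumerate(d.snp_ids)}
    eligible = np.ones(d.nsnps, dtype=bool)
    while len(leads) < max_signals:
        if method == "cond":
            stats_now = d if not leads else conditional_summary(d, ld, leads)
            p = _pvalues(stats_now)
            ids_now = stats_now.snp_ids
            mask_now = np.ones(len(ids_now), dtype=bool)
        else:
            p = _pvalues(d)
            ids_now = d.snp_ids
            mask_now = eligible
        if not mask_now.any():
            break
        masked_p = np.where(mask_now, p, np.inf)
        j = int(np.argmin(masked_p))
        if masked_p[j] > p_threshold:
            break
        lead = str(ids_now[j])
        leads.append(lead)
        if method == "mask":
            eligible &= r2[index[lead]] < r2_threshold
    return SignalSet(
        lead_ids=tuple(leads),
        method=method,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        max_signals=max_signals,
    )


# ---------------------------------------------------------------------------
# masking of per-SNP Bayes factors
# ---------------------------------------------------------------------------

def mask_log_abf(labf, ld: LDMatrix, leads_to_mask, r2_threshold: float = 0.01):
    """Set log ABF to 0 (BF = 1) for SNPs in LD with any masked lead.

    Masked SNPs become uninformative for this trait: configurations
    involving them contribute exactly their prior weight.
    """
    labf = np.asarray(labf, dtype=float).copy()
    if labf.shape != (ld.nsnps,):
        raise ValueError("labf length must match the LD matrix")
    index = {s: i for i, s in enumerate(ld.snp_ids)}
    r2 = ld.r2()
    hit = np.zeros(ld.nsnps, dtype=bool)
    for lead in leads_to_mask:
        lead = str(lead)
        if lead not in index:
            raise KeyError(f"unknown lead SNP {lead!r}")
        hit |= r2[index[lead]] >= r2_threshold
    labf[hit] = 0.0
    return labf


# ---------------------------------------------------------------------------
# orchestration: n x m lead-pair colocalisations
# ---------------------------------------------------------------------------

def _signals_for(d, ld, mode, p_threshold, r2_threshold, max_signals):
    if mode == "single":
        top = str(d.snp_ids[int(np.argmin(_pvalues(d)))])
        return SignalSet((top,), "single", p_threshold, r2_threshold, max_signals)
    if ld is None:
        raise ValueError(f"mode '{mode}' requires an LD matrix")
    sig = stepwise_signals(d, ld, mode, p_threshold, r2_threshold, max_signals)
    if len(sig) == 0:
        # nothing reaches the threshold: fall back to the top SNP so a
        # single (null-ish) comparison is still reported
        top = str(d.snp_ids[int(np.argmin(_pvalues(d)))])
        return SignalSet((top,), "single", p_threshold, r2_threshold, max_signals)
    return sig


def _adjusted_data(d, ld, mode, other_leads, effect_prior, r2_threshold):
    """Per-lead (snp_ids, labf) after conditioning on / masking other leads."""
    if mode == "cond" and other_leads:
        dc = conditional_summary(d, ld, other_leads)
        return dc.snp_ids, region_log_abf(dc, effect_prior)
    labf = region_log_abf(d, effect_prior)
    if mode == "mask" and other_leads:
        labf = mask_log_abf(labf, ld, other_leads, r2_threshold=r2_threshold)
    return d.snp_ids, labf


def coloc_signals(
    d1: RegionSummary,
    d2: RegionSummary,
    ld1: LDMatrix | None = None,
    ld2: LDMatrix | None = None,
    mode1: str = "single",
    mode2: str = "single",
    priors: PriorParams | None = None,
    effect_prior: EffectPrior | None = None,
    p_threshold: float = 1e-6,
    r2_threshold: float = 0.01,
    max_signals: int = 3,
):
    """All pairwise lead-vs-lead colocalisations for two traits.

    Lead SNPs are discovered per trait according to its mode (``single``:
    one pseudo-lead, the top SNP; ``cond``/``mask``: stepwise).  For each
    lead pair, each trait's evidence is adjusted for *its other* leads —
    conditional summary statistics in ``cond`` mode, per-SNP Bayes factors
    set to 1 for SNPs in LD with the other leads in ``mask`` mode — and a
    standard colocalisation is run on the shared SNP set.  Returns a list of
    :class:`~coloctools.bayes.ColocResult`, one per lead pair, annotated
    with the two lead ids.
    """
    priors = priors or default_priors()
    effect_prior = effect_prior or EffectPrior()
    for mode in (mode1, mode2):
        if mode not in ("single", "cond", "mask"):
            raise ValueError("modes must be 'single', 'cond' or 'mask'")
    d1, d2, ld1, ld2 = harmonise(d1, d2, ld1, ld2)
    sig1 = _signals_for(d1, ld1, mode1, p_threshold, r2_threshold, max_signals)
    sig2 = _signals_for(d2, ld2, mode2, p_threshold, r2_threshold, max_signals)

    results = []
    for lead_a in sig1.lead_ids:
        others_a = [s for s in sig1.lead_ids if s != lead_a]
        ids_a, labf_a = _adjusted_data(
            d1, ld1, sig1.method, others_a, effect_prior, r2_threshold
        )
        for lead_b in sig2.lead_ids:
            others_b = [s for s in sig2.lead_ids if s != lead_b]
            ids_b, labf_b = _adjusted_data(
                d2, ld2, sig2.method, others_b, effect_prior, r2_threshold
            )
            shared = [s for s in ids_a if s in set(ids_b)]
            if not shared:
                continue
            ia = {s: i for i, s in enumerate(ids_a)}
            ib = {s: i for i, s in enumerate(ids_b)}
            la = np.array([labf_a[ia[s]] for s in shared])
            lb = np.array([labf_b[ib[s]] for s in shared])
            log_bf = hypothesis_log_bf(la, lb)
            res = coloc_posterior(
                log_bf,
                priors,
                nsnps=len(shared),
                per_snp_h4_vec=per_snp_h4(la, lb),
                snp_ids=np.asarray(shared, dtype=str),
            )
            res.lead1, res.lead2 = lead_a, lead_b
            res.extras["mode1"], res.extras["mode2"] = sig1.method, sig2.method
            results.append(res)
    return results


def label_comparison(
    lead1: str, lead2: str, causal_ids, ld: LDMatrix, r2_min: float = LABEL_R2
) -> ComparisonLabel:
    """Tag a lead pair with the simulated causal variants they track.

    Each lead is labelled with the causal variant of maximal r2, provided
    that r2 reaches ``r2_min`` (default 0.8); otherwise "?".
    """
    causal_ids = [str(s) for s in causal_ids]
    if not causal_ids:
        raise ValueError("truth set must be nonempty")
    index = {s: i for i, s in enumerate(ld.snp_ids)}
    for s in [str(lead1), str(lead2), *causal_ids]:
        if s not in index:
            raise KeyError(f"unknown SNP id {s!r}")
    r2 = ld.r2()

    def tag(lead):
        vals = [r2[index[lead], index[c]] for c in causal_ids]
        k = int(np.argmax(vals))
        return causal_ids[k] if vals[k] >= r2_min else "?"

    return ComparisonLabel(tag(str(lead1)), tag(str(lead2)))
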