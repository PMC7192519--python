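"""Haplotype-based simulation of regional GWAS summary statistics.

The generator emulates the ingredients of a regional association study: a
reference panel of binary haplotypes with block-structured LD, genotypes
drawn by sampling haplotype pairs with replacement, quantitative traits built
from one or two causal variants plus unit-variance Gaussian noise,

    Y = sum_i b_i G_i + e,   e ~ N(0, 1),

and marginal single-SNP OLS summary statistics (beta, varbeta) per SNP.
Ground truth (which hypothesis, which causal SNPs, what effects) is carried
alongside so that downstream inference can be scored.

Causal variants are drawn among common SNPs (MAF > 5%) and effect sizes from
a fixed set spanning 0.17-1.5 trait SDs per allele.  All randomness flows
from one seed; per-replicate streams are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import EffectPrior, coloc_abf
from .priors import PriorParams
from .sumstats import LDMatrix, RegionSummary

__all__ = [
    "EFFECT_SET",
    "HaplotypePanel",
    "SimTruth",
    "synth_haplotype_panel",
    "load_haplotype_panel",
    "sample_genotypes",
    "genotype_ld",
    "single_snp_regression",
    "draw_truth",
    "simulate_trait_pair",
    "expected_posterior_table",
]

#: effect sizes (trait units per allele dose) sampled for causal variants
EFFECT_SET = (0.17, 0.33, 0.50, 0.67, 0.83, 1.00, 1.17, 1.33, 1.50)

COMMON_MAF = 0.05


@dataclass
class HaplotypePanel:
    """Reference panel: binary haplotype x SNP matrix with SNP ids and MAF."""

    haplotypes: np.ndarray  # (n_hap, M) uint8 in {0, 1}
    snp_ids: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes)
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.snp_ids):
            raise ValueError("haplotypes must be (n_hap, M) matching snp_ids")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.haplotypes.shape[1] < 1:
            raise ValueError("panel must contain at least one SNP")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def nsnps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Allele-1 frequency per SNP (column mean)."""
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency (folded column mean)."""
        f = self.freq
        return np.minimum(f, 1.0 - f)

    def filter_maf(self, min_maf: float = COMMON_MAF) -> "HaplotypePanel":
        keep = self.maf >= min_maf
        return HaplotypePanel(self.haplotypes[:, keep], self.snp_ids[keep])

    def common_snps(self, min_maf: float = COMMON_MAF) -> np.ndarray:
        return self.snp_ids[self.maf >= min_maf]


@dataclass
class SimTruth:
    """Ground-truth causal configuration for one simulated trait pair."""

    hypothesis: str  # H0..H4 or "custom"
    causal1: tuple = ()
    causal2: tuple = ()
    beta1: tuple = ()
    beta2: tuple = ()

    def __post_init__(self):
        self.causal1 = tuple(str(s) for s in self.causal1)
        self.causal2 = tuple(str(s) for s in self.causal2)
        self.beta1 = tuple(float(b) for b in self.beta1)
        self.beta2 = tuple(float(b) for b in self.beta2)
        if len(self.causal1) != len(self.beta1) or len(self.causal2) != len(self.beta2):
            raise ValueError("causal ids and effects must pair up")
        if self.hypothesis == "H0" and (self.causal1 or self.causal2):
            raise ValueError("H0 truth must have no causal variants")
        if self.hypothesis == "H4" and set(self.causal1) != set(self.causal2):
            raise ValueError("H4 truth requires identical causal sets")

    @property
    def all_causals(self) -> tuple:
        seen, out = set(), []
        for s in self.causal1 + self.causal2:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return tuple(out)


def synth_haplotype_panel(
    n_hap: int = 1000,
    M: int = 250,
    block_size: int = 25,
    within_block_corr: float = 0.7,
    seed=None,
    maf_range: tuple = (0.02, 0.5),
) -> HaplotypePanel:
    """Synthetic reference panel with block-structured LD.

    SNP frequencies are drawn uniformly on ``maf_range``; within each block
    of ``block_size`` SNPs a shared latent Gaussian factor (weight
    sqrt(within_block_corr)) induces positive LD, and the latent values are
    thresholded at the normal quantile of each SNP's frequency.  Blocks are
    mutually independent, so between-block r2 is ~0.  Deterministic given
    ``seed``.
    """
    from scipy import stats

    if n_hap < 2 or M < 1 or block_size < 1:
        raise ValueError("n_hap, M and block_size must be positive")
    if not 0 <= within_block_corr < 1:
        raise ValueError("within_block_corr must lie in [0, 1)")
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=M)
    thresh = stats.norm.ppf(freqs)
    hap = np.empty((n_hap, M), dtype=np.uint8)
    rho = within_block_corr
    for start in range(0, M, block_size):
        stop = min(start + block_size, M)
        width = stop - start
        shared = rng.standard_normal((n_hap, 1))
        noise = rng.standard_normal((n_hap, width))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        hap[:, start:stop] = (z < thresh[start:stop]).astype(np.uint8)
    ids = np.array([f"snp{i:04d}" for i in range(M)])
    return HaplotypePanel(hap, ids)


def load_haplotype_panel(path) -> HaplotypePanel:
    """Read a plain 0/1 haplotype matrix; first line holds SNP ids."""
    df = pd.read_csv(path, sep=r"\s+")
    return HaplotypePanel(df.to_numpy(dtype=np.uint8), np.array(df.columns, dtype=str))


def sample_genotypes(panel: HaplotypePanel, N: int, seed=None) -> np.ndarray:
    """Draw N diploid genotypes (0/1/2) by sampling 2N haplotypes with replacement."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, panel.n_hap, size=2 * N)
    hap = panel.haplotypes
    return (hap[idx[:N]] + hap[idx[N:]]).astype(np.int8)


def genotype_ld(G: np.ndarray, snp_ids) -> LDMatrix:
    """Signed in-sample LD (Pearson r between genotype columns).

    Monomorphic columns get r = 0 off-diagonal (1 on the diagonal).
    """
    G = np.asarray(G, dtype=float)
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    ok = sd > 0
    denom = np.where(ok, sd, 1.0)
    Z = Gc / denom
    r = (Z.T @ Z) / G.shape[0]
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return LDMatrix(np.asarray(snp_ids, dtype=str), r)


def single_snp_regression(G: np.ndarray, Y: np.ndarray):
    """Marginal per-SNP OLS with intercept, vectorised over SNPs.

    Returns (beta, varbeta) with beta_j = Sxy_j/Sxx_j and varbeta_j =
    RSS_j / ((N-2) Sxx_j).
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N, M = G.shape
    if Y.shape != (N,):
        raise ValueError("Y must have one value per individual")
    if N < 3:
        raise ValueError("need at least 3 individuals")
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean()
    Sxx = np.einsum("ij,ij->j", Gc, Gc)
    if (Sxx <= 0).any():
        raise ValueError("monomorphic SNP (zero genotype variance)")
    Sxy = Gc.T @ Yc
    Syy = float(Yc @ Yc)
    beta = Sxy / Sxx
    rss = Syy - beta**2 * Sxx
    varbeta = rss / ((N - 2) * Sxx)
    return beta, varbeta


def draw_truth(
    panel: HaplotypePanel,
    hypothesis: str,
    rng,
    effect_set=EFFECT_SET,
    min_maf: float = COMMON_MAF,
    n_causal_h3: int = 1,
) -> SimTruth:
    """Random causal configuration under one of H0..H4.

    H1/H2: one causal variant for one trait; H3: ``n_causal_h3`` distinct
    variants per trait (default one each); H4: a single shared variant.
    Causal SNPs are drawn among common SNPs; effects uniformly from
    ``effect_set``.
    """
    rng = np.random.default_rng(rng)
    common = panel.common_snps(min_maf)
    if hypothesis != "H0" and len(common) < 2 * n_causal_h3:
        raise ValueError("not enough common SNPs in the panel")

    def pick(k):
        snps = rng.choice(common, size=k, replace=False)
        effs = rng.choice(effect_set, size=k)
        return tuple(snps), tuple(effs)

    if hypothesis == "H0":
        return SimTruth("H0")
    if hypothesis == "H1":
        c, b = pick(1)
        return SimTruth("H1", causal1=c, beta1=b)
    if hypothesis == "H2":
        c, b = pick(1)
        return SimTruth("H2", causal2=c, beta2=b)
    if hypothesis == "H3":
        c, b = pick(2 * n_causal_h3)
        return SimTruth(
            "H3",
            causal1=c[:n_causal_h3],
            beta1=b[:n_causal_h3],
            causal2=c[n_causal_h3:],
            beta2=b[n_causal_h3:],
        )
    if hypothesis == "H4":
        c, b = pick(1)
        return SimTruth("H4", causal1=c, beta1=b, causal2=c, beta2=b)
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def _trait(panel, N, causal, beta, rng):
    G = sample_genotypes(panel, N, rng)
    Y = rng.standard_normal(N)
    if causal:
        index = {s: i for i, s in enumerate(panel.snp_ids)}
        for s, b in zip(causal, beta):
            if panel.maf[index[s]] < COMMON_MAF:
                raise ValueError(f"causal SNP {s} is below the MAF filter")
            Y = Y + b * G[:, index[s]]
    return G, Y


def simulate_trait_pair(
    panel: HaplotypePanel,
    N1: int,
    N2: int,
    truth: SimTruth,
    seed=None,
    return_genotypes: bool = False,
):
    """Two independent GWAS of the same region, with ground truth.

    Each trait draws its own genotypes from the panel, builds
    Y = sum b_i G_i + e with e ~ N(0,1), and summarises every SNP by marginal
    OLS.  Returns ``(d1, d2, truth)`` as :class:`RegionSummary` objects
    (sample MAF, signed betas, observed trait SD recorded), or with
    ``return_genotypes=True`` additionally the raw ``(G1, Y1), (G2, Y2)``
    pairs for exact-regression cross-checks.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng1, rng2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    G1, Y1 = _trait(panel, N1, truth.causal1, truth.beta1, rng1)
    G2, Y2 = _trait(panel, N2, truth.causal2, truth.beta2, rng2)

    def summarise(G, Y, N):
        beta, varbeta = single_snp_regression(G, Y)
        f = G.mean(axis=0) / 2.0
        f = np.clip(f, 1e-6, 1 - 1e-6)
        return RegionSummary(
            snp_ids=panel.snp_ids,
            beta=beta,
            varbeta=varbeta,
            maf=np.minimum(f, 1 - f),
            trait_type="quant",
            n_samples=N,
            sd_trait=float(np.std(Y, ddof=1)),
        )

    d1 = summarise(G1, Y1, N1)
    d2 = summarise(G2, Y2, N2)
    if return_genotypes:
        return d1, d2, truth, (G1, Y1), (G2, Y2)
    return d1, d2, truth


def expected_posterior_table(
    scenarios,
    reps: int,
    priors_list,
    seed=None,
    panel: HaplotypePanel | None = None,
    effect_prior: EffectPrior | None = None,
    **panel_kwargs,
) -> pd.DataFrame:
    """Mean posterior per hypothesis across replicates, per scenario x prior.

    ``scenarios`` is an iterable of dicts with keys ``hypothesis`` and ``N``
    (optionally ``M``).  Each replicate draws a fresh truth and a fresh pair
    of GWAS from a shared panel, runs the single-signal colocalisation under
    every prior in ``priors_list`` (reusing the Bayes factors), and averages.
    """
    from .sensitivity import reweight_posteriors

    scenarios = list(scenarios)
    priors_list = list(priors_list)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for scen, scen_ss in zip(scenarios, root.spawn(len(scenarios))):
        hyp, N = scen["hypothesis"], int(scen["N"])
        pan = panel
        if pan is None:
            pan = synth_haplotype_panel(
                M=int(scen.get("M", 250)),
                seed=scen_ss.spawn(1)[0],
                **panel_kwargs,
            )
        acc = {id(pr): np.zeros(5) for pr in priors_list}
        for rep_ss in scen_ss.spawn(reps):
            s_truth, s_sim = rep_ss.spawn(2)
            truth = draw_truth(pan, hyp, np.random.default_rng(s_truth))
            d1, d2, _ = simulate_trait_pair(pan, N, N, truth, seed=s_sim)
            base = coloc_abf(d1, d2, priors_list[0], effect_prior)
            acc[id(priors_list[0])] += base.pp
            for pr in priors_list[1:]:
                acc[id(pr)] += reweight_posteriors(base, pr).pp
        for pr in priors_list:
            mean_pp = acc[id(pr)] / reps
            rows.append(
                {
                    "hypothesis": hyp,
                    "N": N,
                    "p1": pr.p1,
                    "p2": pr.p2,
                    "p12": pr.p12,
                    "reps": reps,
                    **{f"PP.H{i}": mean_pp[i] for i in range(5)},
                }
            )
    return pd.DataFrame(rows)
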