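"""Data model, validation and I/O for regional GWAS summary statistics.

A colocalisation analysis consumes, per genomic region and per trait, a set of
per-SNP summary statistics: an effect estimate ``beta`` (trait units per copy
of the effect allele) and its squared standard error ``varbeta``, or
alternatively a two-sided p-value plus minor allele frequency from which
unsigned effects can be reconstructed.  An optional signed LD correlation
matrix, aligned to the same SNP ids and effect alleles, is required only for
conditioning and masking.

SNP identity is by id string; positions are carried as annotation only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

QUANT = "quant"
CC = "cc"

#: p-values below this are floored before conversion to z (double underflow guard)
_P_FLOOR = 1e-300


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=str)


def _as_float_or_none(x):
    if x is None:
        return None
    return np.asarray(x, dtype=float)


@dataclass
class RegionSummary:
    """Per-SNP summary statistics for one trait in one region.

    Parameters
    ----------
    snp_ids
        Unique SNP identifiers, in region order.
    beta, varbeta
        Per-SNP effect estimates and their squared standard errors.  May be
        ``None`` if ``pvalues`` and ``maf`` are supplied instead (see
        :func:`reconstruct_effects`).
    pvalues
        Two-sided association p-values (alternative route to ``beta``/``varbeta``).
    maf
        Minor allele frequency in (0, 1).
    trait_type
        ``"quant"`` for a quantitative trait, ``"cc"`` for case-control.
    n_samples
        Total GWAS sample size.
    case_fraction
        Proportion of cases (case-control traits only).
    sd_trait
        Standard deviation of the quantitative trait (sdY).  May be estimated
        from the data via :func:`estimate_sd_trait` when absent.
    signed
        Whether ``beta`` carries its true sign.  Effects reconstructed from
        p-values are unsigned and are refused by summary-statistic
        conditioning, which needs signs aligned to the LD matrix.
    """

    snp_ids: np.ndarray
    beta: np.ndarray | None = None
    varbeta: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    maf: np.ndarray | None = None
    positions: np.ndarray | None = None
    trait_type: str = QUANT
    n_samples: int | None = None
    case_fraction: float | None = None
    sd_trait: float | None = None
    signed: bool = True

    def __post_init__(self):
        self.snp_ids = _as_str_array(self.snp_ids)
        for name in ("beta", "varbeta", "pvalues", "maf", "positions"):
            setattr(self, name, _as_float_or_none(getattr(self, name)))
        n = len(self.snp_ids)
        if n < 1:
            raise ValueError("RegionSummary requires at least one SNP")
        ids, counts = np.unique(self.snp_ids, return_counts=True)
        if (counts > 1).any():
            dup = ", ".join(ids[counts > 1][:5])
            raise ValueError(f"duplicate SNP ids: {dup}")
        for name in ("beta", "varbeta", "pvalues", "maf", "positions"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, expected {n}")
        has_effects = self.beta is not None and self.varbeta is not None
        has_pmaf = self.pvalues is not None and self.maf is not None
        if not (has_effects or has_pmaf):
            raise ValueError(
                "need either (beta, varbeta) or (pvalues, maf) for every SNP"
            )
        if self.varbeta is not None and not (self.varbeta > 0).all():
            bad = self.snp_ids[~(self.varbeta > 0)]
            raise ValueError(f"non-positive varbeta at: {', '.join(bad[:5])}")
        if self.maf is not None and not ((self.maf > 0) & (self.maf < 1)).all():
            bad = self.snp_ids[~((self.maf > 0) & (self.maf < 1))]
            raise ValueError(f"maf outside (0, 1) at: {', '.join(bad[:5])}")
        if self.pvalues is not None and not (
            (self.pvalues > 0) & (self.pvalues <= 1)
        ).all():
            raise ValueError("p-values must lie in (0, 1]")
        if self.trait_type not in (QUANT, CC):
            raise ValueError(f"trait_type must be '{QUANT}' or '{CC}'")
        if self.trait_type == CC and self.case_fraction is not None:
            if not 0 < self.case_fraction < 1:
                raise ValueError("case_fraction must lie in (0, 1)")

    # -- convenience -------------------------------------------------------

    @property
    def nsnps(self) -> int:
        return len(self.snp_ids)

    @property
    def needs_reconstruction(self) -> bool:
        """True when beta/varbeta must be rebuilt from p-values and MAF."""
        return self.beta is None or self.varbeta is None

    @property
    def z(self) -> np.ndarray:
        if self.needs_reconstruction:
            raise ValueError("no beta/varbeta; call reconstruct_effects first")
        return self.beta / np.sqrt(self.varbeta)

    def subset(self, ids: Sequence[str]) -> "RegionSummary":
        """Restrict to ``ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            take = np.array([index[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown SNP id {e.args[0]!r}") from None
        kw = {}
        for name in ("beta", "varbeta", "pvalues", "maf", "positions"):
            v = getattr(self, name)
            kw[name] = None if v is None else v[take]
        return replace(self, snp_ids=self.snp_ids[take], **kw)

    def to_frame(self) -> pd.DataFrame:
        cols = {"snp": self.snp_ids}
        for name in ("position", "beta", "varbeta", "pvalue", "maf"):
            attr = {"position": "positions", "pvalue": "pvalues"}.get(name, name)
            v = getattr(self, attr)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


@dataclass
class LDMatrix:
    """Signed SNP x SNP correlation matrix aligned to effect alleles.

    The sign convention is a contract with the caller: ``r[i, j]`` refers to
    the same effect alleles as the ``beta`` vectors it will be combined with.
    """

    snp_ids: np.ndarray
    r: np.ndarray
    _tol: float = field(default=1e-6, repr=False)

    def __post_init__(self):
        self.snp_ids = _as_str_array(self.snp_ids)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"r has shape {self.r.shape}, expected ({n}, {n})")
        if len(np.unique(self.snp_ids)) != n:
            raise ValueError("duplicate SNP ids in LD matrix")
        if not np.allclose(self.r, self.r.T, atol=self._tol):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=self._tol):
            raise ValueError("LD matrix diagonal must be 1")
        if np.abs(self.r).max() > 1 + self._tol:
            raise ValueError("LD correlations must satisfy |r| <= 1")

    @property
    def nsnps(self) -> int:
        return len(self.snp_ids)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            take = np.array([index[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown SNP id {e.args[0]!r}") from None
        return LDMatrix(self.snp_ids[take], self.r[np.ix_(take, take)])

    def r2(self) -> np.ndarray:
        return self.r**2


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_region_summary(
    path,
    *,
    n_samples: int | None = None,
    trait_type: str = QUANT,
    case_fraction: float | None = None,
    sd_trait: float | None = None,
) -> RegionSummary:
    """Read a whitespace/tab-delimited summary-statistic table.

    Recognised header columns: ``snp`` (required), ``position``, ``beta``,
    ``varbeta``, ``pvalue``, ``maf``.  Rows missing every usable statistic are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    if "snp" not in df.columns:
        raise ValueError(f"{path}: missing required column 'snp'")
    has_effects = {"beta", "varbeta"} <= set(df.columns)
    has_pmaf = {"pvalue", "maf"} <= set(df.columns)
    if not (has_effects or has_pmaf):
        raise ValueError(
            f"{path}: need columns (beta, varbeta) or (pvalue, maf)"
        )
    need = ["beta", "varbeta"] if has_effects else ["pvalue", "maf"]
    ok = df[need].notna().all(axis=1)
    if (~ok).any():
        logger.info("%s: dropped %d rows with missing %s", path, (~ok).sum(), need)
        df = df[ok]
    if len(df) == 0:
        raise ValueError(f"{path}: no complete rows")
    d = RegionSummary(
        snp_ids=df["snp"].to_numpy(),
        beta=df["beta"].to_numpy() if has_effects else None,
        varbeta=df["varbeta"].to_numpy() if has_effects else None,
        pvalues=df["pvalue"].to_numpy() if "pvalue" in df.columns else None,
        maf=df["maf"].to_numpy() if "maf" in df.columns else None,
        positions=df["position"].to_numpy() if "position" in df.columns else None,
        trait_type=trait_type,
        n_samples=n_samples,
        case_fraction=case_fraction,
        sd_trait=sd_trait,
    )
    if d.needs_reconstruction:
        logger.info("%s: p-value/MAF input, effects will be reconstructed", path)
    return d


def load_ld_matrix(path) -> LDMatrix:
    """Read a delimited square LD matrix whose first row/column are SNP ids."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if ids_row != ids_col:
        raise ValueError(f"{path}: row and column SNP ids differ")
    return LDMatrix(np.array(ids_row), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# effect reconstruction and harmonisation
# ---------------------------------------------------------------------------

def reconstruct_effects(d: RegionSummary) -> RegionSummary:
    """Rebuild unsigned (|beta|, varbeta) from p-values, MAF and design.

    For a quantitative trait with trait SD ``sdY``,

        varbeta = sdY^2 / (2 N f (1-f)),

    and for a case-control trait with case fraction ``s``,

        varbeta = 1 / (2 N f (1-f) s (1-s)).

    |beta| = z * sqrt(varbeta) with z the two-sided normal quantile of the
    p-value.  The result is flagged unsigned: it supports Bayes-factor
    computation but not conditioning.
    """
    if not d.needs_reconstruction:
        return d
    if d.pvalues is None or d.maf is None:
        raise ValueError("reconstruction requires pvalues and maf")
    if d.n_samples is None:
        raise ValueError("reconstruction requires n_samples")
    p = np.asarray(d.pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p < _P_FLOOR).any():
        warnings.warn(
            f"{(p < _P_FLOOR).sum()} p-values below {_P_FLOOR:g} floored "
            "before z conversion",
            stacklevel=2,
        )
        p = np.maximum(p, _P_FLOOR)
    f = d.maf
    if d.trait_type == QUANT:
        sdY = d.sd_trait
        if sdY is None:
            warnings.warn(
                "sd_trait not supplied for quantitative trait; assuming 1.0",
                stacklevel=2,
            )
            sdY = 1.0
        varbeta = sdY**2 / (2.0 * d.n_samples * f * (1.0 - f))
    else:
        s = d.case_fraction
        if s is None:
            raise ValueError("case_fraction required for case-control traits")
        varbeta = 1.0 / (2.0 * d.n_samples * f * (1.0 - f) * s * (1.0 - s))
    z = stats.norm.isf(p / 2.0)
    beta = z * np.sqrt(varbeta)
    return replace(d, beta=beta, varbeta=varbeta, signed=False)


def estimate_sd_trait(d: RegionSummary) -> float:
    """Estimate the quantitative-trait SD (sdY) from varbeta, MAF and N.

    Under the single-SNP OLS variance approximation varbeta ~= sdY^2 / (2 N
    f(1-f)), a regression through the origin of 1/varbeta on 2 N f(1-f) has
    slope 1/sdY^2; returns sqrt(1/slope).
    """
    if d.varbeta is None or d.maf is None or d.n_samples is None:
        raise ValueError("estimate_sd_trait requires varbeta, maf and n_samples")
    if d.nsnps < 2:
        raise ValueError("need at least 2 SNPs to estimate sd_trait")
    x = 2.0 * d.n_samples * d.maf * (1.0 - d.maf)
    y = 1.0 / d.varbeta
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0 or not np.isfinite(slope):
        raise ValueError(
            "could not estimate sd_trait (non-positive slope); "
            "please supply sd_trait explicitly"
        )
    return float(np.sqrt(1.0 / slope))


def harmonise(
    d1: RegionSummary,
    d2: RegionSummary,
    ld1: LDMatrix | None = None,
    ld2: LDMatrix | None = None,
):
    """Restrict all inputs to the shared SNP set, in a single common order.

    The common order is d1's order filtered to the intersection.  Returns
    ``(d1, d2, ld1, ld2)`` with the LD slots ``None`` where not supplied.
    """
    shared = set(d1.snp_ids) & set(d2.snp_ids)
    if ld1 is not None:
        shared &= set(ld1.snp_ids)
    if ld2 is not None:
        shared &= set(ld2.snp_ids)
    if not shared:
        raise ValueError("no SNP ids shared between inputs")
    order = [s for s in d1.snp_ids if s in shared]
    for name, obj in (("trait 1", d1), ("trait 2", d2), ("ld 1", ld1), ("ld 2", ld2)):
        if obj is not None and obj.nsnps != len(order):
            logger.info("harmonise: dropped %d SNPs from %s", obj.nsnps - len(order), name)
    return (
        d1.subset(order),
        d2.subset(order),
        None if ld1 is None else ld1.subset(order),
        None if ld2 is None else ld2.subset(order),
    )
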