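"""Posterior sensitivity to prior choice, without re-computing Bayes factors.

Because P(Hi | data, priors) is proportional to BF_i x P(Hi | priors), the
posterior under an alternative prior vector is obtained by reweighting:

    P(Hi | data, priors*) ∝ P(Hi | data, priors) x P(Hi | priors*) / P(Hi | priors).

The prior ratios are taken in the same ratio-to-H0 form used by the posterior
computation (H0 ratio = 1, and the region size cancels), so reweighting
agrees with full recomputation from the stored log Bayes factors to machine
precision.

A decision rule such as ``"H4 > 0.5"`` or ``"H4/(H3+H4) > 0.9"`` can be
scanned over a grid of p12 values to find the prior range over which a
conclusion holds.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .bayes import ColocResult
from .priors import PriorParams, hypothesis_priors

__all__ = [
    "reweight_posteriors",
    "evaluate_rule",
    "sensitivity_grid",
    "SensitivityTable",
    "plot_sensitivity",
]


def _prior_odds(p: PriorParams) -> np.ndarray:
    """Per-hypothesis prior weights relative to H0 with region size factored out."""
    return np.array([1.0, p.p1, p.p2, p.p1 * p.p2, p.p12])


def reweight_posteriors(result: ColocResult, new_priors: PriorParams) -> ColocResult:
    """Posteriors under ``new_priors`` from a completed analysis.

    Log Bayes factors are unchanged; only the prior weights move.  Raises if
    the new priors are infeasible at the result's region size (per-hypothesis
    priors would exceed 1).
    """
    hypothesis_priors(result.nsnps, new_priors)  # feasibility check
    ratio = _prior_odds(new_priors) / _prior_odds(result.priors_used)
    w = result.pp * ratio
    return dc_replace(result, pp=w / w.sum(), priors_used=new_priors)


# ---------------------------------------------------------------------------
# decision-rule mini-language
# ---------------------------------------------------------------------------

_ALLOWED_NAMES = {"H0": 0, "H1": 1, "H2": 2, "H3": 3, "H4": 4}
_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.divide,
}
_CMPOPS = {
    ast.Gt: np.greater,
    ast.GtE: np.greater_equal,
    ast.Lt: np.less,
    ast.LtE: np.less_equal,
    ast.Eq: np.equal,
    ast.NotEq: np.not_equal,
}


class RuleError(ValueError):
    """Malformed or out-of-grammar decision-rule expression."""


def _eval_node(node, pp):
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, pp)
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
            return float(node.value)
        raise RuleError(f"non-numeric literal at column {node.col_offset}")
    if isinstance(node, ast.Name):
        if node.id in _ALLOWED_NAMES:
            return pp[..., _ALLOWED_NAMES[node.id]]
        raise RuleError(
            f"unknown symbol {node.id!r} at column {node.col_offset} "
            "(allowed: H0..H4)"
        )
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return -_eval_node(node.operand, pp)
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](
            _eval_node(node.left, pp), _eval_node(node.right, pp)
        )
    if isinstance(node, ast.Compare):
        if len(node.ops) != 1:
            raise RuleError("chained comparisons are not supported")
        if type(node.ops[0]) not in _CMPOPS:
            raise RuleError(f"unsupported comparison at column {node.col_offset}")
        return _CMPOPS[type(node.ops[0])](
            _eval_node(node.left, pp), _eval_node(node.comparators[0], pp)
        )
    if isinstance(node, ast.BoolOp):
        vals = [_eval_node(v, pp) for v in node.values]
        op = np.logical_and if isinstance(node.op, ast.And) else np.logical_or
        out = vals[0]
        for v in vals[1:]:
            out = op(out, v)
        return out
    raise RuleError(
        f"unsupported syntax ({type(node).__name__}) at column "
        f"{getattr(node, 'col_offset', 0)}"
    )


def _compile_rule(rule: str):
    src = rule.replace("×", "*").replace("÷", "/")
    try:
        tree = ast.parse(src, mode="eval")
    except SyntaxError as e:
        raise RuleError(f"cannot parse rule at position {e.offset}: {e.msg}") from None
    return tree


def evaluate_rule(pp, rule: str):
    """Evaluate a decision-rule expression on a posterior vector.

    The grammar admits the symbols H0..H4, numeric literals, + - * / (and
    the typographic x and division signs), one comparison, and and/or.
    ``pp`` may be a length-5 vector or an (m, 5) array (vectorised verdicts).
    """
    pp = np.asarray(pp, dtype=float)
    if pp.shape[-1] != 5:
        raise ValueError("pp must have 5 entries (H0..H4) in its last axis")
    tree = _compile_rule(rule)
    out = _eval_node(tree, pp)
    out = np.asarray(out, dtype=bool)
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# p12 grid scan
# ---------------------------------------------------------------------------

@dataclass
class SensitivityTable:
    """Prior/posterior probabilities and rule verdicts along a p12 grid."""

    p12_grid: np.ndarray
    priors: pd.DataFrame      # per-hypothesis prior probabilities per grid point
    posteriors: pd.DataFrame  # per-hypothesis posterior probabilities per grid point
    verdicts: np.ndarray
    rule: str
    base_p12: float

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                pd.Series(self.p12_grid, name="p12"),
                self.priors.add_prefix("prior."),
                self.posteriors.add_prefix("PP."),
                pd.Series(self.verdicts, name="pass"),
            ],
            axis=1,
        )
        return out

    def passing_intervals(self) -> list[tuple[float, float]]:
        """Contiguous sub-intervals of the grid where the rule holds."""
        out = []
        v = self.verdicts
        start = None
        for i, ok in enumerate(v):
            if ok and start is None:
                start = i
            if not ok and start is not None:
                out.append((float(self.p12_grid[start]), float(self.p12_grid[i - 1])))
                start = None
        if start is not None:
            out.append((float(self.p12_grid[start]), float(self.p12_grid[-1])))
        return out


def sensitivity_grid(
    result: ColocResult,
    rule: str = "H4 > 0.5",
    p12_from: float = 1e-8,
    p12_to: float = 1e-4,
    n_grid: int = 100,
) -> SensitivityTable:
    """Scan a decision rule over a log-spaced grid of p12 values.

    p1 and p2 are held at the values used in the original analysis; only p12
    moves.  Grid points at which the per-hypothesis priors would be
    infeasible (or p12 >= min(q1, q2)) are excluded.
    """
    base = result.priors_used
    if p12_from <= 0 or p12_to <= p12_from:
        raise ValueError("need 0 < p12_from < p12_to")
    grid = np.logspace(np.log10(p12_from), np.log10(p12_to), n_grid)
    rows_prior, rows_post, keep = [], [], []
    for p12 in grid:
        try:
            np_priors = PriorParams(base.p1, base.p2, float(p12))
            hp = hypothesis_priors(result.nsnps, np_priors)
        except ValueError:
            continue
        keep.append(p12)
        rows_prior.append(hp.as_array())
        rows_post.append(reweight_posteriors(result, np_priors).pp)
    if not keep:
        raise ValueError("empty feasible p12 range for this region size")
    cols = ["H0", "H1", "H2", "H3", "H4"]
    priors_df = pd.DataFrame(rows_prior, columns=cols)
    post_df = pd.DataFrame(rows_post, columns=cols)
    verdicts = evaluate_rule(post_df.to_numpy(), rule)
    return SensitivityTable(
        p12_grid=np.asarray(keep),
        priors=priors_df,
        posteriors=post_df,
        verdicts=np.atleast_1d(verdicts),
        rule=rule,
        base_p12=base.p12,
    )


def plot_sensitivity(table: SensitivityTable, path=None):
    """Two-panel prior/posterior plot along the p12 grid.

    H0 is omitted from the prior panel so the relative movement of H1..H4 is
    visible.  Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    x = table.p12_grid
    for h in ["H1", "H2", "H3", "H4"]:
        axes[0].plot(x, table.priors[h], label=h)
    for h in ["H0", "H1", "H2", "H3", "H4"]:
        axes[1].plot(x, table.posteriors[h], label=h)
    for ax, title in zip(axes, ["prior", "posterior"]):
        ax.set_xscale("log")
        ax.set_xlabel("p12")
        ax.set_title(title)
        ax.axvline(table.base_p12, ls="--", c="grey")
        ax.legend(fontsize=7)
    axes[1].set_ylim(0, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
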