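"""Relating single-cell expression to TF activity.

Cells are binned by their peak TF level (or by the Msn2:Msn4 ratio) and each
bin is summarized by its mean expression and its responder fraction — the
proportion of cells whose expression exceeds a threshold derived from an
unstimulated control population. Empty bins are reported as missing, never
as zero, and every excluded cell is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class ResponderRule:
    """Expression threshold above which a cell counts as a responder."""

    threshold: float
    source: str = "absolute"


@dataclass
class BinnedRelationship:
    """Expression summaries per TF-level (or TF-ratio) bin."""

    tf: str
    bin_edges: np.ndarray
    bin_means: np.ndarray            # NaN for empty bins
    responder_fraction: np.ndarray   # NaN for empty bins or without a rule
    n_per_bin: np.ndarray
    tf_bin_means: np.ndarray         # mean TF level of the cells in each bin
    within_ss: np.ndarray | None = None  # within-bin sum of squares of expression
    n_excluded: int = 0
    stat: str = "endpoint"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        ws = self.within_ss if self.within_ss is not None else np.full(len(self.bin_means), np.nan)
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "tf_bin_mean": self.tf_bin_means,
                "mean_expression": self.bin_means,
                "responder_fraction": self.responder_fraction,
                "n": self.n_per_bin,
                "within_ss": ws,
            }
        )


def derive_responder_threshold(
    control_endpoints, quantile: float = 0.95, min_cells: int = 50
) -> ResponderRule:
    """Responder cut from an unstimulated control population.

    The threshold is the stated quantile (default 95th percentile) of the
    control endpoint-expression distribution.
    """
    x = np.asarray(control_endpoints, dtype=float)
    if x.size < min_cells:
        raise ValueError(
            f"control population too small: {x.size} cells < {min_cells}"
        )
    if not 0.0 <= quantile <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    thr = float(np.quantile(x, quantile))
    return ResponderRule(threshold=thr, source=f"control_quantile_{quantile:g}")


def _expression_column(stat: str) -> str:
    if stat not in ("endpoint", "max"):
        raise ValueError(f"stat must be 'endpoint' or 'max', got {stat!r}")
    return "expr_endpoint" if stat == "endpoint" else "expr_max"


def _binned(
    tf_values: np.ndarray,
    expr: np.ndarray,
    bin_edges: np.ndarray,
    responder_rule: Optional[ResponderRule],
    tf_name: str,
    stat: str,
    n_excluded_pre: int = 0,
) -> BinnedRelationship:
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    nb = len(edges) - 1
    idx = np.digitize(tf_values, edges) - 1
    # the last edge is inclusive (closed final bin)
    idx[np.isclose(tf_values, edges[-1])] = nb - 1
    inside = (idx >= 0) & (idx < nb)
    if not inside.any():
        raise ValueError("no cells fall inside the bin edges")
    means = np.full(nb, np.nan)
    fracs = np.full(nb, np.nan)
    tf_means = np.full(nb, np.nan)
    within = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    for i in range(nb):
        sel = inside & (idx == i)
        counts[i] = int(sel.sum())
        if counts[i]:
            means[i] = expr[sel].mean()
            tf_means[i] = tf_values[sel].mean()
            within[i] = float(np.sum((expr[sel] - means[i]) ** 2))
            if responder_rule is not None:
                fracs[i] = (expr[sel] > responder_rule.threshold).mean()
    return BinnedRelationship(
        tf=tf_name,
        bin_edges=edges,
        bin_means=means,
        responder_fraction=fracs,
        n_per_bin=counts,
        tf_bin_means=tf_means,
        within_ss=within,
        n_excluded=int((~inside).sum()) + n_excluded_pre,
        stat=stat,
    )


def default_bin_edges(values: np.ndarray, n_bins: int = 5, upper_quantile: float = 0.99):
    """Equal-width bins spanning [0, the stated upper percentile]."""
    hi = float(np.quantile(values, upper_quantile))
    if hi <= 0:
        raise ValueError("cannot build bins: upper percentile is not positive")
    return np.linspace(0.0, hi, n_bins + 1)


def bin_by_tf(
    features: pd.DataFrame,
    tf: str = "msn4",
    bin_edges: Optional[Sequence[float]] = None,
    n_bins: int = 5,
    responder_rule: Optional[ResponderRule] = None,
    stat: str = "endpoint",
) -> BinnedRelationship:
    """Bin cells by peak TF level; summarize expression per bin."""
    if tf not in ("msn2", "msn4"):
        raise ValueError(f"tf must be 'msn2' or 'msn4', got {tf!r}")
    x = features[f"peak_{tf}"].to_numpy(dtype=float)
    y = features[_expression_column(stat)].to_numpy(dtype=float)
    if bin_edges is None:
        bin_edges = default_bin_edges(x, n_bins)
    return _binned(x, y, np.asarray(bin_edges), responder_rule, tf, stat)


def ratio_relationship(
    features: pd.DataFrame,
    bin_edges: Optional[Sequence[float]] = None,
    n_bins: int = 5,
    responder_rule: Optional[ResponderRule] = None,
    stat: str = "endpoint",
) -> BinnedRelationship:
    """Bin cells by their peak Msn2 : peak Msn4 ratio.

    Cells without measurable Msn4 (ratio undefined) are excluded and counted.
    """
    m2 = features["peak_msn2"].to_numpy(dtype=float)
    m4 = features["peak_msn4"].to_numpy(dtype=float)
    y = features[_expression_column(stat)].to_numpy(dtype=float)
    defined = m4 > 0
    if not defined.any():
        raise ValueError("all Msn2:Msn4 ratios are undefined (no Msn4 signal)")
    ratio = m2[defined] / m4[defined]
    if bin_edges is None:
        bin_edges = default_bin_edges(ratio, n_bins)
    return _binned(
        ratio,
        y[defined],
        np.asarray(bin_edges),
        responder_rule,
        "ratio_msn2_over_msn4",
        stat,
        n_excluded_pre=int((~defined).sum()),
    )


def distribution_summary(
    features: pd.DataFrame,
    by: Sequence[str] = ("genotype",),
    stat: str = "endpoint",
) -> pd.DataFrame:
    """Per-group quantiles {5,25,50,75,95}%, mean and n of expression.

    The table is the numeric content of a violin-style summary plot.
    """
    col = _expression_column(stat)
    if len(features) == 0:
        raise ValueError("empty feature table")
    rows = []
    for keys, grp in features.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        x = grp[col].to_numpy(dtype=float)
        row = dict(zip(by, keys))
        row["n"] = len(x)
        row["mean"] = x.mean()
        for q in QUANTILES:
            row[f"q{int(q * 100)}"] = float(np.quantile(x, q))
        rows.append(row)
    return pd.DataFrame(rows)
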