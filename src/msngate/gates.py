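"""Logic-gate classification and switch-vs-rheostat regulator fits.

Two complementary readouts of combinatorial regulation:

* deletion analysis — comparing mean expression of WT, msn2Δ and msn4Δ
  populations classifies a promoter/input combination as an OR gate, an AND
  gate, or a single-factor requirement;
* single-cell binning — fitting a step (switch), a line (rheostat) or a
  constant to binned expression-vs-TF relationships distinguishes a
  low-threshold ON/OFF regulator from one that tunes expression gradually.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .analysis import BinnedRelationship, ResponderRule
from .features import expression_endpoint
from .simulate import ExperimentSet


class GateLabel(str, enum.Enum):
    OR = "OR"
    AND = "AND"
    MSN2_REQUIRED = "MSN2_REQUIRED"
    MSN4_REQUIRED = "MSN4_REQUIRED"
    NONE = "NONE"


class RegulatorMode(str, enum.Enum):
    SWITCH = "switch"
    RHEOSTAT = "rheostat"
    FLAT = "flat"


@dataclass(frozen=True)
class GateCall:
    label: GateLabel
    wt_mean: float
    msn2d_mean: float
    msn4d_mean: float
    frac_msn4_only: float  # msn2d mean / WT mean
    frac_msn2_only: float  # msn4d mean / WT mean
    low_cut: float = 0.25
    high_cut: float = 0.5


@dataclass
class RegulatorModeFit:
    mode: RegulatorMode
    theta_hat: Optional[float]          # switch threshold, normalized a.u.
    theta_pct_of_max: Optional[float]   # threshold as % of maximal mean TF level
    step_base: Optional[float]
    step_height: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    sse_flat: float
    sse_step: float
    sse_linear: float
    criterion: Dict[str, float] = field(default_factory=dict)


def classify_gate(
    wt_mean: float,
    msn2d_mean: float,
    msn4d_mean: float,
    low_cut: float = 0.25,
    high_cut: float = 0.5,
) -> GateCall:
    """Classify gate logic from deletion-strain population means.

    ``f2 = msn2d/WT`` measures what Msn4 alone achieves; ``f4 = msn4d/WT``
    what Msn2 alone achieves. Both factors individually sufficient
    (min >= high_cut) is an OR gate; both individually insufficient
    (max < low_cut) an AND gate; one sufficient while the other deletion
    abolishes expression is a single-factor requirement.
    """
    if min(wt_mean, msn2d_mean, msn4d_mean) < 0:
        raise ValueError("population means must be non-negative")
    if not 0 <= low_cut <= high_cut:
        raise ValueError("need 0 <= low_cut <= high_cut")
    if wt_mean == 0:
        return GateCall(GateLabel.NONE, wt_mean, msn2d_mean, msn4d_mean,
                        float("nan"), float("nan"), low_cut, high_cut)
    f2 = msn2d_mean / wt_mean
    f4 = msn4d_mean / wt_mean
    if min(f2, f4) >= high_cut:
        label = GateLabel.OR
    elif max(f2, f4) < low_cut:
        label = GateLabel.AND
    elif f2 < low_cut <= high_cut <= f4:
        label = GateLabel.MSN2_REQUIRED
    elif f4 < low_cut <= high_cut <= f2:
        label = GateLabel.MSN4_REQUIRED
    else:
        label = GateLabel.NONE
    return GateCall(label, wt_mean, msn2d_mean, msn4d_mean, f2, f4, low_cut, high_cut)


def _aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample corrected information criterion for least squares."""
    k = n_params + 1  # + residual variance
    a = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        a += 2 * k * (k + 1) / (n - k - 1)
    return float(a)


def fit_regulator_mode(binned: BinnedRelationship, min_bins: int = 4) -> RegulatorModeFit:
    """Select switch vs rheostat vs flat for a binned expression relationship.

    Candidate models for the per-bin mean expression: a constant; a step
    ``b + h*1{x >= theta}`` with the threshold at an interior bin boundary;
    and a line ``b + m*x`` in the bin centers. Each model is scored at the
    cell level: its residual sum of squares is the occupancy-weighted sum of
    squared bin-mean residuals plus the (model-independent) within-bin sum
    of squares, so the comparison is an honest small-sample information
    criterion over the cells retained in the bins. Ties go to the simpler
    model (flat, then switch, then rheostat). The threshold is reported both
    in normalized a.u. and as a percentage of the maximal per-bin mean TF
    level.
    """
    ok = ~np.isnan(binned.bin_means)
    n_bins = int(ok.sum())
    if n_bins < min_bins:
        raise ValueError(f"need >= {min_bins} populated bins, got {n_bins}")
    centers = binned.bin_centers[ok]
    y = binned.bin_means[ok]
    w = binned.n_per_bin[ok].astype(float)
    n_cells = float(w.sum())
    within = float(binned.within_ss[ok].sum()) if binned.within_ss is not None else 0.0

    # flat
    mean_flat = float(np.average(y, weights=w))
    sse_flat = float(np.sum(w * (y - mean_flat) ** 2))

    # step: thresholds at interior boundaries between populated bins
    all_idx = np.flatnonzero(ok)
    best = (np.inf, None, None, None)
    for j in range(1, n_bins):
        theta = float(binned.bin_edges[all_idx[j]])
        lo, hi = y[:j], y[j:]
        wl, wh = w[:j], w[j:]
        b = float(np.average(lo, weights=wl))
        h = float(np.average(hi, weights=wh)) - b
        sse = float(np.sum(wl * (lo - b) ** 2) + np.sum(wh * (hi - b - h) ** 2))
        if sse < best[0]:
            best = (sse, theta, b, h)
    sse_step, theta_hat, step_base, step_height = best

    # linear (weighted least squares)
    X = np.column_stack([np.ones(n_bins), centers])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    intercept, slope = (float(coef[0]), float(coef[1]))
    sse_linear = float(np.sum(w * (y - X @ coef) ** 2))

    n_eff = int(n_cells)
    crit = {
        "flat": _aicc(within + sse_flat, n_eff, 1),
        "switch": _aicc(within + sse_step, n_eff, 3),
        "rheostat": _aicc(within + sse_linear, n_eff, 2),
    }
    simplicity = {"flat": 0, "switch": 1, "rheostat": 2}  # simpler wins ties
    pick = min(crit, key=lambda m: (crit[m], simplicity[m]))
    mode = {"flat": RegulatorMode.FLAT, "switch": RegulatorMode.SWITCH,
            "rheostat": RegulatorMode.RHEOSTAT}[pick]

    theta_pct = None
    if theta_hat is not None:
        max_tf = np.nanmax(binned.tf_bin_means)
        theta_pct = 100.0 * theta_hat / max_tf if max_tf > 0 else float("nan")
    return RegulatorModeFit(
        mode=mode,
        theta_hat=theta_hat,
        theta_pct_of_max=theta_pct,
        step_base=step_base,
        step_height=step_height,
        slope=slope,
        intercept=intercept,
        sse_flat=sse_flat,
        sse_step=sse_step,
        sse_linear=sse_linear,
        criterion=crit,
    )


def reporter_half_rise_delay(
    experiment: ExperimentSet,
    responder_rule: Optional[ResponderRule] = None,
) -> float:
    """Median activation delay of the reporter across responding cells.

    Per cell: the linearly interpolated time at which the reporter first
    crosses half of its final level, minus stimulus onset and minus the
    maturation delay (both known from the experiment's configuration).
    Cells that never respond (endpoint at or below the responder threshold)
    are excluded; with no responders the delay is undefined.
    """
    cfg = experiment.config
    if cfg is None:
        raise ValueError("experiment lacks a configuration (onset/maturation unknown)")
    onset = cfg.stimulus.onset_min
    maturation = cfg.promoter.maturation_delay_min
    if responder_rule is not None:
        thr = responder_rule.threshold
    else:
        # fallback: 5% of the largest endpoint in the experiment
        thr = 0.05 * max(expression_endpoint(tr.reporter) for tr in experiment.traces)
    delays = []
    for tr in experiment.traces:
        final = expression_endpoint(tr.reporter)
        if final <= thr:
            continue
        half = final / 2.0
        above = tr.reporter >= half
        idx = np.nonzero(above)[0]
        if len(idx) == 0:
            continue
        i = int(idx[0])
        if i == 0:
            t_half = float(tr.time_min[0])
        else:
            r0, r1 = tr.reporter[i - 1], tr.reporter[i]
            f = (half - r0) / (r1 - r0)
            t_half = float(tr.time_min[i - 1] + f * (tr.time_min[i] - tr.time_min[i - 1]))
        delays.append(t_half - onset - maturation)
    if not delays:
        raise ValueError("no responding cells: activation delay undefined")
    return float(np.median(delays))


def estimate_kinetic_ratio(
    fast_experiment: ExperimentSet,
    slow_experiment: ExperimentSet,
    responder_rule: Optional[ResponderRule] = None,
) -> float:
    """Ratio of slow-to-fast promoter activation timescales.

    Both experiments must share the stimulus program; the per-class
    activation timescale is the median reporter half-of-final-rise delay
    (see :func:`reporter_half_rise_delay`).
    """
    cf, cs = fast_experiment.config, slow_experiment.config
    if cf is not None and cs is not None and cf.stimulus != cs.stimulus:
        raise ValueError("experiments must share the stimulus program")
    t_fast = reporter_half_rise_delay(fast_experiment, responder_rule)
    t_slow = reporter_half_rise_delay(slow_experiment, responder_rule)
    if t_fast <= 0:
        raise ValueError(f"fast-class activation delay is not positive ({t_fast:.3g} min)")
    return t_slow / t_fast


def gate_from_experiments(
    experiments: Mapping[str, ExperimentSet],
    low_cut: float = 0.25,
    high_cut: float = 0.5,
) -> GateCall:
    """Classify gate logic from a genotype -> experiment mapping."""
    needed = ("WT", "msn2d", "msn4d")
    missing = [g for g in needed if g not in experiments]
    if missing:
        raise KeyError(f"missing genotypes for gate classification: {missing}")
    means = {
        g: float(np.mean([expression_endpoint(tr.reporter) for tr in experiments[g].traces]))
        for g in needed
    }
    # measurement noise can push an uninduced population mean slightly below 0
    means = {g: max(0.0, m) for g, m in means.items()}
    return classify_gate(means["WT"], means["msn2d"], means["msn4d"], low_cut, high_cut)


def gate_vs_duration(
    experiments_by_duration: Mapping[float, Mapping[str, ExperimentSet]],
    low_cut: float = 0.25,
    high_cut: float = 0.5,
) -> pd.DataFrame:
    """Gate call per input duration (the duration-dependent logic table)."""
    rows = []
    for duration in sorted(experiments_by_duration):
        call = gate_from_experiments(experiments_by_duration[duration], low_cut, high_cut)
        rows.append(
            {
                "duration_min": duration,
                "label": call.label.value,
                "wt_mean": call.wt_mean,
                "msn2d_mean": call.msn2d_mean,
                "msn4d_mean": call.msn4d_mean,
                "frac_msn4_only": call.frac_msn4_only,
                "frac_msn2_only": call.frac_msn2_only,
            }
        )
    return pd.DataFrame(rows)
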