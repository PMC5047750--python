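"""Per-cell and per-ensemble summary statistics of single-cell time traces.

Conventions follow common practice for chemically induced TF-translocation
experiments: the peak is the maximal sample in the first 30 min after
stimulus onset, the AUC is the plain sum of in-window samples on the 2-min
grid (no trapezoid weighting), translocation speed is the linearly
interpolated time to half-maximum, and expression is read out as the last
sample of the reporter trace (which coincides with its maximum once the
reporter has plateaued).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .simulate import ExperimentSet


@dataclass(frozen=True)
class ChannelScaling:
    """Multiplicative factor mapping channel-A fluorescence onto channel B."""

    factor: float
    source: str = ""

    def apply(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) * self.factor

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) / self.factor


@dataclass
class EnsembleStats:
    mean_trace: np.ndarray
    sd_trace: np.ndarray
    cv_at_peak: float
    sd_at_peak: float
    peak_time_of_mean: float
    scale_mode: str = "normalized_au"


def compute_scaling_factor(
    ensemble_a: np.ndarray, ensemble_b: np.ndarray, source: str = ""
) -> ChannelScaling:
    """Cross-channel scaling factor from paired calibration ensembles.

    Both ensembles (cells x time, same grid) carry the same tagged protein
    imaged in two channels; the factor is the ratio of the maxima of the two
    averaged traces, max(mean B) / max(mean A), and multiplies channel-A
    values onto the channel-B scale.
    """
    a = np.atleast_2d(np.asarray(ensemble_a, dtype=float))
    b = np.atleast_2d(np.asarray(ensemble_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"calibration ensembles are on different grids: {a.shape[1]} vs {b.shape[1]} samples"
        )
    max_a = a.mean(axis=0).max()
    max_b = b.mean(axis=0).max()
    if max_a <= 0 or max_b <= 0:
        raise ValueError("averaged calibration traces must have positive maxima")
    return ChannelScaling(factor=max_b / max_a, source=source)


def _window_mask(time_min: np.ndarray, window_min: Tuple[float, float]) -> np.ndarray:
    lo, hi = window_min
    mask = (time_min >= lo - 1e-9) & (time_min <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_min} contains no samples")
    return mask


def peak_level(values, time_min, window_min: Tuple[float, float]) -> float:
    """Maximal sample value within the closed window."""
    values = np.asarray(values, dtype=float)
    mask = _window_mask(np.asarray(time_min, dtype=float), window_min)
    return float(values[mask].max())


def auc(values, time_min, window_min: Tuple[float, float]) -> float:
    """Sum of in-window samples (the 2-min-grid integration convention)."""
    values = np.asarray(values, dtype=float)
    mask = _window_mask(np.asarray(time_min, dtype=float), window_min)
    return float(values[mask].sum())


def _first_crossing(time_min, values, level, rising: bool) -> Optional[float]:
    """Earliest linearly interpolated crossing of ``level``; None if absent."""
    v = values - level
    if not rising:
        v = -v
    if v[0] >= 0:
        return float(time_min[0])
    above = v >= 0
    idx = np.nonzero(above)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    t0, t1 = time_min[i - 1], time_min[i]
    f = -v[i - 1] / (v[i] - v[i - 1])
    return float(t0 + f * (t1 - t0))


def half_max_times(
    values,
    time_min,
    onset_min: float = 0.0,
    offset_min: Optional[float] = None,
) -> Tuple[float, float]:
    """Times to reach (import) and fall back to (export) half-maximum.

    Import: first crossing of half the post-onset maximum, linearly
    interpolated between samples. Export: first crossing below half-max
    after input removal; NaN when the input is never removed (sustained
    stimulation) or the trace does not fall below half-max within the record.
    """
    values = np.asarray(values, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    post = time_min >= onset_min - 1e-9
    vmax = values[post].max()
    if vmax <= 0:
        raise ValueError("trace has no positive maximum after onset")
    half = vmax / 2.0
    t_import = _first_crossing(time_min[post], values[post], half, rising=True)
    if t_import is None:  # cannot happen: max >= half
        raise ValueError("no import half-max crossing found")
    if offset_min is None:
        return t_import, float("nan")
    after = time_min >= offset_min - 1e-9
    t_export = _first_crossing(time_min[after], values[after], half, rising=False)
    return t_import, (float("nan") if t_export is None else t_export)


def expression_endpoint(values) -> float:
    """Last sample of a reporter trace."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty reporter trace")
    return float(values[-1])


def expression_max(values) -> float:
    """Maximal sample of a reporter trace (the plateau readout)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty reporter trace")
    return float(values.max())


def ensemble_stats(
    traces: np.ndarray,
    time_min: np.ndarray,
    scale_mode: str = "normalized_au",
) -> EnsembleStats:
    """Mean trace, per-timepoint sample SD (n-1) and CV at the mean's peak.

    ``scale_mode="percent_of_mean_peak"`` rescales mean and SD by the peak
    of the mean trace (the "% max of mean" presentation); the CV is
    unaffected by this choice.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("ensemble_stats needs at least 2 traces on a shared grid")
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0, ddof=1)
    ipk = int(np.argmax(mean))
    sd_at_peak = float(sd[ipk])
    mean_at_peak = float(mean[ipk])
    cv = sd_at_peak / mean_at_peak if mean_at_peak != 0 else float("nan")
    if scale_mode == "percent_of_mean_peak":
        peak = mean.max()
        mean = 100.0 * mean / peak
        sd = 100.0 * sd / peak
        sd_at_peak = float(sd[ipk])
    elif scale_mode != "normalized_au":
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    return EnsembleStats(
        mean_trace=mean,
        sd_trace=sd,
        cv_at_peak=float(cv),
        sd_at_peak=sd_at_peak,
        peak_time_of_mean=float(np.asarray(time_min)[ipk]),
        scale_mode=scale_mode,
    )


def extract_features(
    experiment: ExperimentSet,
    window_min: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Per-cell scalar features for a whole experiment.

    The peak/AUC window defaults to the first 30 min after stimulus onset.
    Half-max times are NaN for channels that never rise (deleted TFs).
    """
    cfg = experiment.config
    if window_min is None:
        onset = cfg.stimulus.onset_min if cfg is not None else 0.0
        window_min = (onset, onset + 30.0)
    onset = window_min[0]
    offset = cfg.stimulus.offset_min if cfg is not None else None

    rows = []
    for tr in experiment.traces:
        row = {"cell_id": tr.cell_id, "genotype": tr.genotype.value}
        for name, vals in (("msn2", tr.msn2_nuc), ("msn4", tr.msn4_nuc)):
            row[f"peak_{name}"] = peak_level(vals, tr.time_min, window_min)
            row[f"auc_{name}"] = auc(vals, tr.time_min, window_min)
            try:
                ti, te = half_max_times(vals, tr.time_min, onset, offset)
            except ValueError:
                ti, te = float("nan"), float("nan")
            row[f"t_half_import_{name}"] = ti
            row[f"t_half_export_{name}"] = te
        row["expr_endpoint"] = expression_endpoint(tr.reporter)
        row["expr_max"] = expression_max(tr.reporter)
        row["capacity"] = tr.capacity
        rows.append(row)
    return pd.DataFrame(rows)
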