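"""Seeded end-to-end recovery benchmarks.

Each function runs the full generator + analysis chain and recovers one of
the quantities the model is anchored to: the cross-channel calibration
factor, the slow:fast promoter activation-timescale ratio, the Msn2:Msn4
mean peak-level ratio, and the Msn2 switch threshold as a percentage of
its maximal nuclear level. They are used both by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import bin_by_tf
from .features import compute_scaling_factor, extract_features, peak_level
from .gates import RegulatorModeFit, estimate_kinetic_ratio, fit_regulator_mode
from .params import ExperimentConfig, PromoterParams, StimulusProgram, TFParams
from .simulate import generate_experiment, sample_tf_traces


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds derived from one base seed (all < 2**31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def scaling_factor_calibration(n_cells: int = 100) -> float:
    """Cross-channel scaling factor from a paired calibration experiment.

    Two noiseless ensembles of identical sustained-translocation shape are
    imaged on two channels whose averaged-trace maxima stand in the ratio
    152:100; the recovered factor maps channel A onto channel B.
    """
    stim = StimulusProgram(kind="sustained")
    t = stim.time_grid()
    shape = 1.0 - np.exp(-np.clip(t - stim.onset_min, 0.0, None) / 2.0)
    ensemble_a = np.tile(100.0 * shape, (n_cells, 1))
    ensemble_b = np.tile(152.0 * shape, (n_cells, 1))
    return compute_scaling_factor(ensemble_a, ensemble_b, source="paired calibration").factor


def kinetic_ratio_recovery(seed: int, n_cells: int = 200) -> float:
    """Slow:fast activation-timescale ratio from reporter half-rise delays.

    WT ensembles under a saturating 60-min pulse are simulated for the
    default fast and slow promoter parameterizations; the per-class
    activation timescale is the median reporter half-of-final-rise delay
    (onset and maturation delay subtracted).
    """
    s_fast, s_slow = child_seeds(seed, 2)
    stim = StimulusProgram(duration_min=60.0, dose=1.0)
    fast = generate_experiment(
        ExperimentConfig(n_cells=n_cells, seed=s_fast,
                         promoter=PromoterParams.fast(), stimulus=stim)
    )
    slow = generate_experiment(
        ExperimentConfig(n_cells=n_cells, seed=s_slow,
                         promoter=PromoterParams.slow(), stimulus=stim)
    )
    return estimate_kinetic_ratio(fast, slow)


def amplitude_ratio_recovery(seed: int, n_cells: int = 2000) -> float:
    """Mean peak nuclear Msn2 over mean peak nuclear Msn4 in WT cells.

    Peaks are the maximal samples within the first 30 min after onset of a
    30-min pulse, on the noisy recorded channels.
    """
    tf = TFParams()
    stim = StimulusProgram(duration_min=30.0)
    ens = sample_tf_traces(tf, stim, "WT", n_cells, seed=child_seeds(seed, 1)[0])
    window = (stim.onset_min, stim.onset_min + 30.0)
    pk2 = np.array([peak_level(v, ens.time_min, window) for v in ens.msn2_nuc])
    pk4 = np.array([peak_level(v, ens.time_min, window) for v in ens.msn4_nuc])
    return float(pk2.mean() / pk4.mean())


def switch_threshold_recovery(
    seed: int,
    n_cells_total: int = 2000,
    doses: tuple = (0.1, 0.25, 0.5, 0.75, 1.0),
    n_bins: int = 5,
) -> RegulatorModeFit:
    """Msn2 switch threshold from binned slow-promoter expression.

    WT slow-promoter responses to 30-min pulses are pooled across doses to
    cover the full dynamic range of Msn2 levels, binned by peak Msn2
    (equal-width bins), and fit with the step/line/flat model family. The
    returned fit carries the threshold both in normalized a.u. and as a
    percentage of the maximal per-bin mean Msn2 level.
    """
    seeds = child_seeds(seed, len(doses))
    n_per = n_cells_total // len(doses)
    frames = []
    for s, dose in zip(seeds, doses):
        es = generate_experiment(
            ExperimentConfig(
                n_cells=n_per, seed=s, promoter=PromoterParams.slow(),
                stimulus=StimulusProgram(duration_min=30.0, dose=dose),
            )
        )
        frames.append(extract_features(es))
    pooled = pd.concat(frames, ignore_index=True)
    binned = bin_by_tf(pooled, tf="msn2", n_bins=n_bins)
    return fit_regulator_mode(binned)
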