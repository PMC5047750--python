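"""Generative model of single-cell TF translocation and reporter expression.

The generator separates three layers:

1. *TF dynamics* — per-cell nuclear Msn2/Msn4 traces with first-order
   import/export kinetics toward a cell-specific, log-normally distributed
   amplitude. Msn4 lags Msn2 by a short fixed delay and sits ~3-fold lower
   on the normalized scale with larger relative heterogeneity.
2. *Promoter activation* — a deterministic chromatin-opening chain driven by
   the TF traces (see :func:`simulate_promoter`), followed by transcription
   under shared-site competition and accumulation of a stable reporter with
   a fixed maturation delay.
3. *Measurement* — additive Gaussian noise on every recorded channel.

Deletion genotypes are simulated by zeroing the corresponding TF channel
*after* all random draws, so that a WT run and a deletion run under the
same seed agree exactly on the remaining channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    ExperimentConfig,
    Genotype,
    KineticsClass,
    PromoterParams,
    StimulusKind,
    StimulusProgram,
    TFParams,
)

SCHEMA_VERSION = "1"

#: integration step (min) of the production integrator
DEFAULT_DT = 0.05


@dataclass
class CellTrace:
    """One cell's sampled time series plus metadata."""

    cell_id: str
    genotype: Genotype
    time_min: np.ndarray
    msn2_nuc: np.ndarray
    msn4_nuc: np.ndarray
    reporter: np.ndarray
    capacity: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.time_min)
        for name in ("msn2_nuc", "msn4_nuc", "reporter"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"{name} of cell {self.cell_id} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )


@dataclass
class TFEnsemble:
    """TF traces of an ensemble of cells on a shared grid (cells x time)."""

    time_min: np.ndarray
    msn2_nuc: np.ndarray
    msn4_nuc: np.ndarray
    capacity: np.ndarray

    def __iter__(self):
        for i in range(self.msn2_nuc.shape[0]):
            yield self.msn2_nuc[i], self.msn4_nuc[i], self.capacity[i]


@dataclass
class ExperimentSet:
    """A simulated (or loaded) experiment: traces plus full metadata."""

    traces: List[CellTrace]
    config: Optional[ExperimentConfig] = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def time_min(self) -> np.ndarray:
        return self.traces[0].time_min

    def channel_matrix(self, channel: str) -> np.ndarray:
        key = {"msn2": "msn2_nuc", "msn4": "msn4_nuc", "reporter": "reporter"}[channel]
        return np.vstack([getattr(tr, key) for tr in self.traces])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: cell_id, genotype, promoter, stimulus, time_min, channel, value."""
        promoter = self.metadata.get("promoter", "")
        stimulus = self.metadata.get("stimulus", "")
        frames = []
        for tr in self.traces:
            for channel, values in (
                ("msn2", tr.msn2_nuc),
                ("msn4", tr.msn4_nuc),
                ("reporter", tr.reporter),
            ):
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_id": tr.cell_id,
                            "genotype": tr.genotype.value,
                            "promoter": promoter,
                            "stimulus": stimulus,
                            "time_min": tr.time_min,
                            "channel": channel,
                            "value": values,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _shape_on_grid(
    t: np.ndarray, stim: StimulusProgram, tau_import: float, tau_export: float, lag: float
) -> np.ndarray:
    """Unit-amplitude nuclear-localization shape for one TF on grid ``t``."""
    t0 = stim.onset_min + lag
    s = np.zeros_like(t, dtype=float)
    rising = t >= t0
    if stim.kind is StimulusKind.PULSE:
        toff = stim.onset_min + stim.duration_min
        on = rising & (t < toff)
        s[on] = 1.0 - np.exp(-(t[on] - t0) / tau_import)
        if toff > t0:
            level_off = 1.0 - np.exp(-(toff - t0) / tau_import)
            after = t >= toff
            s[after] = level_off * np.exp(-(t[after] - toff) / tau_export)
    elif stim.kind is StimulusKind.SUSTAINED:
        s[rising] = 1.0 - np.exp(-(t[rising] - t0) / tau_import)
    else:  # adaptive_transient: sustained stress, adapting response
        u = t[rising] - t0
        raw = (1.0 - np.exp(-u / tau_import)) * np.exp(-u / stim.adaptation_tau_min)
        # normalize so the cell-specific amplitude is the peak level
        tpk = tau_import * np.log1p(stim.adaptation_tau_min / tau_import)
        peak = (1.0 - np.exp(-tpk / tau_import)) * np.exp(-tpk / stim.adaptation_tau_min)
        s[rising] = raw / peak
    return s


def _draw_amplitudes(mean: float, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal draws parameterized by arithmetic mean and CV."""
    s2 = np.log1p(cv**2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size=n)


def _tf_dynamics(
    tf: TFParams, stim: StimulusProgram, n_cells: int, rng: np.random.Generator
):
    """Noiseless TF traces and capacities; draws are genotype-independent."""
    t = stim.time_grid()
    amp2 = _draw_amplitudes(tf.mean_amp_msn2, tf.cv_amp_msn2, n_cells, rng)
    amp4 = _draw_amplitudes(tf.mean_amp_msn4, tf.cv_amp_msn4, n_cells, rng)
    shape2 = _shape_on_grid(t, stim, tf.tau_import_min, tf.tau_export_min, 0.0)
    shape4 = _shape_on_grid(t, stim, tf.tau_import_min, tf.tau_export_min, tf.lag_msn4_min)
    msn2 = (stim.dose * amp2)[:, None] * shape2[None, :]
    msn4 = (tf.msn4_dose_scale(stim.dose) * amp4)[:, None] * shape4[None, :]
    if stim.kind is StimulusKind.SUSTAINED:
        capacity = rng.beta(tf.capacity_beta_a, tf.capacity_beta_b, size=n_cells)
    else:
        capacity = np.ones(n_cells)
    return t, msn2, msn4, capacity


def sample_tf_traces(
    tf: TFParams,
    stim: StimulusProgram,
    genotype: Genotype | str = Genotype.WT,
    n_cells: int = 1,
    seed: int | None = None,
    measurement_noise: bool = True,
) -> TFEnsemble:
    """Draw an ensemble of single-cell TF translocation traces.

    Deleted channels are identically zero; measurement noise (if enabled) is
    drawn for every channel regardless of genotype so that ensembles with
    the same seed differ only in the zeroed channel.
    """
    genotype = Genotype(genotype)
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    t, msn2, msn4, capacity = _tf_dynamics(tf, stim, n_cells, rng)
    if measurement_noise and tf.meas_noise_sd > 0:
        msn2 = msn2 + rng.normal(0.0, tf.meas_noise_sd, msn2.shape)
        msn4 = msn4 + rng.normal(0.0, tf.meas_noise_sd, msn4.shape)
    if not genotype.has_msn2:
        msn2 = np.zeros_like(msn2)
    if not genotype.has_msn4:
        msn4 = np.zeros_like(msn4)
    return TFEnsemble(time_min=t, msn2_nuc=msn2, msn4_nuc=msn4, capacity=capacity)


def _interp_fine(x: np.ndarray, n_sub: int) -> np.ndarray:
    """Piecewise-linear refinement of (cells, T) onto a grid n_sub x finer."""
    cells, nt = x.shape
    frac = np.arange(n_sub) / n_sub
    left = x[:, :-1, None]
    right = x[:, 1:, None]
    fine = left + (right - left) * frac[None, None, :]
    fine = fine.reshape(cells, (nt - 1) * n_sub)
    return np.concatenate([fine, x[:, -1:]], axis=1)


def simulate_promoter(
    msn2_nuc: np.ndarray,
    msn4_nuc: np.ndarray,
    capacity: np.ndarray | float,
    prom: PromoterParams,
    time_min: np.ndarray,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Deterministically integrate promoter opening and reporter accumulation.

    Accepts traces of shape (T,) for a single cell or (cells, T); returns the
    reporter on the same sample grid, shifted by the maturation delay.

    The chromatin state is a chain S0 -> S1 -> ... -> Sn; each forward step
    proceeds at ``k_open`` while the activation gate is on (slow class:
    nuclear Msn2 above ``theta_msn2``, rate additionally scaled by Msn4
    occupancy; fast class: combined TF level above ``basal_occ``), and
    reverses at ``k_close``. Transcription from the open state S_n runs at
    ``beta_max * (w2*msn2 + w4*msn4) / (K_occ + msn2 + msn4)``, scaled by the
    cell's translational capacity, and saturates softly as the accumulated
    reporter approaches ``expr_sat``.
    """
    single = np.asarray(msn2_nuc).ndim == 1
    m2 = np.atleast_2d(np.asarray(msn2_nuc, dtype=float))
    m4 = np.atleast_2d(np.asarray(msn4_nuc, dtype=float))
    t = np.asarray(time_min, dtype=float)
    if m2.shape != m4.shape or m2.shape[1] != len(t):
        raise ValueError(
            f"trace shapes do not match the grid: msn2 {m2.shape}, "
            f"msn4 {m4.shape}, grid length {len(t)}"
        )
    cap = np.broadcast_to(np.asarray(capacity, dtype=float), (m2.shape[0],))

    interval = t[1] - t[0]
    n_sub = max(1, int(round(interval / dt)))
    dt = interval / n_sub
    m2f = _interp_fine(m2, n_sub)
    m4f = _interp_fine(m4, n_sub)

    phi = (prom.w_msn2 * m2f + prom.w_msn4 * m4f) / (prom.K_occ + m2f + m4f)
    if prom.kinetics_class is KineticsClass.SLOW:
        gate = (m2f >= prom.theta_msn2).astype(float)
        accel = prom.msn4_open_floor + (1.0 - prom.msn4_open_floor) * m4f / (
            prom.msn4_open_K + m4f
        )
        k_on = prom.k_open_per_min * gate * accel
    else:
        gate = ((m2f + m4f) > prom.basal_occ).astype(float)
        k_on = prom.k_open_per_min * gate

    n_cells, n_fine = m2f.shape
    n_states = prom.n_open_steps + 1
    S = np.zeros((n_cells, n_states))
    S[:, 0] = 1.0
    R = np.zeros(n_cells)
    R_fine = np.empty((n_cells, n_fine))
    kc = prom.k_close_per_min
    rate_scale = cap * prom.beta_max
    for i in range(n_fine):
        R_fine[:, i] = R
        k = k_on[:, i][:, None]
        forward = k * S[:, :-1]
        backward = kc * S[:, 1:]
        dS = np.zeros_like(S)
        dS[:, :-1] -= forward
        dS[:, 1:] += forward
        dS[:, 1:] -= backward
        dS[:, :-1] += backward
        S = S + dt * dS
        R = R + dt * rate_scale * phi[:, i] * S[:, -1] * np.clip(
            1.0 - R / prom.expr_sat, 0.0, None
        )

    # maturation as a pure delay of the observed fluorescence
    t_fine = np.arange(n_fine) * dt
    sample_times = np.clip(t - t[0] - prom.maturation_delay_min, 0.0, None)
    idx = np.clip(np.round(sample_times / dt).astype(int), 0, n_fine - 1)
    reporter = R_fine[:, idx]
    return reporter[0] if single else reporter


def generate_experiment(config: ExperimentConfig | dict) -> ExperimentSet:
    """Run the full generator for one configuration.

    The promoter sees the noiseless TF dynamics; measurement noise is added
    to the recorded channels only. Identical config + seed gives
    bit-identical output.
    """
    if isinstance(config, dict):
        config = ExperimentConfig(**config)
    rng = np.random.default_rng(config.seed)
    t, msn2, msn4, capacity = _tf_dynamics(config.tf, config.stimulus, config.n_cells, rng)
    if not config.genotype.has_msn2:
        msn2 = np.zeros_like(msn2)
    if not config.genotype.has_msn4:
        msn4 = np.zeros_like(msn4)
    reporter = simulate_promoter(msn2, msn4, capacity, config.promoter, t)

    sd_tf = config.tf.meas_noise_sd
    sd_r = config.promoter.expr_noise_sd
    obs2 = msn2 + (rng.normal(0.0, sd_tf, msn2.shape) if sd_tf > 0 else 0.0)
    obs4 = msn4 + (rng.normal(0.0, sd_tf, msn4.shape) if sd_tf > 0 else 0.0)
    obsr = reporter + (rng.normal(0.0, sd_r, reporter.shape) if sd_r > 0 else 0.0)
    if not config.genotype.has_msn2:
        obs2 = np.zeros_like(obs2)
    if not config.genotype.has_msn4:
        obs4 = np.zeros_like(obs4)

    width = max(4, len(str(config.n_cells - 1)))
    traces = [
        CellTrace(
            cell_id=f"c{i:0{width}d}",
            genotype=config.genotype,
            time_min=t,
            msn2_nuc=obs2[i],
            msn4_nuc=obs4[i],
            reporter=obsr[i],
            capacity=float(capacity[i]),
        )
        for i in range(config.n_cells)
    ]
    metadata = {
        "schema_version": SCHEMA_VERSION,
        "label": config.resolved_label(),
        "promoter": config.promoter.kinetics_class.value,
        "stimulus": config.stimulus.label(),
        "genotype": config.genotype.value,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
    }
    return ExperimentSet(traces=traces, config=config, metadata=metadata)


def generate_condition_grid(
    tf: TFParams,
    promoter: PromoterParams,
    stimulus: StimulusProgram,
    genotypes: Sequence[Genotype | str],
    n_cells: int,
    seed: int,
) -> dict:
    """Generate one experiment per genotype under a shared stimulus.

    Every genotype uses the same seed, so deletions differ from WT only by
    the zeroed channel (paired in-silico strains).
    """
    out = {}
    for g in genotypes:
        g = Genotype(g)
        cfg = ExperimentConfig(
            genotype=g, n_cells=n_cells, seed=seed, tf=tf,
            promoter=promoter, stimulus=stimulus,
        )
        out[g.value] = generate_experiment(cfg)
    return out
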