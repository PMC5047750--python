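"""Parameter models for stimulus programs, TF translocation and promoters.

All times are minutes; TF levels are in cross-channel "normalized a.u."
(Msn2-RFP rescaled onto the Msn4-YFP scale); reporter expression is in
expression a.u. Validation is handled by pydantic so that configurations
loaded from JSON fail loudly rather than silently misbehaving.
"""

from __future__ import annotations

import enum

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class StimulusKind(str, enum.Enum):
    """Shape of the TF nuclear-localization input.

    ``pulse``
        Square chemical-inhibitor pulse of a given duration: TF enters the
        nucleus at onset and exits when the inhibitor is washed out.
    ``adaptive_transient``
        Osmotic-stress-like input: the stress is applied continuously but the
        TF response adapts, producing a transient pulse of nuclear
        localization even though the stimulus is sustained.
    ``sustained``
        Ethanol-like input: TF nuclear localization rises and is held for the
        remainder of the experiment; translational capacity of most cells is
        strongly reduced.
    """

    PULSE = "pulse"
    ADAPTIVE_TRANSIENT = "adaptive_transient"
    SUSTAINED = "sustained"


class Genotype(str, enum.Enum):
    WT = "WT"
    MSN2D = "msn2d"
    MSN4D = "msn4d"
    MSN2D_MSN4D = "msn2d_msn4d"

    @property
    def has_msn2(self) -> bool:
        return self in (Genotype.WT, Genotype.MSN4D)

    @property
    def has_msn4(self) -> bool:
        return self in (Genotype.WT, Genotype.MSN2D)


class StimulusProgram(BaseModel):
    """Description of one input program driving TF nuclear translocation."""

    model_config = ConfigDict(frozen=True)

    kind: StimulusKind = StimulusKind.PULSE
    dose: float = Field(default=1.0, ge=0.0, le=1.0)
    onset_min: float = Field(default=10.0, ge=0.0)
    duration_min: float = Field(default=30.0, gt=0.0)
    total_min: float = Field(default=180.0, gt=0.0)
    sample_interval_min: float = Field(default=2.0, gt=0.0)
    #: adaptation timescale of the TF response under adaptive_transient inputs
    adaptation_tau_min: float = Field(default=15.0, gt=0.0)

    @model_validator(mode="after")
    def _check_grid(self) -> "StimulusProgram":
        if self.kind is StimulusKind.PULSE:
            if self.onset_min + self.duration_min > self.total_min:
                raise ValueError(
                    "pulse must end within the experiment: onset + duration "
                    f"= {self.onset_min + self.duration_min} > total "
                    f"{self.total_min}"
                )
        n = self.total_min / self.sample_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_min must be a multiple of the sample interval")
        k = self.onset_min / self.sample_interval_min
        if abs(k - round(k)) > 1e-9:
            raise ValueError("onset_min must lie on the sample grid")
        return self

    @property
    def offset_min(self) -> Optional[float]:
        """Input-removal time, or None when the input is never removed."""
        if self.kind is StimulusKind.PULSE:
            return self.onset_min + self.duration_min
        return None

    def time_grid(self) -> np.ndarray:
        """Closed, uniform sample grid [0, total_min]."""
        n = int(round(self.total_min / self.sample_interval_min))
        return np.linspace(0.0, self.total_min, n + 1)

    def label(self) -> str:
        if self.kind is StimulusKind.PULSE:
            return f"pulse{self.duration_min:g}@{self.onset_min:g}_d{self.dose:g}"
        return f"{self.kind.value}@{self.onset_min:g}_d{self.dose:g}"


class TFParams(BaseModel):
    """Population parameters of Msn2/Msn4 nuclear translocation.

    Mean nuclear Msn4 sits ``amp_ratio_msn2_over_msn4``-fold (default 3)
    below Msn2 on the normalized scale, with larger relative cell-to-cell
    heterogeneity (cv 0.5 vs 0.2) and a short translocation lag
    (default 2.5 min). ``dose_sat_msn4`` makes Msn4's amplitude
    dose-response saturate at low stimulus strength while Msn2's remains
    proportional to dose.
    """

    model_config = ConfigDict(frozen=True)

    mean_amp_msn2: float = Field(default=40.0, gt=0.0)
    amp_ratio_msn2_over_msn4: float = Field(default=3.0, gt=0.0)
    cv_amp_msn2: float = Field(default=0.2, gt=0.0)
    cv_amp_msn4: float = Field(default=0.5, gt=0.0)
    lag_msn4_min: float = Field(default=2.5, ge=0.0)
    tau_import_min: float = Field(default=2.0, gt=0.0)
    tau_export_min: float = Field(default=2.5, gt=0.0)
    meas_noise_sd: float = Field(default=0.8, ge=0.0)
    #: half-saturating dose of Msn4 nuclear accumulation
    dose_sat_msn4: float = Field(default=0.15, gt=0.0)
    #: Beta-distribution shape of per-cell translational capacity under
    #: sustained (ethanol-like) stress; mass concentrated near zero
    capacity_beta_a: float = Field(default=0.4, gt=0.0)
    capacity_beta_b: float = Field(default=2.0, gt=0.0)

    @property
    def mean_amp_msn4(self) -> float:
        return self.mean_amp_msn2 / self.amp_ratio_msn2_over_msn4

    def msn4_dose_scale(self, dose: float) -> float:
        """Amplitude scale of Msn4 at a given dose, normalized to 1 at dose 1."""
        k = self.dose_sat_msn4
        return dose * (1.0 + k) / (k + dose) if dose > 0 else 0.0


class KineticsClass(str, enum.Enum):
    FAST = "fast"
    SLOW = "slow"


class PromoterParams(BaseModel):
    """Kinetic parameters of one promoter class.

    Chromatin opening is a chain of ``n_open_steps`` sequential first-order
    transitions at per-step rate ``k_open_per_min`` (an Erlang activation
    delay); transcription from the open state proceeds at
    ``beta_max * (w_msn2*msn2 + w_msn4*msn4) / (K_occ + msn2 + msn4)``,
    i.e. the two factors compete for shared binding sites. For the slow
    class the opening chain only advances while nuclear Msn2 exceeds the
    switch threshold ``theta_msn2``, and the per-step rate is scaled by
    ``msn4_open_floor + (1-msn4_open_floor)*msn4/(msn4_open_K + msn4)``:
    without Msn4 the promoter still opens, but several-fold more slowly.
    """

    model_config = ConfigDict(frozen=True)

    kinetics_class: KineticsClass
    k_open_per_min: float = Field(gt=0.0)
    k_close_per_min: float = Field(default=0.01, ge=0.0)
    n_open_steps: int = Field(default=6, ge=1)
    theta_msn2: float = Field(default=10.0, gt=0.0)
    basal_occ: float = Field(default=1.0, gt=0.0)
    beta_max: float = Field(default=100.0, gt=0.0)
    expr_sat: float = Field(default=100.0, gt=0.0)
    K_occ: float = Field(default=5.0, gt=0.0)
    w_msn2: float = Field(ge=0.0)
    w_msn4: float = Field(default=1.0, ge=0.0)
    msn4_open_floor: float = Field(default=1.0, gt=0.0, le=1.0)
    msn4_open_K: float = Field(default=10.0, gt=0.0)
    maturation_delay_min: float = Field(default=10.0, ge=0.0)
    expr_noise_sd: float = Field(default=1.0, ge=0.0)

    @classmethod
    def fast(cls, **overrides) -> "PromoterParams":
        """Fast-kinetics promoter: opens whenever either factor is present."""
        defaults = dict(
            kinetics_class=KineticsClass.FAST,
            k_open_per_min=0.9,
            w_msn2=1.0,
            w_msn4=1.0,
            msn4_open_floor=1.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def slow(cls, **overrides) -> "PromoterParams":
        """Slow-kinetics promoter: Msn2 switch gate, Msn4-accelerated opening.

        Default per-step opening rate is 5-fold below the fast class.
        """
        defaults = dict(
            kinetics_class=KineticsClass.SLOW,
            k_open_per_min=0.18,
            w_msn2=0.2,
            w_msn4=1.0,
            msn4_open_floor=0.48,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def for_class(cls, kinetics_class: "KineticsClass | str", **overrides):
        kc = KineticsClass(kinetics_class)
        return cls.fast(**overrides) if kc is KineticsClass.FAST else cls.slow(**overrides)


class ExperimentConfig(BaseModel):
    """Complete, reproducible description of one simulated experiment."""

    model_config = ConfigDict(frozen=True)

    label: Optional[str] = None
    genotype: Genotype = Genotype.WT
    n_cells: int = Field(ge=1)
    seed: int = Field(ge=0)
    tf: TFParams = TFParams()
    promoter: PromoterParams = PromoterParams.slow()
    stimulus: StimulusProgram = StimulusProgram()

    def resolved_label(self) -> str:
        if self.label:
            return self.label
        return (
            f"{self.promoter.kinetics_class.value}_{self.genotype.value}_"
            f"{self.stimulus.label()}"
        )


def config_json_schema() -> dict:
    """JSON schema for :class:`ExperimentConfig` (shipped via the CLI)."""
    return ExperimentConfig.model_json_schema()
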