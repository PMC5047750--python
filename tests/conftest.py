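import numpy as np
import pytest

import msngate as mg


@pytest.fixture(scope="session")
def tf_params():
    return mg.TFParams()


@pytest.fixture(scope="session")
def slow_prom():
    return mg.PromoterParams.slow()


@pytest.fixture(scope="session")
def fast_prom():
    return mg.PromoterParams.fast()


@pytest.fixture(scope="session")
def pulse30():
    return mg.StimulusProgram(duration_min=30.0)


@pytest.fixture(scope="session")
def pulse60():
    return mg.StimulusProgram(duration_min=60.0)


@pytest.fixture(scope="session")
def slow_wt30(slow_prom, pulse30):
    """Slow-promoter WT experiment, saturating 30-min pulse."""
    return mg.generate_experiment(
        mg.ExperimentConfig(n_cells=150, seed=11, promoter=slow_prom, stimulus=pulse30)
    )


@pytest.fixture(scope="session")
def slow_wt30_features(slow_wt30):
    return mg.extract_features(slow_wt30)


@pytest.fixture(scope="session")
def mean_cell_traces():
    """Noiseless single-cell TF traces at the population-mean amplitudes."""

    def build(duration_min, genotype="WT", dose=1.0, amp2=40.0, amp4=40.0 / 3):
        stim = mg.StimulusProgram(duration_min=duration_min, dose=dose)
        t = stim.time_grid()
        tf = mg.TFParams()

        def first_order(amp, lag):
            t0 = stim.onset_min + lag
            off = stim.onset_min + duration_min
            x = np.zeros_like(t)
            on = (t >= t0) & (t < off)
            x[on] = amp * (1 - np.exp(-(t[on] - t0) / tf.tau_import_min))
            lvl = amp * (1 - np.exp(-(off - t0) / tf.tau_import_min))
            dec = t >= off
            x[dec] = lvl * np.exp(-(t[dec] - off) / tf.tau_export_min)
            return x

        g = mg.Genotype(genotype)
        m2 = first_order(amp2 * dose, 0.0) if g.has_msn2 else np.zeros_like(t)
        m4 = first_order(amp4 * dose, tf.lag_msn4_min) if g.has_msn4 else np.zeros_like(t)
        return t, m2, m4

    return build
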