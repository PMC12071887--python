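import numpy as np
import pytest

from plateletkin import HillParams, StimulusProtocol, Trace


@pytest.fixture
def eq5_trace():
    """Factory for monoexponential-saturation traces I(t) = Im - (Im-Io)e^{-kt}."""

    def make(k, i_m=100.0, i_o=0.0, t_end=60.0, dt=0.1, channel="LSI12",
             noise_sd=0.0, seed=0):
        t = np.arange(0.0, t_end + dt / 2, dt)
        y = i_m - (i_m - i_o) * np.exp(-k * t)
        if noise_sd > 0:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, y.shape)
        return Trace(t, {channel: y})

    return make


@pytest.fixture
def adp_protocol():
    """Single ADP addition at t = 5 s."""

    def make(conc, t_end=300.0, **kw):
        return StimulusProtocol(
            events=[dict(t=5.0, kind="add_agonist", species="ADP", conc=conc)],
            t_end=t_end, **kw,
        )

    return make


# printed summary data used as fitting inputs across tests:
# desensitization constants out of the shape-changed state (k5) and the
# integrin-active state (k6) at three ADP doses, each tabulated both as a
# rate constant (2 significant digits) and as a half-time (3 digits)
DESENS_ADP_NM = np.array([1000.0, 2000.0, 5000.0])
K5_PRINTED = np.array([0.0019, 0.0013, 0.0005])
K5_TAU_PRINTED = np.array([364.0, 554.0, 1280.0])
K6_PRINTED = np.array([0.0279, 0.0092, 0.0026])

# dose-response parameters: shape change (Vsh) and integrin activation
# (Vagg) for ADP and TRAP; iloprost inhibition of Vagg
SHAPE_CHANGE_ADP = HillParams(0.19, 46.8, 1.27)
INTEGRIN_ADP = HillParams(0.03, 589.8, 3.92)
ILO_VAGG = HillParams(100.0, 0.21, 2.14, mode="inhibition")
K5_LAW = HillParams(0.0028, 1840.0, 1.4, mode="inhibition")
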