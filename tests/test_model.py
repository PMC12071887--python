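"""Phenotype ODE system: rate assembly, integration, conservation and
qualitative pharmacology."""

import numpy as np
import pytest

from plateletkin import (
    HillParams,
    StimulusProtocol,
    assemble_rate_constants,
    default_parameter_table,
    observables,
    simulate,
)
from plateletkin.errors import ConfigurationError, ProtocolError
from plateletkin.model import STATE_NAMES

ZERO_FIT = {"k1r": 0.0, "k4r": 0.0, "k7": 0.0}


class TestRateAssembly:
    def test_no_stimulus_is_stationary(self):
        ks = assemble_rate_constants({}, {}, fitted=ZERO_FIT)
        assert (ks.k1, ks.k2, ks.k4, ks.k5, ks.k6) == (0, 0, 0, 0, 0)

    def test_saturating_agonist_reaches_maximal_rates(self):
        ks = assemble_rate_constants({"ADP": 1e9})
        assert ks.k1 == pytest.approx(0.19, rel=1e-4)
        assert ks.k2 == pytest.approx(0.03, rel=1e-4)

    def test_stir_off_only_zeroes_aggregation(self):
        on = assemble_rate_constants({"ADP": 1000.0}, stirring=True)
        off = assemble_rate_constants({"ADP": 1000.0}, stirring=False)
        assert on.k3 == pytest.approx(2 * 0.03 / 100)
        assert off.k3 == 0.0
        assert off.k6 == on.k6 > 0  # desensitization continues unstirred

    def test_noncompetitive_inhibition_scales_with_exposure(self):
        free = assemble_rate_constants({"ADP": 5000.0})
        full = assemble_rate_constants(
            {"ADP": 5000.0}, {"iloprost": 5.0}, inhibitor_exposure=1.0
        )
        fresh = assemble_rate_constants(
            {"ADP": 5000.0}, {"iloprost": 5.0}, inhibitor_exposure=0.0
        )
        assert full.k1 < 0.01 * free.k1  # saturating iloprost blocks k1
        assert fresh.k1 == pytest.approx(free.k1)  # no effect until onset
        assert full.k4 == pytest.approx(0.31, rel=0.01)

    def test_missing_agonist_law_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            assemble_rate_constants(
                {"collagen": 100.0}, param_table={"k1:ADP": HillParams(0.19, 46.8, 1.27)}
            )


class TestSimulation:
    def test_all_zero_constants_stay_at_rest(self):
        p = StimulusProtocol(events=[], t_end=100.0)
        traj = simulate(p, fitted=ZERO_FIT)
        assert np.allclose(traj.states[:, 0], 100.0)
        assert np.allclose(traj.states[:, 1:], 0.0)

    @pytest.mark.parametrize("dose", [100.0, 2000.0, 10000.0])
    def test_conservation_and_nonnegativity(self, adp_protocol, dose):
        traj = simulate(adp_protocol(dose))
        assert traj.conservation_error() < 1e-6
        assert traj.states.min() > -1e-9
        assert traj.frame()[list(STATE_NAMES)].min().min() >= 0.0

    def test_shape_change_matches_closed_form(self):
        """With only the shape-change reaction active the sphered fraction
        follows 100 (1 - exp(-k1 t)) exactly."""
        table = {"k1:ADP": HillParams(0.19, 46.8, 1.27)}
        p = StimulusProtocol(
            events=[dict(t=0.0, kind="add_agonist", species="ADP",
                         conc=46.8)],
            t_end=60.0,
        )
        traj = simulate(p, param_table=table, fitted=ZERO_FIT)
        expected = 100.0 * (1.0 - np.exp(-0.095 * traj.t))
        assert np.allclose(traj.states[:, 1], expected, atol=1e-5)

    def test_event_split_invariance(self, adp_protocol):
        base = simulate(adp_protocol(2000.0))
        split = StimulusProtocol(
            events=[
                dict(t=5.0, kind="add_agonist", species="ADP", conc=2000.0),
                dict(t=77.0, kind="add_agonist", species="ADP", conc=0.0),
            ],
            t_end=300.0,
        )
        traj = simulate(split)
        assert np.allclose(traj.states, base.states, atol=1e-6)

    def test_event_outside_horizon_rejected(self):
        with pytest.raises(ProtocolError):
            StimulusProtocol(
                events=[dict(t=400.0, kind="add_agonist", species="ADP",
                             conc=1.0)],
                t_end=300.0,
            )

    def test_peak_aggregation_monotone_in_agonist(self, adp_protocol):
        peaks = [simulate(adp_protocol(c)).peak() for c in
                 (100, 500, 2000, 10000)]
        assert all(a <= b + 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_peak_aggregation_monotone_decreasing_in_inhibitor(self):
        peaks = []
        for ilo in (0.0, 0.05, 0.1, 0.5, 5.0):
            events = [dict(t=5.0, kind="add_agonist", species="ADP",
                           conc=2000.0)]
            if ilo:
                events.insert(0, dict(t=5.0, kind="add_inhibitor",
                                      species="iloprost", conc=ilo))
            peaks.append(simulate(StimulusProtocol(events=events,
                                                   t_end=300.0)).peak())
        assert all(a >= b - 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_low_dose_shape_change_high_dose_aggregation(self, adp_protocol):
        low = simulate(adp_protocol(100.0))
        high = simulate(adp_protocol(10000.0))
        assert low.peak() < 0.5 and low.peak("n_sph") > 30.0
        assert low.final("n_exh") > 20.0  # exhaustion follows shape change
        assert high.peak() > 80.0
        assert high.final("n_exh") < 10.0  # slow exhaustion at high dose

    def test_initial_state_override(self):
        p = StimulusProtocol(events=[], t_end=10.0)
        traj = simulate(p, y0=[50, 0, 0, 50, 0, 0], fitted=ZERO_FIT)
        assert traj.states[-1, 3] == pytest.approx(50.0)


class TestObservables:
    def test_resting_trajectory_is_flat_at_baseline(self):
        p = StimulusProtocol(events=[], t_end=50.0)
        tr = observables(simulate(p, fitted=ZERO_FIT))
        assert np.allclose(tr.channel("LSI1"), 0.0)
        assert np.allclose(tr.channel("LSI12"), 0.0)

    def test_shape_change_rises_only_at_twelve_degrees(self):
        table = {"k1:ADP": HillParams(0.19, 46.8, 1.27)}
        p = StimulusProtocol(
            events=[dict(t=0.0, kind="add_agonist", species="ADP",
                         conc=1000.0)],
            t_end=60.0,
        )
        tr = observables(simulate(p, param_table=table, fitted=ZERO_FIT))
        assert np.allclose(tr.channel("LSI1"), 0.0)
        assert tr.channel("LSI12")[-1] > 99.0

    def test_aggregation_signature(self, adp_protocol):
        """LSI1 rises monotonically during full aggregation while LSI12
        falls after its peak."""
        tr = observables(simulate(adp_protocol(10000.0)))
        lsi1, lsi12 = tr.channel("LSI1"), tr.channel("LSI12")
        assert np.all(np.diff(lsi1) >= -1e-9)
        ipk = int(np.argmax(lsi12))
        assert lsi12[-1] < lsi12[ipk] - 10.0

    def test_affine_map_spec(self, adp_protocol):
        spec = {"LSI1": {"baseline": 5.0, "gain": 2.0,
                         "weights": {"n_agg": 1.0}}}
        traj = simulate(adp_protocol(10000.0))
        tr = observables(traj, spec)
        assert np.allclose(
            tr.channel("LSI1"),
            5.0 + 2.0 * np.clip(traj.states[:, 3], 0, None),
        )
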