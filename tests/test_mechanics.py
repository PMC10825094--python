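import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ventbench import (
    InvalidSettingsError,
    LungCircuit,
    VentilatorSettings,
    auto_peep,
    breath_timing,
    simulate_breath,
)


def iterated_auto_peep(settings, lung, extra_exp_resistance=0.0):
    """Independent oracle: breath-by-breath exhalation to its fixed point.

    Steady state is declared when successive end-expiratory volumes differ
    by < 1e-6 mL (1e-9 L) or after 200 breaths.
    """
    _, t_exp = breath_timing(settings)
    tau = (lung.resistance_exp + extra_exp_resistance) * lung.compliance / 1000.0
    if tau <= 0:
        return 0.0
    decay = math.exp(-t_exp / tau)
    v_ee = 0.0
    for _ in range(200):
        v_next = (v_ee + settings.tidal_volume_set) * decay
        if abs(v_next - v_ee) < 1e-6:
            v_ee = v_next
            break
        v_ee = v_next
    return v_ee / lung.compliance


@pytest.mark.parametrize(
    "vt, flow, pause, rr, expected",
    [
        (400.0, 60.0, 0.4, 20.0, (0.8, 2.2)),
        (0.0, 60.0, 0.0, 20.0, (0.0, 3.0)),
        (580.0, 60.0, 0.4, 35.0, (0.98, 0.7343)),
    ],
)
def test_breath_timing(vt, flow, pause, rr, expected):
    s = VentilatorSettings(vt, flow, pause, rr, 5.0)
    t_i, t_e = breath_timing(s)
    assert t_i == pytest.approx(expected[0], abs=1e-4)
    assert t_e == pytest.approx(expected[1], abs=1e-4)


def test_settings_without_expiratory_time_rejected():
    with pytest.raises(InvalidSettingsError):
        VentilatorSettings(1600.0, 60.0, 0.4, 40.0, 5.0)


class TestAutoPeep:
    def test_reference_settings_negligible_trapping(self, lung60, base_settings):
        # tau 0.3 s vs Te 2.2 s: essentially complete exhalation
        assert auto_peep(base_settings, lung60) == pytest.approx(0.00436, abs=2e-4)

    def test_high_rate_traps_gas(self, lung60):
        s = VentilatorSettings(400.0, 60.0, 0.4, 35.0, 5.0)
        assert auto_peep(s, lung60) == pytest.approx(0.3323, abs=1e-3)

    def test_complete_exhalation_limit(self):
        # Te/tau > 20 -> zero within 1e-6
        lung = LungCircuit(20.0, 2.0, 2.0, 120.0)  # tau 0.04 s
        s = VentilatorSettings(400.0, 60.0, 0.0, 20.0, 5.0)
        assert auto_peep(s, lung) < 1e-6

    def test_closed_form_equals_breath_iteration_fixed_point(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            c = rng.uniform(10.0, 100.0)
            r = rng.uniform(2.0, 30.0)
            vt = rng.uniform(200.0, 800.0)
            rr = rng.uniform(10.0, 35.0)
            pause = rng.uniform(0.0, 0.5)
            try:
                s = VentilatorSettings(vt, 60.0, pause, rr, 5.0)
            except InvalidSettingsError:
                continue
            lung = LungCircuit(c, r, r, 120.0)
            assert auto_peep(s, lung) == pytest.approx(
                iterated_auto_peep(s, lung), abs=1e-6
            )
            checked += 1

    def test_monotone_in_rate_and_expiratory_resistance(self, lung60):
        values = [
            auto_peep(VentilatorSettings(400.0, 60.0, 0.4, rr, 5.0), lung60)
            for rr in (15.0, 20.0, 25.0, 30.0, 35.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))
        s = VentilatorSettings(400.0, 60.0, 0.4, 30.0, 5.0)
        by_res = [auto_peep(s, lung60, extra) for extra in (0.0, 5.0, 10.0, 20.0)]
        assert all(a < b for a, b in zip(by_res, by_res[1:]))


class TestSimulateBreath:
    def test_reference_condition_pressures(self, lung60, base_settings):
        m = simulate_breath(base_settings, lung60)
        assert m.p_plat == pytest.approx(11.67, abs=0.01)
        assert m.p_peak == pytest.approx(16.67, abs=0.01)
        assert m.peep_total == pytest.approx(5.0, abs=0.01)

    def test_zero_volume_breath_stays_at_peep(self, lung60):
        s = VentilatorSettings(0.0, 60.0, 0.0, 20.0, 5.0)
        m = simulate_breath(s, lung60)
        assert m.p_peak == m.p_plat == m.peep_total == 5.0

    def test_stiff_lung_high_peep(self, lung20):
        s = VentilatorSettings(400.0, 60.0, 0.4, 20.0, 15.0)
        m = simulate_breath(s, lung20)
        assert m.p_plat == pytest.approx(35.0, abs=0.01)
        assert m.p_peak == pytest.approx(40.0, abs=0.01)

    def test_delivered_volume_matches_setting(self, lung60, base_settings):
        m = simulate_breath(base_settings, lung60)
        assert m.delivered_vt == pytest.approx(400.0, rel=0.005)

    def test_waveform_is_tidy_and_plateau_visible(self, lung60, base_settings):
        wf = simulate_breath(base_settings, lung60).waveform
        assert list(wf.columns) == ["time_s", "flow_Lps", "pressure_cmH2O", "volume_mL"]
        pause = wf[(wf.time_s > 0.41) & (wf.time_s < 0.79)]
        assert np.allclose(pause.flow_Lps, 0.0)
        assert np.allclose(pause.pressure_cmH2O, 11.67, atol=0.01)

    @given(
        c=st.floats(15.0, 90.0),
        r=st.floats(1.0, 25.0),
        vt=st.floats(100.0, 700.0),
        peep=st.floats(0.0, 15.0),
        extra=st.floats(0.0, 10.0),
    )
    def test_pressure_chain_and_resistive_drop(self, c, r, vt, peep, extra):
        lung = LungCircuit(c, r, r, 120.0)
        s = VentilatorSettings(vt, 60.0, 0.4, 20.0, peep)
        m = simulate_breath(s, lung, extra_resistance_insp=extra)
        assert m.p_peak >= m.p_plat >= m.peep_total >= s.peep_set
        # square-flow model: resistive drop is exactly R_total * flow
        assert m.p_peak - m.p_plat == pytest.approx((r + extra) * 1.0, abs=1e-9)
        # ideal-compartment driving pressure
        assert m.p_plat - m.peep_total == pytest.approx(vt / c, abs=1e-9)
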