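"""Steady-state breath mechanics of a passive single-compartment lung.

The model is the textbook linear one-compartment equation of motion under
volume-controlled ventilation: a constant (square) inspiratory flow delivers
the set tidal volume, an end-inspiratory pause exposes the plateau pressure,
and exhalation is passive and exponential against the set PEEP with time
constant ``tau = R_exp * C``.  When the expiratory time is short relative to
``tau`` the compartment does not empty completely and gas trapping produces
auto-PEEP; the periodic steady state of that process has a closed form, used
here directly.

Closed forms (volumes in mL, compliance in mL/cmH2O, resistance in
cmH2O/L/s, flow converted to L/s):

* trapped volume   ``V_trap = VT * exp(-Te/tau) / (1 - exp(-Te/tau))``
* auto-PEEP        ``V_trap / C``
* total PEEP       ``PEEP_set + auto-PEEP``
* plateau          ``PEEP_total + VT / C``
* peak             ``P_plat + R_insp_total * flow``

Resistive pressure of an in-line sedation device can be added through the
``extra_resistance_*`` arguments; by default it is zero because the bench's
pressure transducers sit downstream of the device, so measured pressures
exclude it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSettingsError

#: Waveform sampling rate (Hz); mirrors a typical bench datalogger.
DEFAULT_SAMPLE_RATE_HZ = 200.0


def lpm_to_lps(flow_lpm: float) -> float:
    """Convert a flow from L/min (ventilator convention) to L/s.

    All resistive-pressure arithmetic in this package goes through this one
    helper so the unit convention lives in a single place.
    """
    return flow_lpm / 60.0


@dataclass(frozen=True)
class VentilatorSettings:
    """The controlled knobs of volume-controlled ventilation.

    Parameters
    ----------
    tidal_volume_set : float
        Set tidal volume (mL).
    inspiratory_flow : float
        Square inspiratory flow (L/min).
    pause_time : float
        End-inspiratory occlusion time (s).
    respiratory_rate : float
        Breaths per minute.
    peep_set : float
        External PEEP (cmH2O).
    fio2 : float
        Inspired oxygen fraction; metadata only.
    """

    tidal_volume_set: float
    inspiratory_flow: float
    pause_time: float
    respiratory_rate: float
    peep_set: float
    fio2: float = 0.21

    def __post_init__(self) -> None:
        if self.tidal_volume_set < 0:
            raise InvalidSettingsError("tidal volume must be >= 0")
        if self.inspiratory_flow <= 0:
            raise InvalidSettingsError("inspiratory flow must be > 0")
        if self.pause_time < 0:
            raise InvalidSettingsError("pause time must be >= 0")
        if self.respiratory_rate <= 0:
            raise InvalidSettingsError("respiratory rate must be > 0")
        if self.peep_set < 0:
            raise InvalidSettingsError("PEEP must be >= 0")
        if not 0 <= self.fio2 <= 1:
            raise InvalidSettingsError("FiO2 must be in [0, 1]")
        t_insp = self.tidal_volume_set / 1000.0 / lpm_to_lps(self.inspiratory_flow) + self.pause_time
        if t_insp >= 60.0 / self.respiratory_rate:
            raise InvalidSettingsError(
                f"inspiratory time {t_insp:.3f} s leaves no expiratory time at "
                f"RR {self.respiratory_rate}/min"
            )


@dataclass(frozen=True)
class LungCircuit:
    """Passive single-compartment lung plus breathing circuit.

    ``physiologic_dead_space`` is the series (apparatus + anatomical
    stand-in) dead space of the circuit *without* any sedation device.
    """

    compliance: float  # mL/cmH2O
    resistance_insp: float  # cmH2O/L/s
    resistance_exp: float  # cmH2O/L/s
    physiologic_dead_space: float  # mL
    label: str = ""

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise InvalidSettingsError("compliance must be > 0")
        if self.resistance_insp < 0 or self.resistance_exp < 0:
            raise InvalidSettingsError("resistances must be >= 0")
        if self.physiologic_dead_space < 0:
            raise InvalidSettingsError("dead space must be >= 0")


@dataclass
class BreathMechanics:
    """Steady-state pressures and timing of one breath.

    ``waveform`` is a tidy frame (time_s, flow_Lps, pressure_cmH2O,
    volume_mL) sampling one steady-state breath; volume is measured above
    the relaxation volume at the set PEEP.
    """

    p_peak: float
    p_plat: float
    peep_total: float
    auto_peep: float
    t_insp: float
    t_exp: float
    delivered_vt: float
    waveform: pd.DataFrame = field(repr=False, default=None)

    def waveform_to_csv(self, path) -> None:
        """Export the one-breath waveform as tidy CSV."""
        self.waveform.to_csv(path, index=False)


def breath_timing(settings: VentilatorSettings) -> tuple[float, float]:
    """Return (inspiratory, expiratory) time in seconds.

    Inspiratory time is insufflation (VT / flow) plus the pause; expiratory
    time is the remainder of the cycle.
    """
    flow_lps = lpm_to_lps(settings.inspiratory_flow)
    t_insp = settings.tidal_volume_set / 1000.0 / flow_lps + settings.pause_time
    t_exp = 60.0 / settings.respiratory_rate - t_insp
    if t_exp <= 0:
        raise InvalidSettingsError("non-positive expiratory time")
    return t_insp, t_exp


def auto_peep(
    settings: VentilatorSettings,
    lung: LungCircuit,
    extra_exp_resistance: float = 0.0,
) -> float:
    """Auto-PEEP (cmH2O) of the periodic steady state of passive exhalation.

    With expiratory time ``Te`` and time constant
    ``tau = (R_exp + extra) * C``, the trapped volume converges to
    ``VT * x / (1 - x)`` with ``x = exp(-Te/tau)``; auto-PEEP is that volume
    over compliance.  Tends to 0 as ``Te/tau`` grows.
    """
    _, t_exp = breath_timing(settings)
    tau = (lung.resistance_exp + extra_exp_resistance) * lung.compliance / 1000.0
    if tau <= 0 or settings.tidal_volume_set == 0:
        return 0.0
    x = math.exp(-t_exp / tau)
    if x >= 1.0:  # pragma: no cover - excluded by breath_timing
        raise InvalidSettingsError("no exhalation possible")
    v_trap = settings.tidal_volume_set * x / (1.0 - x)
    return v_trap / lung.compliance


def simulate_breath(
    settings: VentilatorSettings,
    lung: LungCircuit,
    extra_resistance_insp: float = 0.0,
    extra_resistance_exp: float = 0.0,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> BreathMechanics:
    """Simulate one steady-state breath and return its mechanics.

    Pressures follow the closed forms in the module docstring; the waveform
    samples the same analytic solution at ``sample_rate_hz``.
    """
    t_insp, t_exp = breath_timing(settings)
    vt = settings.tidal_volume_set
    flow_lps = lpm_to_lps(settings.inspiratory_flow)
    ap = auto_peep(settings, lung, extra_resistance_exp)
    peep_total = settings.peep_set + ap
    p_plat = peep_total + vt / lung.compliance
    r_insp_total = lung.resistance_insp + extra_resistance_insp
    p_peak = p_plat + r_insp_total * flow_lps if vt > 0 else p_plat

    v_trap = ap * lung.compliance
    t_flow = vt / 1000.0 / flow_lps
    tau = (lung.resistance_exp + extra_resistance_exp) * lung.compliance / 1000.0

    def seg(t0, t1):
        n = max(int(math.ceil((t1 - t0) * sample_rate_hz)), 1)
        return np.linspace(t0, t1, n + 1)

    # insufflation
    t1 = seg(0.0, t_flow) if t_flow > 0 else np.array([0.0])
    v1 = v_trap + flow_lps * 1000.0 * t1
    f1 = np.full_like(t1, flow_lps if vt > 0 else 0.0)
    p1 = settings.peep_set + v1 / lung.compliance + r_insp_total * f1
    # pause (zero flow -> plateau)
    if settings.pause_time > 0:
        t2 = seg(t_flow, t_insp)[1:]
        v2 = np.full_like(t2, v_trap + vt)
        f2 = np.zeros_like(t2)
        p2 = settings.peep_set + v2 / lung.compliance
    else:
        t2 = np.array([])
        v2 = f2 = p2 = t2
    # passive exhalation
    t3 = seg(t_insp, t_insp + t_exp)[1:]
    if tau > 0:
        v3 = (v_trap + vt) * np.exp(-(t3 - t_insp) / tau)
        f3 = -v3 / (tau * 1000.0)
    else:
        v3 = np.zeros_like(t3)
        f3 = np.zeros_like(t3)
    # pressure at the lung inlet during passive exhalation equals the applied
    # PEEP: recoil (V/C) exactly balances the resistive drop R_exp * flow
    p3 = np.full_like(t3, float(settings.peep_set))

    waveform = pd.DataFrame(
        {
            "time_s": np.concatenate([t1, t2, t3]),
            "flow_Lps": np.concatenate([f1, f2, f3]),
            "pressure_cmH2O": np.concatenate([p1, p2, p3]),
            "volume_mL": np.concatenate([v1, v2, v3]),
        }
    )
    # integrate inspiratory flow over the insufflation segment only; the
    # trapezoid rule is exact for the square profile
    delivered = float(np.trapezoid(f1, t1) * 1000.0)

    return BreathMechanics(
        p_peak=p_peak,
        p_plat=p_plat,
        peep_total=peep_total,
        auto_peep=ap,
        t_insp=t_insp,
        t_exp=t_exp,
        delivered_vt=delivered,
        waveform=waveform,
    )
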