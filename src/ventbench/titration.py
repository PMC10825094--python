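"""EtCO2-correction protocol: stepwise minute-ventilation titration.

After a sedation device is inserted, EtCO2 rises above the 40 mmHg
baseline.  The protocol restores it by raising either tidal volume or
respiratory rate in 15 %-of-baseline steps (60 mL or 3 breaths/min at the
reference settings), dwelling at each step, until EtCO2 returns to the
40 +/- 2 mmHg band.

Because the grid is fixed, the modelled EtCO2 can jump from above the band
straight to below it; the controller therefore stops at the *first* grid
value with EtCO2 <= target + band (the only monotone reading of the stop
rule that always terminates) and reports whether the final value actually
lies inside the band via ``within_band``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .calibration import SedationDevice
from .errors import InvalidSettingsError, TitrationError
from .gas_exchange import (
    DEFAULT_FRC_ML,
    GasState,
    alveolar_ventilation,
    steady_state_etco2,
    washout_to_steady_state,
)
from .mechanics import BreathMechanics, LungCircuit, VentilatorSettings, simulate_breath


@dataclass
class TitrationResult:
    """Step sequence and final state of one EtCO2-correction run.

    ``steps`` lists ``(setting_value, steady EtCO2)`` for each increment
    actually taken (the pre-titration device baseline is not a step).
    """

    mode: str  # "VT" or "RR"
    steps: list[tuple[float, float]]
    final_vt: float
    final_rr: float
    final_etco2: float
    n_steps: int
    within_band: bool
    final_mechanics: BreathMechanics | None = field(repr=False, default=None)


def titrate(
    mode: str,
    device: SedationDevice,
    base: VentilatorSettings,
    lung: LungCircuit,
    target: float = 40.0,
    band: float = 2.0,
    max_steps: int = 20,
    with_mechanics: bool = True,
    dynamics: bool = False,
    dwell_s: float = 150.0,
    functional_residual_capacity: float = DEFAULT_FRC_ML,
) -> TitrationResult:
    """Run the stepwise EtCO2-correction protocol for one device arm.

    Parameters
    ----------
    mode : {"VT", "RR"}
        Which setting is raised; increments are 15 % of its *baseline*
        value, i.e. an arithmetic grid.
    dynamics : bool
        When True each step's EtCO2 is the value actually reached after the
        dwell time by the per-breath washout model; the default evaluates
        the closed-form steady state directly.

    Raises
    ------
    TitrationError
        If ``max_steps`` increments do not bring EtCO2 to the stop rule;
        carries the trajectory walked so far.
    """
    if mode not in ("VT", "RR"):
        raise ValueError(f"mode must be 'VT' or 'RR', got {mode!r}")
    step = 0.15 * (base.tidal_volume_set if mode == "VT" else base.respiratory_rate)
    vd_total = lung.physiologic_dead_space + device.effective_dead_space_added

    va_baseline = alveolar_ventilation(
        base.respiratory_rate, base.tidal_volume_set, lung.physiologic_dead_space
    )
    anchor = GasState.anchored(target, va_baseline)

    def etco2_at(settings: VentilatorSettings, current: float | None) -> float:
        va = alveolar_ventilation(
            settings.respiratory_rate, settings.tidal_volume_set, vd_total
        )
        if dynamics and current is not None:
            state = GasState(
                etco2=current,
                alveolar_ventilation=anchor.baseline_etco2
                * anchor.baseline_alveolar_ventilation
                / current,
                baseline_etco2=anchor.baseline_etco2,
                baseline_alveolar_ventilation=anchor.baseline_alveolar_ventilation,
            )
            n = max(int(dwell_s / 60.0 * settings.respiratory_rate), 1)
            seq = washout_to_steady_state(
                state,
                va,
                functional_residual_capacity=functional_residual_capacity,
                rr=settings.respiratory_rate,
                rel_tol=1e-6,
                max_breaths=n,
            )
            return float(seq[-1])
        return steady_state_etco2(va, anchor)

    settings = base
    etco2 = etco2_at(settings, None)
    steps: list[tuple[float, float]] = []
    stop = target + band

    while etco2 > stop:
        if len(steps) >= max_steps:
            raise TitrationError(
                f"{mode} titration did not reach EtCO2 <= {stop} mmHg within "
                f"{max_steps} steps",
                trajectory=steps,
            )
        if mode == "VT":
            settings = replace(
                settings, tidal_volume_set=settings.tidal_volume_set + step
            )
            value = settings.tidal_volume_set
        else:
            settings = replace(
                settings, respiratory_rate=settings.respiratory_rate + step
            )
            value = settings.respiratory_rate
        etco2 = etco2_at(settings, etco2)
        steps.append((value, etco2))

    mech = None
    if with_mechanics:
        mech = simulate_breath(
            settings, lung, device.resistance_insp, device.resistance_exp
        )
    return TitrationResult(
        mode=mode,
        steps=steps,
        final_vt=settings.tidal_volume_set,
        final_rr=settings.respiratory_rate,
        final_etco2=etco2,
        n_steps=len(steps),
        within_band=abs(etco2 - target) <= band,
        final_mechanics=mech,
    )
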