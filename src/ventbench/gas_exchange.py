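"""Steady-state EtCO2 as a function of alveolar ventilation.

The bench injects CO2 at a constant rate and is tuned to read 40 mmHg
end-tidal CO2 at the baseline settings.  With a constant CO2 inflow and a
series (Bohr) dead space, the steady-state alveolar — and hence end-tidal —
CO2 fraction is inversely proportional to alveolar ventilation:

    EtCO2_new * VA_new = EtCO2_baseline * VA_baseline

Alveolar ventilation is ``RR * (VT - VD_total)`` where ``VD_total`` is the
series dead space per breath (circuit plus any sedation-device effective
dead space).  A per-breath washout model provides first-order dynamics
toward the closed-form steady state for step changes in ventilation; it is
used only for dwell-time realism, never for steady-state targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleVentilationError, OutOfDomainError

#: Default functional residual capacity (mL) used by the washout dynamics.
DEFAULT_FRC_ML = 2500.0


@dataclass(frozen=True)
class GasState:
    """Current EtCO2/ventilation pair anchored to a measured baseline.

    The invariant ``etco2 * alveolar_ventilation == baseline_etco2 *
    baseline_alveolar_ventilation`` (constant CO2 inflow) is checked on
    construction.
    """

    etco2: float  # mmHg
    alveolar_ventilation: float  # mL/min
    baseline_etco2: float  # mmHg
    baseline_alveolar_ventilation: float  # mL/min

    def __post_init__(self) -> None:
        for name in (
            "etco2",
            "alveolar_ventilation",
            "baseline_etco2",
            "baseline_alveolar_ventilation",
        ):
            if getattr(self, name) <= 0:
                raise OutOfDomainError(f"{name} must be > 0")
        lhs = self.etco2 * self.alveolar_ventilation
        rhs = self.baseline_etco2 * self.baseline_alveolar_ventilation
        if abs(lhs - rhs) > 1e-6 * rhs:
            raise OutOfDomainError(
                "state violates constant-CO2-inflow conservation: "
                f"{lhs:.6g} != {rhs:.6g}"
            )

    @classmethod
    def anchored(cls, baseline_etco2: float, baseline_alveolar_ventilation: float) -> "GasState":
        """State at the measured baseline itself."""
        return cls(
            etco2=baseline_etco2,
            alveolar_ventilation=baseline_alveolar_ventilation,
            baseline_etco2=baseline_etco2,
            baseline_alveolar_ventilation=baseline_alveolar_ventilation,
        )

    def at_ventilation(self, va_new: float) -> "GasState":
        """The steady state reached at a new alveolar ventilation."""
        return GasState(
            etco2=steady_state_etco2(va_new, self),
            alveolar_ventilation=va_new,
            baseline_etco2=self.baseline_etco2,
            baseline_alveolar_ventilation=self.baseline_alveolar_ventilation,
        )


def alveolar_ventilation(rr: float, vt: float, total_dead_space: float) -> float:
    """Alveolar ventilation ``RR * (VT - VD)`` in mL/min.

    Raises
    ------
    InfeasibleVentilationError
        If the tidal volume does not exceed the total dead space — every
        breath then rebreathes dead-space gas only and CO2 cannot be cleared.
    """
    if vt <= total_dead_space:
        raise InfeasibleVentilationError(
            f"tidal volume {vt} mL <= total dead space {total_dead_space} mL"
        )
    return rr * (vt - total_dead_space)


def steady_state_etco2(va_new: float, state: GasState) -> float:
    """Steady-state EtCO2 (mmHg) at alveolar ventilation ``va_new``."""
    if va_new <= 0:
        raise OutOfDomainError("alveolar ventilation must be > 0")
    return state.baseline_etco2 * state.baseline_alveolar_ventilation / va_new


def washout_to_steady_state(
    state: GasState,
    va_new: float,
    functional_residual_capacity: float = DEFAULT_FRC_ML,
    rr: float = 20.0,
    rel_tol: float = 0.01,
    max_breaths: int = 2000,
) -> np.ndarray:
    """Per-breath EtCO2 sequence after a step change in ventilation.

    Each breath dilutes the alveolar store (FRC) with ``VA/RR`` of fresh
    gas, a first-order relaxation toward the closed-form steady state with
    per-breath gain ``k = VA_b / (FRC + VA_b)``.  The sequence starts at the
    current EtCO2 and stops once within ``rel_tol`` of the target (or at
    ``max_breaths``); its limit is ``steady_state_etco2(va_new, state)``.
    """
    if functional_residual_capacity <= 0:
        raise OutOfDomainError("FRC must be > 0")
    target = steady_state_etco2(va_new, state)
    va_breath = va_new / rr
    k = va_breath / (functional_residual_capacity + va_breath)
    values = [state.etco2]
    e = state.etco2
    for _ in range(max_breaths):
        if abs(e - target) <= rel_tol * target:
            break
        e = e + k * (target - e)
        values.append(e)
    return np.asarray(values)
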