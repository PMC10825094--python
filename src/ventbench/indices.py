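"""Derived lung-stress indices.

* simplified mechanical power (J/min):
  ``MP = 0.098 * RR * VT * (Ppeak - 0.5 * dP)`` with VT in litres
* driving pressure: ``dP = Pplat - PEEP_total`` (cmH2O)
* Costa index: ``4 * dP + RR`` (arbitrary units)
* sevoflurane density correction of measured tidal volume
  (``VT / 0.993`` at an expired fraction of 1.3 %, flow sensors being
  air-calibrated)

All internal computation is on unrounded values; printing rounds half-up.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnitConfusionError
from .mechanics import BreathMechanics

#: J/min per (breaths/min * L * cmH2O): unit conversion of the simplified
#: mechanical-power equation.
MP_CONSTANT = 0.098

#: Air-to-sevoflurane density ratio at 1.3 % expired fraction.
SEVOFLURANE_DENSITY_FACTOR = 0.993


def mechanical_power(rr: float, vt: float, p_peak: float, driving_pressure: float) -> float:
    """Simplified mechanical power (J/min); ``vt`` must be in LITRES."""
    if min(rr, vt, p_peak, driving_pressure) < 0:
        raise ValueError("all inputs must be >= 0")
    if vt > 10:
        raise UnitConfusionError(
            f"tidal volume {vt} is implausible in litres; pass litres, not mL"
        )
    if driving_pressure > p_peak:
        raise ValueError("driving pressure cannot exceed peak pressure")
    return MP_CONSTANT * rr * vt * (p_peak - 0.5 * driving_pressure)


def driving_pressure(p_plat: float, peep_total: float) -> float:
    """Plateau pressure minus total PEEP (cmH2O)."""
    if p_plat < peep_total:
        raise ValueError("plateau pressure below total PEEP")
    return p_plat - peep_total


def costa_index(driving_pressure: float, rr: float) -> float:
    """Composite injury-risk index ``4 * dP + RR`` (a.u.)."""
    if driving_pressure < 0 or rr < 0:
        raise ValueError("inputs must be >= 0")
    return 4.0 * driving_pressure + rr


def correct_vt_density(measured_vt: float) -> float:
    """Sevoflurane density correction of a measured tidal volume (mL)."""
    if measured_vt < 0:
        raise ValueError("tidal volume must be >= 0")
    return measured_vt / SEVOFLURANE_DENSITY_FACTOR


def percent_change(value: float, reference: float) -> float:
    """Percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class DerivedIndices:
    """Indices of one condition row, with optional changes vs control."""

    mechanical_power: float  # J/min
    driving_pressure: float  # cmH2O
    costa_index: float  # a.u.
    vt_corrected: float  # mL (density-corrected when requested)
    mp_pct_change: float | None = None
    dp_pct_change: float | None = None
    costa_pct_change: float | None = None


def compute_indices(
    mechanics: BreathMechanics,
    rr: float,
    vt: float,
    density_correction: bool = False,
    reference: DerivedIndices | None = None,
) -> DerivedIndices:
    """Assemble all indices from simulated breath mechanics.

    ``vt`` is the set tidal volume in mL; the sevoflurane density
    correction is applied only when requested (device arms with
    sevoflurane flowing).
    """
    vt_used = correct_vt_density(vt) if density_correction else vt
    dp = driving_pressure(mechanics.p_plat, mechanics.peep_total)
    mp = mechanical_power(rr, vt_used / 1000.0, mechanics.p_peak, dp)
    costa = costa_index(dp, rr)
    kwargs = {}
    if reference is not None:
        kwargs = dict(
            mp_pct_change=percent_change(mp, reference.mechanical_power),
            dp_pct_change=percent_change(dp, reference.driving_pressure),
            costa_pct_change=percent_change(costa, reference.costa_index),
        )
    return DerivedIndices(
        mechanical_power=mp,
        driving_pressure=dp,
        costa_index=costa,
        vt_corrected=vt_used,
        **kwargs,
    )
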