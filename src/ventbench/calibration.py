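"""Calibrate device effective dead space from EtCO2 observations.

A sedation filter inserted between the Y-piece and the lung adds its
geometric internal volume to the series dead space, plus an additional
"CO2 reflection" component: the reflective medium returns part of the
expired CO2 during the next insufflation.  Both effects are summarised as a
single *effective* dead space per device, obtained by inverting the
constant-CO2-inflow steady-state model at the observed EtCO2 ratio:

    VD_total = VT - (VT - VD_circuit) / ratio

The brute-force counterpart bounds the effective dead space from observed
titration endpoints instead: it scans candidate values and keeps those for
which the titration controller reproduces the endpoint(s).  An empty result
is a model-inconsistency signal (constant dead space cannot explain the
observations), not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import InfeasibleVentilationError, InvalidSettingsError, OutOfDomainError, TitrationError
from .mechanics import LungCircuit, VentilatorSettings


@dataclass(frozen=True)
class SedationDevice:
    """One inhaled-sedation device arm.

    ``effective_dead_space_added`` is the calibrated dead space the device
    adds on top of the circuit dead space; for a reflective filter it is
    expected to exceed the geometric internal volume.
    """

    name: str
    geometric_volume: float  # mL
    effective_dead_space_added: float  # mL
    resistance_insp: float = 0.0  # cmH2O/L/s
    resistance_exp: float = 0.0  # cmH2O/L/s
    fesevo_target: float = 0.013  # expired sevoflurane fraction, metadata

    def __post_init__(self) -> None:
        if self.geometric_volume < 0:
            raise OutOfDomainError("geometric volume must be >= 0")
        if self.effective_dead_space_added < self.geometric_volume:
            # expected (reflection adds dead space) but not enforced
            warnings.warn(
                f"{self.name}: effective added dead space "
                f"{self.effective_dead_space_added:.1f} mL below geometric "
                f"volume {self.geometric_volume:.1f} mL",
                stacklevel=2,
            )

    @property
    def reflection_volume(self) -> float:
        """Effective dead space beyond the geometric volume (mL)."""
        return self.effective_dead_space_added - self.geometric_volume


@dataclass(frozen=True)
class EtCO2Observation:
    """A printed device-induced EtCO2 increase (percent over baseline)."""

    device_name: str
    percent_increase: float
    percent_increase_sd: float = 0.0
    condition_label: str = "ATPD"

    def __post_init__(self) -> None:
        if self.percent_increase <= -100:
            raise OutOfDomainError("percent increase must exceed -100")


def effective_dead_space_from_ratio(
    ratio: float, vt: float, rr: float, physiologic_dead_space: float
) -> float:
    """Total effective dead space (mL) implied by an EtCO2 ratio.

    ``ratio`` is EtCO2-with-device over baseline EtCO2 at unchanged
    settings; ``rr`` is accepted for interface symmetry (the steady-state
    inversion is rate-independent).
    """
    del rr
    if ratio < 1:
        raise OutOfDomainError("ratio < 1 implies a device removing dead space")
    if vt <= physiologic_dead_space:
        raise InfeasibleVentilationError("VT must exceed the circuit dead space")
    return vt - (vt - physiologic_dead_space) / ratio


def device_from_observation(
    observation: EtCO2Observation,
    geometric_volume: float,
    vt: float = 400.0,
    rr: float = 20.0,
    physiologic_dead_space: float = 120.0,
    **device_kwargs,
) -> SedationDevice:
    """Build a calibrated device from a printed EtCO2 increase."""
    total = effective_dead_space_from_ratio(
        1.0 + observation.percent_increase / 100.0, vt, rr, physiologic_dead_space
    )
    return SedationDevice(
        name=observation.device_name,
        geometric_volume=geometric_volume,
        effective_dead_space_added=total - physiologic_dead_space,
        **device_kwargs,
    )


def load_device_catalog(path=None) -> list[dict]:
    """Read the device catalog (packaged default or a user YAML file)."""
    if path is None:
        text = resources.files("ventbench.data").joinpath("devices.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)["devices"]


def default_devices(
    vt: float = 400.0,
    rr: float = 20.0,
    physiologic_dead_space: float = 120.0,
    path=None,
) -> list[SedationDevice]:
    """Calibrated devices from the shipped catalog, at the reference bench
    settings the printed EtCO2 increases were observed under."""
    out = []
    for entry in load_device_catalog(path):
        obs = EtCO2Observation(
            device_name=entry["name"],
            percent_increase=float(entry["etco2_increase_pct"]),
            percent_increase_sd=float(entry.get("etco2_increase_sd_pct", 0.0)),
        )
        out.append(
            device_from_observation(
                obs,
                geometric_volume=float(entry["geometric_volume_mL"]),
                vt=vt,
                rr=rr,
                physiologic_dead_space=physiologic_dead_space,
                resistance_insp=float(entry.get("resistance_insp", 0.0)),
                resistance_exp=float(entry.get("resistance_exp", 0.0)),
            )
        )
    return out


def feasible_dead_space_interval(
    endpoints: dict,
    base: VentilatorSettings,
    lung: LungCircuit,
    target: float = 40.0,
    band: float = 2.0,
    resolution: float = 0.1,
    max_steps: int = 20,
) -> tuple[float, float] | None:
    """Bound the effective total dead space from titration endpoints.

    ``endpoints`` may carry ``final_vt`` (mL) and/or ``final_rr``
    (breaths/min), observed endpoints of the VT- and RR-correction arms.
    Candidate total dead spaces on ``[VD_circuit, VT)`` at ``resolution``
    are kept when the titration controller reproduces every (on-grid)
    endpoint; the (min, max) of the surviving set is returned, or ``None``
    when no candidate survives — a constant effective dead space is then
    inconsistent with the observations.

    Off-grid endpoints (not reachable from the base settings in whole 15 %
    steps) are dropped with a warning rather than snapped to the grid.
    """
    from .titration import titrate  # local import to avoid a cycle

    vt_step = 0.15 * base.tidal_volume_set
    rr_step = 0.15 * base.respiratory_rate

    checks = []
    for key, step, attr in (
        ("final_vt", vt_step, base.tidal_volume_set),
        ("final_rr", rr_step, base.respiratory_rate),
    ):
        if key not in endpoints or endpoints[key] is None:
            continue
        k = (endpoints[key] - attr) / step
        if abs(k - round(k)) > 1e-9 or k < 0:
            warnings.warn(
                f"{key}={endpoints[key]} is off the titration grid "
                f"(base {attr}, step {step}); constraint dropped",
                stacklevel=2,
            )
            continue
        checks.append((key, float(endpoints[key])))

    candidates = np.arange(
        lung.physiologic_dead_space, base.tidal_volume_set, resolution
    )
    matched = []
    for vd_total in candidates:
        probe = SedationDevice(
            name="probe",
            geometric_volume=0.0,
            effective_dead_space_added=float(vd_total) - lung.physiologic_dead_space,
        )
        ok = True
        for key, value in checks:
            mode = "VT" if key == "final_vt" else "RR"
            try:
                res = titrate(
                    mode,
                    probe,
                    base,
                    lung,
                    target=target,
                    band=band,
                    max_steps=max_steps,
                    with_mechanics=False,
                )
            except (TitrationError, InfeasibleVentilationError, InvalidSettingsError):
                ok = False
                break
            got = res.final_vt if key == "final_vt" else res.final_rr
            if abs(got - value) > 1e-9:
                ok = False
                break
        if ok:
            matched.append(float(vd_total))
    if not matched:
        return None
    return (min(matched), max(matched))
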