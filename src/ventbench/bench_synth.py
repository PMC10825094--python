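"""Synthetic bench records: the stand-in for the physical rig.

Produces "measured" records with the structure the analysis pipeline
assumes: the deterministic simulator output passed through the bench's
measurement process — optional zero-mean Gaussian noise (the real bench is
reported deterministic within condition, so noise exists purely to
exercise pipeline robustness) followed by instrument rounding (pressures
to whole cmH2O, EtCO2 to 0.1 mmHg, volumes to 1 mL).

Records regenerate bit-for-bit from the same seed, and with zero noise
they equal the ideal pipeline output after rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment import ConditionResult, ExperimentConfig, run_grid


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero-bound upward (2.5 -> 3), as bench displays do."""
    scale = 10.0**decimals
    return np.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class BenchRecord:
    """One simulated bench measurement of a (condition, arm, state) cell."""

    condition_label: str
    scenario: str
    compliance: float
    peep: float
    arm: str
    state: str
    p_peak: float  # cmH2O, integer-rounded
    p_plat: float
    peep_total: float
    etco2: float  # mmHg, 0.1 resolution
    vt: float  # mL, set value, 1 mL resolution
    rr: float  # breaths/min
    seed: int


def records_from_results(
    results: list[ConditionResult],
    noise_sd_pressure: float = 0.0,
    noise_sd_etco2: float = 0.0,
    seed: int = 0,
) -> list[BenchRecord]:
    """Apply the measurement process to already-computed grid results.

    Split out from :func:`generate_bench_records` so that replicated noise
    draws can reuse one deterministic simulation.
    """
    rng = np.random.default_rng(seed)
    records = []
    for r in results:
        if r.error is not None or r.mechanics is None:
            continue
        noise_p = rng.normal(0.0, noise_sd_pressure, size=3) if noise_sd_pressure else np.zeros(3)
        noise_e = rng.normal(0.0, noise_sd_etco2) if noise_sd_etco2 else 0.0
        records.append(
            BenchRecord(
                condition_label=(
                    f"{r.scenario}_C{r.compliance:g}_PEEP{r.peep:g}"
                ),
                scenario=r.scenario,
                compliance=r.compliance,
                peep=r.peep,
                arm=r.arm,
                state=r.state,
                p_peak=round_half_up(r.mechanics.p_peak + noise_p[0]),
                p_plat=round_half_up(r.mechanics.p_plat + noise_p[1]),
                peep_total=round_half_up(r.mechanics.peep_total + noise_p[2]),
                etco2=round_half_up(r.etco2 + noise_e, 1),
                vt=round_half_up(r.vt),
                rr=r.rr,
                seed=seed,
            )
        )
    return records


def generate_bench_records(
    config: ExperimentConfig,
    noise_sd_pressure: float = 0.0,
    noise_sd_etco2: float = 0.0,
    seed: int = 0,
) -> list[BenchRecord]:
    """Run the full simulator and emit noisy, rounded bench records.

    The default factorial ATPD config yields 72 records (3 compliances x
    2 PEEP x 4 arms x 3 states, control corrections being no-ops); setting
    ``config.emit_ctrl_corrections = False`` drops the control no-op rows.
    """
    results = run_grid(config)
    return records_from_results(results, noise_sd_pressure, noise_sd_etco2, seed)
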