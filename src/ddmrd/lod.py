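"""Limit-of-detection experiments on simulated dilution series.

Runs the full analysis path (gating from controls, classification, Poisson
quantification, calling against an NC cfDNA plate) on a ten-fold dilution
series of tumor gDNA in normal gDNA at fixed total input, and reduces the
per-step calls to a limit of detection.
"""

from __future__ import annotations

from .calling import LoDResult, assess_lod, call_target, estimate_fpr
from .classify import classify_droplets, derive_gates
from .constants import PG_PER_HGE
from .quantify import merge_replicates
from .simulate import (
    AmplitudeModel,
    WellSpec,
    simulate_control_wells,
    simulate_dilution_series,
    simulate_nc_plate,
)


def run_lod_experiment(
    assay: str = "target",
    dilutions: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4),
    total_mass_ng: float = 10.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    amplitude_model: AmplitudeModel | None = None,
    well_spec: WellSpec | None = None,
    nc_wells: int = 12,
) -> LoDResult:
    """Simulate and call one dilution series; return its LoD.

    One well per dilution step; calls are made against a merged
    ``nc_wells``-well NC cfDNA estimate simulated with the same assay and
    ``fp_rate``.
    """
    well_spec = well_spec or WellSpec()
    model = amplitude_model or AmplitudeModel.default([assay], fp_rate=fp_rate)

    series = simulate_dilution_series(
        list(dilutions), total_mass_ng, assay, model, well_spec, seed
    )
    controls = simulate_control_wells([assay], model, well_spec, seed + 10_001)
    nc_plate = simulate_nc_plate(
        nc_wells, fp_rate, model, well_spec, seed=seed + 20_002
    )

    gates = derive_gates(controls, [assay])
    vd = well_spec.droplet_volume_ul
    nc_classified = [classify_droplets(w, gates) for w in nc_plate]
    fpr = estimate_fpr(nc_classified, assay)
    nc_estimate = merge_replicates(nc_classified, assay, vd)

    steps = []
    for well in series:
        cw = classify_droplets(well, gates)
        est = merge_replicates([cw], assay, vd)
        call = call_target(est, nc_estimate, fpr)
        steps.append((well.truth["tumor_mass_pg"], call))
    return assess_lod(steps, target_id=assay)


def hge_loaded(total_mass_ng: float, dilution: float) -> float:
    """Tumor hGE loaded in one well at a dilution step."""
    return total_mass_ng * dilution * 1000.0 / PG_PER_HGE
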