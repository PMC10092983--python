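"""End-to-end orchestration: simulate (or load) a plate, derive gates,
classify, quantify, estimate FPRs and emit MRD calls.

Re-running with the same configuration and seed reproduces byte-identical
outputs; every floating-point value is serialized at fixed precision and
the run log records seeds and constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calling import AssayFPR, TargetCall, call_sample, call_target, estimate_fpr
from .classify import GateSet, classify_droplets, derive_gates
from .config import RunConfig
from .containers import ClassifiedWell, DropletWell
from .quantify import (
    ConcentrationEstimate,
    copies_per_ml_biofluid,
    estimate_concentration,
    hge_to_mass_pg,
    merge_replicates,
    reference_positive_counts,
    total_cfdna_hge_per_ml,
)
from .simulate import (
    AmplitudeModel,
    WellSpec,
    _rng_for_well,
    simulate_control_wells,
    simulate_nc_plate,
    simulate_well,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class SampleResult:
    sample_id: str
    status: str
    target_calls: list[TargetCall]
    per_target_estimates: dict[str, ConcentrationEstimate]
    per_target_copies_per_ml: dict[str, ConcentrationEstimate]
    total_cfdna_hge_per_ml: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class RunResult:
    gates: GateSet
    classified: list[ClassifiedWell]
    fprs: dict[str, AssayFPR]
    nc_estimates: dict[str, ConcentrationEstimate]
    samples: list[SampleResult]
    qc_flags: list[str]
    output_dir: Path | None = None


def simulate_plate(config: RunConfig) -> list[DropletWell]:
    """Build the full synthetic plate a RunConfig describes."""
    spec = WellSpec(
        n_droplets=config.n_droplets,
        droplet_volume_nl=config.constants.droplet_volume_nl,
        reaction_volume_ul=config.constants.reaction_volume_ul,
    )
    model = AmplitudeModel.default(config.targets, fp_rate=config.fp_rate)
    wells = simulate_control_wells(config.targets, model, spec, config.seed)
    wells += simulate_nc_plate(
        config.nc_wells,
        config.fp_rate,
        model,
        spec,
        seed=config.seed + 1,
        reference_concentration=config.nc_reference_concentration,
    )
    widx = 0
    for s in config.samples:
        for rep in range(s.n_replicates):
            wells.append(
                simulate_well(
                    {t: s.target_concentrations.get(t, 0.0) for t in config.targets},
                    s.reference_concentration,
                    model,
                    spec,
                    _rng_for_well(config.seed + 2, widx),
                    well_id=f"S{widx + 1:02d}",
                    sample_id=s.sample_id,
                    role="sample",
                    replicate_group=s.sample_id,
                    biofluid_volume_ml=s.biofluid_volume_ml,
                )
            )
            widx += 1
    return wells


def run_pipeline(
    config: RunConfig,
    wells: list[DropletWell] | None = None,
    write_outputs: bool = True,
) -> RunResult:
    """Execute gate derivation → classification → quantification → calling.

    ``wells`` defaults to the synthetic plate the config describes. Output
    TSVs and a machine-readable run log land in ``config.output_dir``.
    """
    if wells is None:
        wells = simulate_plate(config)
    vd = config.constants.droplet_volume_nl * 1e-3

    try:
        controls = [w for w in wells if w.role in ("NC_gDNA", "PC_gDNA", "NTC")]
        gates = derive_gates(controls, config.targets)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"gate derivation: {e}") from e

    try:
        classified = [classify_droplets(w, gates) for w in wells]
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"classification: {e}") from e

    qc_flags = []
    for cw in classified:
        if cw.role == "NTC":
            positives = sum(cw.target_positive(t) for t in config.targets)
            if positives or cw.reference_positive():
                qc_flags.append(
                    f"plate QC: NTC well {cw.well_id} shows {positives} gated droplets"
                )

    nc_wells = [w for w in classified if w.role == "NC_cfDNA"]
    if not nc_wells:
        raise PipelineError("calling: no NC cfDNA wells on the plate")
    try:
        fprs = {t: estimate_fpr(nc_wells, t) for t in config.targets}
        nc_estimates = {
            t: merge_replicates(nc_wells, t, vd) for t in config.targets
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"FPR estimation: {e}") from e

    sample_results = []
    by_sample: dict[str, list[ClassifiedWell]] = {}
    for cw in classified:
        if cw.role == "sample":
            by_sample.setdefault(cw.sample_id, []).append(cw)

    for sample_id, swells in by_sample.items():
        try:
            estimates = {
                t: merge_replicates(swells, t, vd) for t in config.targets
            }
            calls = [
                call_target(
                    estimates[t],
                    nc_estimates[t],
                    fprs[t],
                    min_droplets=config.constants.min_positive_droplets,
                )
                for t in config.targets
            ]
            status = call_sample(calls)

            flags = []
            per_ml: dict[str, ConcentrationEstimate] = {}
            vol = swells[0].biofluid_volume_ml
            total_hge = None
            if vol is None:
                flags.append("biofluid volume missing; per-mL outputs suppressed")
            else:
                for t in config.targets:
                    per_ml[t] = copies_per_ml_biofluid(
                        estimates[t],
                        reaction_volume_ul=config.constants.reaction_volume_ul,
                        wells=len(swells),
                        biofluid_volume_ml=vol,
                        input_fraction=config.constants.input_fraction,
                    )
                k_ref, n_ref = reference_positive_counts(swells)
                ref_est = estimate_concentration(k_ref, n_ref, vd)
                ref_est.wells_merged = len(swells)
                ref_per_ml = copies_per_ml_biofluid(
                    ref_est,
                    reaction_volume_ul=config.constants.reaction_volume_ul,
                    wells=len(swells),
                    biofluid_volume_ml=vol,
                    input_fraction=config.constants.input_fraction,
                )
                total_hge = total_cfdna_hge_per_ml(
                    reference_copies_per_ml=ref_per_ml.copies_per_ul
                )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"quantification/calling for {sample_id}: {e}") from e

        sample_results.append(
            SampleResult(
                sample_id=sample_id,
                status=status,
                target_calls=calls,
                per_target_estimates=estimates,
                per_target_copies_per_ml=per_ml,
                total_cfdna_hge_per_ml=total_hge,
                flags=flags,
            )
        )

    result = RunResult(
        gates=gates,
        classified=classified,
        fprs=fprs,
        nc_estimates=nc_estimates,
        samples=sample_results,
        qc_flags=qc_flags,
    )
    if write_outputs:
        result.output_dir = _write_outputs(config, result, wells)
    return result


def _fmt(x) -> str:
    return "" if x is None else f"{x:.6g}"


def _write_outputs(config: RunConfig, result: RunResult, wells) -> Path:
    from . import io as ddio

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ddio.write_droplet_csv(wells, out / "droplets.csv")
    ddio.write_manifest_csv(wells, out / "manifest.csv")
    ddio.write_gates_json(result.gates, out / "gates.json")
    ddio.write_classification_tsv(result.classified, out / "classification.tsv")

    quant_rows, call_rows = [], []
    for s in result.samples:
        for t in config.targets:
            est = s.per_target_estimates[t]
            per_ml = s.per_target_copies_per_ml.get(t)
            quant_rows.append(
                {
                    "sample": s.sample_id,
                    "target": t,
                    "k": est.k_positive,
                    "n": est.n_total,
                    "copies_per_ul": _fmt(est.copies_per_ul),
                    "ci_low": _fmt(est.ci_low),
                    "ci_high": _fmt(est.ci_high),
                    "ci_kind": est.ci_kind,
                    "copies_per_ml": _fmt(per_ml.copies_per_ul if per_ml else None),
                    "total_cfdna_hge_per_ml": _fmt(s.total_cfdna_hge_per_ml),
                    "total_cfdna_pg_per_ml": _fmt(
                        hge_to_mass_pg(s.total_cfdna_hge_per_ml)
                        if s.total_cfdna_hge_per_ml is not None
                        else None
                    ),
                }
            )
        for c in s.target_calls:
            call_rows.append(
                {
                    "sample": s.sample_id,
                    "target": c.target_id,
                    "fam_droplets": c.fam_droplets,
                    "ci_nonoverlap": c.ci_nonoverlap,
                    "fpr_events_per_well": f"{float(c.fpr):.2f}",
                    "call": c.call,
                    "sample_status": s.status,
                }
            )
    pd.DataFrame(quant_rows).to_csv(out / "quantification.tsv", sep="\t", index=False)
    pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t", index=False)

    log = {
        "config": config.model_dump(),
        "gates_id": result.gates.fingerprint,
        "fpr_events_per_well": {
            t: f.display for t, f in result.fprs.items()
        },
        "qc_flags": result.qc_flags,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
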