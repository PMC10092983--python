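"""Readers and writers for the plate-text formats the pipeline exchanges.

Droplet tables follow a QX-Manager-export-like dialect: one row per
droplet with columns ``Well, Sample, Ch1Amplitude, Ch2Amplitude`` (FAM,
HEX). The plate manifest carries one row per well: ``Well, Sample, Role,
BiofluidVolumeML, ReplicateGroup``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import GateSet
from .containers import ROLES, ClassifiedWell, DropletWell

DROPLET_COLUMNS = ["Well", "Sample", "Ch1Amplitude", "Ch2Amplitude"]
MANIFEST_COLUMNS = ["Well", "Sample", "Role", "BiofluidVolumeML", "ReplicateGroup"]


def write_droplet_csv(wells: list[DropletWell], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "Well": w.well_id,
                "Sample": w.sample_id,
                "Ch1Amplitude": np.round(w.fam, 4),
                "Ch2Amplitude": np.round(w.hex, 4),
            }
        )
        for w in wells
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_manifest_csv(wells: list[DropletWell], path: str | Path) -> None:
    pd.DataFrame(
        {
            "Well": [w.well_id for w in wells],
            "Sample": [w.sample_id for w in wells],
            "Role": [w.role for w in wells],
            "BiofluidVolumeML": [w.biofluid_volume_ml for w in wells],
            "ReplicateGroup": [w.replicate_group for w in wells],
        }
    ).to_csv(path, index=False)


def read_droplet_csv(path: str | Path, manifest_path: str | Path) -> list[DropletWell]:
    """Load a droplet table joined to its plate manifest.

    Every well in the droplet table must appear in the manifest; malformed
    amplitudes are reported with their line number. Row counts per well are
    preserved exactly.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: droplet table is empty")
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("Ch1Amplitude", "Ch2Amplitude"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: malformed amplitude in column {col} at line {bad[0] + 2}"
            )
        df[col] = vals

    man = pd.read_csv(manifest_path)
    man_missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if man_missing:
        raise ValueError(f"{manifest_path}: missing columns {man_missing}")
    man = man.set_index("Well")
    bad_roles = set(man["Role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"{manifest_path}: unknown roles {sorted(bad_roles)}")

    wells = []
    for well_id, grp in df.groupby("Well", sort=True):
        if well_id not in man.index:
            raise ValueError(f"well {well_id} not present in manifest")
        row = man.loc[well_id]
        vol = row["BiofluidVolumeML"]
        wells.append(
            DropletWell(
                well_id=str(well_id),
                sample_id=str(row["Sample"]),
                role=str(row["Role"]),
                fam=grp["Ch1Amplitude"].to_numpy(),
                hex=grp["Ch2Amplitude"].to_numpy(),
                replicate_group="" if pd.isna(row["ReplicateGroup"]) else str(row["ReplicateGroup"]),
                biofluid_volume_ml=None if pd.isna(vol) else float(vol),
            )
        )
    return wells


def write_classification_tsv(wells: list[ClassifiedWell], path: str | Path) -> None:
    rows = [
        {"well": w.well_id, "sample": w.sample_id, "class": cls, "count": cnt}
        for w in wells
        for cls, cnt in sorted(w.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gates_json(gates: GateSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gates.to_dict(), indent=2, sort_keys=True) + "\n")


def read_gates_json(path: str | Path) -> GateSet:
    return GateSet.from_dict(json.loads(Path(path).read_text()))
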