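"""In-memory containers for droplet-level ddPCR data.

A plate is a list of :class:`DropletWell` objects; classification turns each
into a :class:`ClassifiedWell` holding per-class droplet counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised manifest roles for a well.
ROLES = ("sample", "NC_gDNA", "PC_gDNA", "NTC", "NC_cfDNA")


@dataclass
class DropletWell:
    """Per-droplet two-channel fluorescence amplitudes for one well.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A01"``.
    sample_id : str
        Sample the well belongs to.
    role : str
        One of :data:`ROLES` — patient sample or control type.
    fam, hex : ndarray of float
        End-point fluorescence amplitudes (arbitrary units), one entry per
        accepted droplet, FAM channel (targets) and HEX channel (reference).
    replicate_group : str
        Wells sharing a group are merged as technical replicates.
    biofluid_volume_ml : float or None
        Initial liquid-biopsy volume; absent for controls.
    truth : dict
        Simulator bookkeeping (true template-positive droplet counts per
        target, injected false positives). Empty for wells read from disk.
    """

    well_id: str
    sample_id: str
    role: str
    fam: np.ndarray
    hex: np.ndarray
    replicate_group: str = ""
    biofluid_volume_ml: float | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fam = np.asarray(self.fam, dtype=float)
        self.hex = np.asarray(self.hex, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.fam.shape != self.hex.shape:
            raise ValueError("FAM and HEX amplitude arrays differ in length")
        if self.fam.size and not (
            np.isfinite(self.fam).all() and np.isfinite(self.hex).all()
        ):
            raise ValueError(f"non-finite amplitude in well {self.well_id}")

    @property
    def n_droplets(self) -> int:
        return int(self.fam.size)


@dataclass
class ClassifiedWell:
    """Droplet counts per class for one well.

    Classes are ``empty``, ``reference_only``, ``target_only:<t>``,
    ``target_and_reference:<t>`` for each target ``t``, and ``unassigned``
    (FAM-positive droplets falling in no target gate — rain). Counts always
    sum to ``total_droplets``.
    """

    well_id: str
    sample_id: str
    role: str
    counts: dict[str, int]
    total_droplets: int
    gates_id: str = ""
    replicate_group: str = ""
    biofluid_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative class count")
        if sum(self.counts.values()) != self.total_droplets:
            raise ValueError(
                f"class counts do not sum to total droplets in {self.well_id}"
            )

    def target_positive(self, target_id: str) -> int:
        """Droplets positive for ``target_id`` (with or without reference)."""
        return self.counts.get(f"target_only:{target_id}", 0) + self.counts.get(
            f"target_and_reference:{target_id}", 0
        )

    def reference_positive(self) -> int:
        """Droplets positive in the HEX reference channel."""
        return self.counts.get("reference_only", 0) + sum(
            v for k, v in self.counts.items() if k.startswith("target_and_reference:")
        )
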