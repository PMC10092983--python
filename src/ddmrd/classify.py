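"""Droplet gating: derive amplitude thresholds from control wells and
assign every droplet to a class.

The instrument workflow this replaces is manual 2D threshold review; here
gates are rectangular (a FAM interval per target band crossed with a HEX
threshold for the reference), derived from the negative-control and
positive-control gDNA wells run on each plate. Rectangular gates are
deterministic and auditable, and sufficient for well-separated clusters;
wells whose clusters cannot be separated are reported as errors rather
than gated badly.

Boundary convention: gate intervals are half-open ``[low, high)`` and a
droplet exactly at a threshold is negative, removing the tie-breaking that
manual review leaves implicit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .containers import ClassifiedWell, DropletWell


class GatingError(ValueError):
    """Control wells do not support a usable gate set."""


@dataclass(frozen=True)
class TargetGate:
    target_id: str
    fam_low: float
    fam_high: float


@dataclass(frozen=True)
class GateSet:
    """Amplitude thresholds for one multiplexed assay.

    ``fam_threshold`` separates FAM-negative droplets from anything
    FAM-positive; each target additionally owns a disjoint FAM interval.
    Droplets above ``fam_threshold`` but inside no target interval are rain
    and count as ``unassigned``.
    """

    fam_threshold: float
    hex_threshold: float
    target_gates: tuple[TargetGate, ...]

    def __post_init__(self) -> None:
        gates = sorted(self.target_gates, key=lambda g: g.fam_low)
        for g in gates:
            if g.fam_low >= g.fam_high:
                raise GatingError(f"empty gate for {g.target_id}")
            if g.fam_low <= self.fam_threshold:
                raise GatingError(
                    f"gate for {g.target_id} does not clear the FAM threshold"
                )
        for a, b in zip(gates, gates[1:]):
            if b.fam_low < a.fam_high:
                raise GatingError(
                    f"gates for {a.target_id} and {b.target_id} overlap"
                )

    @property
    def fingerprint(self) -> str:
        """Stable id used to refuse merging wells gated differently."""
        parts = [f"{self.fam_threshold:.4f}", f"{self.hex_threshold:.4f}"] + [
            f"{g.target_id}:{g.fam_low:.4f}:{g.fam_high:.4f}"
            for g in sorted(self.target_gates, key=lambda g: g.target_id)
        ]
        return hashlib.sha1("|".join(parts).encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "fam_threshold": self.fam_threshold,
            "hex_threshold": self.hex_threshold,
            "target_gates": [
                {"target_id": g.target_id, "fam_low": g.fam_low, "fam_high": g.fam_high}
                for g in self.target_gates
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        return cls(
            fam_threshold=float(d["fam_threshold"]),
            hex_threshold=float(d["hex_threshold"]),
            target_gates=tuple(
                TargetGate(g["target_id"], float(g["fam_low"]), float(g["fam_high"]))
                for g in d["target_gates"]
            ),
        )


def _robust_stats(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based SD — insensitive to a few stray positives."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, max(1.4826 * mad, 1e-9)


def _split_two_clusters(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 1D sample at its largest gap into (low, high) clusters."""
    srt = np.sort(values)
    gaps = np.diff(srt)
    cut = int(np.argmax(gaps)) + 1
    return srt[:cut], srt[cut:]


def derive_gates(
    control_wells: list[DropletWell],
    panel: list[str],
    k_sd: float = 7.0,
    band_halfwidth_sd: float = 5.0,
) -> GateSet:
    """Derive a :class:`GateSet` from NC gDNA and PC gDNA control wells.

    The FAM threshold is the NC negative-cluster median plus ``k_sd`` robust
    SDs, capped below the lowest positive-control band. PC FAM positives are
    clustered into ``len(panel)`` bands by the largest-gap rule; each target
    gets an interval centred on its band median with half-width
    ``band_halfwidth_sd`` band SDs, trimmed to stay disjoint. Panel order
    maps to bands in ascending FAM amplitude.
    """
    nc = [w for w in control_wells if w.role == "NC_gDNA"]
    pc = [w for w in control_wells if w.role == "PC_gDNA"]
    if not nc or not pc:
        raise GatingError("need at least one NC_gDNA and one PC_gDNA well")
    if not panel:
        raise GatingError("empty target panel")

    nc_fam = np.concatenate([w.fam for w in nc])
    nc_med, nc_sd = _robust_stats(nc_fam)
    fam_threshold = nc_med + k_sd * nc_sd

    pc_fam = np.concatenate([w.fam for w in pc])
    positives = pc_fam[pc_fam > fam_threshold]
    k = len(panel)
    if positives.size < 10 * k:
        raise GatingError(
            f"unresolvable multiplex: PC wells show too few FAM-positive "
            f"droplets for a {k}-target panel"
        )

    srt = np.sort(positives)
    if k == 1:
        clusters = [srt]
    else:
        gaps = np.diff(srt)
        cut_idx = np.sort(np.argsort(gaps)[-(k - 1):]) + 1
        clusters = np.split(srt, cut_idx)
    if any(c.size < 5 for c in clusters):
        raise GatingError(
            "unresolvable multiplex: PC wells show fewer FAM clusters than targets"
        )
    medians = [float(np.median(c)) for c in clusters]
    sds = [_robust_stats(c)[1] for c in clusters]
    for (m1, s1), (m2, s2) in zip(zip(medians, sds), zip(medians[1:], sds[1:])):
        if m2 - m1 < 5 * max(s1, s2):
            raise GatingError("unresolvable multiplex: FAM bands overlap")

    lowest_band_low = medians[0] - band_halfwidth_sd * sds[0]
    if nc_med + 5 * nc_sd >= lowest_band_low:
        raise GatingError("inseparable assay: NC and PC FAM clusters overlap")
    if fam_threshold >= lowest_band_low:
        fam_threshold = 0.5 * (nc_med + medians[0])

    gates = []
    for i, (t, m, s) in enumerate(zip(panel, medians, sds)):
        half = band_halfwidth_sd * s
        if i > 0:
            half = min(half, 0.45 * (m - medians[i - 1]))
        if i < k - 1:
            half = min(half, 0.45 * (medians[i + 1] - m))
        gates.append(TargetGate(t, m - half, m + half))

    # HEX threshold from NC wells, which carry both empty and
    # reference-positive droplets.
    nc_hex = np.concatenate([w.hex for w in nc])
    low, high = _split_two_clusters(nc_hex)
    if high.size < 5 or low.size < 5:
        # No resolvable reference cluster in NC; fall back to negatives only.
        neg_med, neg_sd = _robust_stats(nc_hex)
        hex_threshold = neg_med + k_sd * neg_sd
    else:
        neg_med, neg_sd = _robust_stats(low)
        pos_med, pos_sd = _robust_stats(high)
        if pos_med - neg_med < 5 * max(neg_sd, pos_sd):
            raise GatingError("inseparable assay: HEX clusters overlap")
        hex_threshold = min(neg_med + k_sd * neg_sd, 0.5 * (neg_med + pos_med))

    return GateSet(
        fam_threshold=float(fam_threshold),
        hex_threshold=float(hex_threshold),
        target_gates=tuple(gates),
    )


def classify_droplets(well: DropletWell, gates: GateSet) -> ClassifiedWell:
    """Assign every droplet in ``well`` to a class under ``gates``.

    Droplet order does not matter; counts conserve the total. FAM-positive
    droplets in no target gate are ``unassigned`` (rain), never dropped.
    """
    if well.n_droplets == 0:
        raise ValueError(f"well {well.well_id} has no droplets")

    fam, hexv = well.fam, well.hex
    hex_pos = hexv > gates.hex_threshold
    fam_pos = fam > gates.fam_threshold

    counts: dict[str, int] = {
        "empty": 0,
        "reference_only": 0,
        "unassigned": 0,
    }
    in_any_gate = np.zeros(well.n_droplets, dtype=bool)
    for g in gates.target_gates:
        in_gate = (fam >= g.fam_low) & (fam < g.fam_high)
        in_any_gate |= in_gate
        counts[f"target_only:{g.target_id}"] = int((in_gate & ~hex_pos).sum())
        counts[f"target_and_reference:{g.target_id}"] = int((in_gate & hex_pos).sum())

    unassigned = fam_pos & ~in_any_gate
    counts["unassigned"] = int(unassigned.sum())
    neg = ~fam_pos & ~in_any_gate
    counts["empty"] = int((neg & ~hex_pos).sum())
    counts["reference_only"] = int((neg & hex_pos).sum())

    return ClassifiedWell(
        well_id=well.well_id,
        sample_id=well.sample_id,
        role=well.role,
        counts=counts,
        total_droplets=well.n_droplets,
        gates_id=gates.fingerprint,
        replicate_group=well.replicate_group,
        biofluid_volume_ml=well.biofluid_volume_ml,
    )
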