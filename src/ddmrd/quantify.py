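"""Poisson quantification of droplet counts and unit conversions.

With ``k`` positive droplets of ``n``, the mean occupancy per droplet is
``lambda = -ln(1 - k/n)`` and the template concentration is
``lambda / V_d`` copies/uL of reaction. The 95% "Poisson" interval is the
exact Clopper-Pearson interval on the positive fraction pushed through the
same transform — exact small-count behaviour matters because MRD decisions
ride on k in the single digits. Replicate wells are pooled by summing
counts; the "total error" interval additionally accounts for between-well
scatter via a t interval over per-well concentrations, and the wider of the
two is reported.

Downstream conversions express concentrations as copies per mL of the
original biofluid (correcting for the fraction of the cfDNA eluate loaded),
as haploid genomic equivalents (hGE), and as DNA mass at 3.3 pg/hGE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import INPUT_FRACTION, PG_PER_HGE, REACTION_VOLUME_UL, droplet_volume_ul
from .containers import ClassifiedWell


@dataclass
class ConcentrationEstimate:
    """Template concentration from pooled droplet counts, with 95% CI."""

    k_positive: int
    n_total: int
    lam: float
    copies_per_ul: float
    ci_low: float
    ci_high: float
    ci_kind: str  # "poisson" | "total"
    droplet_volume: float  # uL
    wells_merged: int = 1
    saturated: bool = False
    per_well_copies_per_ul: list[float] = field(default_factory=list)

    def scaled(self, factor: float) -> "ConcentrationEstimate":
        """Same estimate with point and CI multiplied by ``factor``."""
        out = ConcentrationEstimate(**{**self.__dict__})
        out.copies_per_ul = self.copies_per_ul * factor
        out.ci_low = self.ci_low * factor
        out.ci_high = self.ci_high * factor
        return out


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _p_to_conc(p: float, vd: float) -> float:
    if p >= 1.0:
        return math.inf
    return -math.log1p(-p) / vd


def estimate_concentration(
    k: int, n: int, droplet_volume: float | None = None
) -> ConcentrationEstimate:
    """Concentration (copies/uL of reaction) from ``k`` positives of ``n``.

    ``droplet_volume`` is in uL (default the QX200 nominal 0.85 nL). A
    saturated well (k == n) is flagged rather than given a finite estimate.
    """
    vd = droplet_volume if droplet_volume is not None else droplet_volume_ul()
    if n <= 0:
        raise ValueError("need at least one droplet")
    if not 0 <= k <= n:
        raise ValueError("positive count outside [0, n]")
    p_lo, p_hi = _clopper_pearson(k, n)
    if k == n:
        return ConcentrationEstimate(
            k_positive=k,
            n_total=n,
            lam=math.inf,
            copies_per_ul=math.inf,
            ci_low=_p_to_conc(p_lo, vd),
            ci_high=math.inf,
            ci_kind="poisson",
            droplet_volume=vd,
            saturated=True,
        )
    lam = -math.log1p(-k / n) + 0.0  # normalize -0.0 at k = 0
    return ConcentrationEstimate(
        k_positive=k,
        n_total=n,
        lam=lam,
        copies_per_ul=lam / vd,
        ci_low=_p_to_conc(p_lo, vd),
        ci_high=_p_to_conc(p_hi, vd),
        ci_kind="poisson",
        droplet_volume=vd,
    )


def merge_replicates(
    wells: list[ClassifiedWell],
    target: str,
    droplet_volume: float | None = None,
) -> ConcentrationEstimate:
    """Pool replicate wells for one target and attach a total-error CI.

    Counts are summed across wells and quantified as one large partition
    experiment. With >= 2 wells the reported interval is the wider of the
    pooled Clopper-Pearson (Poisson) interval and a t interval over the
    per-well concentrations; ``ci_kind`` records which one won.
    """
    if not wells:
        raise ValueError("no wells to merge")
    gate_ids = {w.gates_id for w in wells}
    if len(gate_ids) > 1:
        raise ValueError("cannot merge wells classified under different gate sets")
    vd = droplet_volume if droplet_volume is not None else droplet_volume_ul()

    ks = [w.target_positive(target) for w in wells]
    ns = [w.total_droplets for w in wells]
    pooled = estimate_concentration(sum(ks), sum(ns), vd)
    pooled.wells_merged = len(wells)
    per_well = [estimate_concentration(k, n, vd).copies_per_ul for k, n in zip(ks, ns)]
    pooled.per_well_copies_per_ul = per_well

    if len(wells) >= 2 and not pooled.saturated and all(np.isfinite(per_well)):
        m = len(per_well)
        mean = float(np.mean(per_well))
        sd = float(np.std(per_well, ddof=1))
        tq = float(stats.t.ppf(0.975, m - 1))
        t_lo = max(0.0, mean - tq * sd / math.sqrt(m))
        t_hi = mean + tq * sd / math.sqrt(m)
        if (t_hi - t_lo) > (pooled.ci_high - pooled.ci_low):
            pooled.ci_low, pooled.ci_high = t_lo, t_hi
            pooled.ci_kind = "total"
    return pooled


def reference_positive_counts(wells: list[ClassifiedWell]) -> tuple[int, int]:
    """Pooled (k, n) of HEX reference-positive droplets across wells."""
    return sum(w.reference_positive() for w in wells), sum(
        w.total_droplets for w in wells
    )


def copies_per_ml_biofluid(
    merged: ConcentrationEstimate,
    reaction_volume_ul: float = REACTION_VOLUME_UL,
    wells: int | None = None,
    biofluid_volume_ml: float | None = None,
    input_fraction: float = INPUT_FRACTION,
) -> ConcentrationEstimate:
    """Express a merged reaction concentration as copies/mL of biofluid.

    Copies detected = copies/uL x reaction volume x number of wells; scaled
    up by 1/``input_fraction`` (the share of the eluate loaded, 33 of
    40 uL) and divided by the initial biofluid volume. CI endpoints are
    transformed identically.
    """
    if biofluid_volume_ml is None or biofluid_volume_ml <= 0:
        raise ValueError("biofluid volume missing or non-positive")
    n_wells = wells if wells is not None else merged.wells_merged
    factor = reaction_volume_ul * n_wells / input_fraction / biofluid_volume_ml
    return merged.scaled(factor)


def total_cfdna_hge_per_ml(
    reference_copies_per_ml: float | None = None,
    wt_copies_per_ml: float | None = None,
    mutant_copies_per_ml: float | None = None,
) -> float:
    """Total cfDNA in hGE/mL from either quantification mode.

    Reference-gene mode: one reference locus per haploid genome, so hGE/mL
    equals the reference copies/mL. SNV mode: wild-type plus mutant copies
    of the SNV locus together count every haploid genome present.
    """
    if reference_copies_per_ml is not None:
        return float(reference_copies_per_ml)
    if wt_copies_per_ml is not None and mutant_copies_per_ml is not None:
        return float(wt_copies_per_ml) + float(mutant_copies_per_ml)
    raise ValueError(
        "need either a reference-gene concentration or wt + mutant SNV concentrations"
    )


def hge_to_mass_pg(hge: float) -> float:
    """hGE -> picograms at 3.3 pg per haploid genome."""
    if hge < 0:
        raise ValueError("negative input")
    return hge * PG_PER_HGE


def mass_pg_to_hge(mass_pg: float) -> float:
    """Picograms -> hGE at 3.3 pg per haploid genome."""
    if mass_pg < 0:
        raise ValueError("negative input")
    return mass_pg / PG_PER_HGE


def hge_mass_convert(value: float, direction: str) -> float:
    """Convert between hGE and DNA mass (pg); full precision, no rounding."""
    if direction == "hge_to_mass":
        return hge_to_mass_pg(value)
    if direction == "mass_to_hge":
        return mass_pg_to_hge(value)
    raise ValueError("direction must be 'hge_to_mass' or 'mass_to_hge'")


def display_hge(hge: float) -> int:
    """hGE rounded to an integer for reporting."""
    return int(round(hge))


def display_mass(mass_pg: float) -> str:
    """Mass for reporting: >= 1 ng shown in ng to one decimal, else pg."""
    if mass_pg >= 1000:
        return f"{mass_pg / 1000:.1f} ng"
    return f"{mass_pg:.0f} pg"


@dataclass
class SampleQuant:
    """Per-sample quantification summary."""

    sample_id: str
    biofluid_volume_ml: float | None
    per_target_copies_per_ml: dict[str, ConcentrationEstimate]
    total_cfdna_hge_per_ml: float | None
    total_cfdna_mass_per_ml_pg: float | None
    input_fraction: float = INPUT_FRACTION
    flags: list[str] = field(default_factory=list)
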