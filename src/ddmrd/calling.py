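"""MRD decision rules: assay false-positive rates, per-target and
per-sample positivity calls, and limit-of-detection assessment.

A target is called **positive** when at least 3 merged FAM droplets are
seen and the sample's 95% concentration interval lies entirely above the
negative-control cfDNA interval ("no overlapping error bars").
A borderline target is **trace positive** when >= 3 droplets are seen on an
assay whose measured false-positive rate is zero, even though the intervals
overlap. Everything else is negative. CI separation is tested before the
zero-FPR rule so unambiguous positives are never downgraded.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .constants import FPR_EVENTS_PER_ML_FACTOR, MIN_POSITIVE_DROPLETS
from .containers import ClassifiedWell
from .quantify import ConcentrationEstimate

CALL_POSITIVE = "positive"
CALL_TRACE = "trace_positive"
CALL_NEGATIVE = "negative"


@dataclass
class AssayFPR:
    """False-positive rate of one assay, in events per NC cfDNA well."""

    target_id: str
    total_events: int
    n_wells: int

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("FPR needs at least one NC well")
        if self.total_events < 0:
            raise ValueError("negative event count")

    @property
    def fpr_events_per_well(self) -> Fraction:
        # Exact rational; rounding happens only at display time.
        return Fraction(self.total_events, self.n_wells)

    @property
    def display(self) -> str:
        return f"{float(self.fpr_events_per_well):.2f}"

    def events_per_ml(self, factor: float = FPR_EVENTS_PER_ML_FACTOR) -> float:
        """Events per mL of NC plasma; conversion factor is configurable."""
        return float(self.fpr_events_per_well) * factor


@dataclass
class TargetCall:
    """Per-assay MRD decision with its supporting evidence."""

    target_id: str
    fam_droplets: int
    sample_ci: tuple[float, float]
    nc_ci: tuple[float, float]
    ci_nonoverlap: bool
    fpr: Fraction
    call: str


@dataclass
class LoDResult:
    """Limit of detection from a dilution-series of calls."""

    target_id: str
    steps: list[tuple[float, str]]  # (tumor mass pg, call)
    lod_mass_pg: float | None
    monotone: bool

    @property
    def display(self) -> str:
        if self.lod_mass_pg is None:
            return f"> {max(m for m, _ in self.steps):g} pg"
        return f"{self.lod_mass_pg:g} pg"


def estimate_fpr(nc_wells: list[ClassifiedWell], target: str) -> AssayFPR:
    """Total target-band events across NC cfDNA wells, per well."""
    if not nc_wells:
        raise ValueError("no NC wells")
    total = sum(w.target_positive(target) for w in nc_wells)
    return AssayFPR(target_id=target, total_events=total, n_wells=len(nc_wells))


def call_target(
    sample_estimate: ConcentrationEstimate,
    nc_estimate: ConcentrationEstimate | None,
    fpr: AssayFPR,
    min_droplets: int = MIN_POSITIVE_DROPLETS,
) -> TargetCall:
    """Apply the positive / trace-positive / negative cascade to one assay.

    Calls are defined relative to the NC cfDNA wells run on the same plate,
    so a missing NC estimate is an error, not a default.
    """
    if nc_estimate is None:
        raise ValueError("MRD calls require the NC cfDNA estimate")
    if sample_estimate.droplet_volume != nc_estimate.droplet_volume:
        raise ValueError("sample and NC estimates use different droplet volumes")

    k = sample_estimate.k_positive
    nonoverlap = sample_estimate.ci_low > nc_estimate.ci_high
    if k < min_droplets:
        call = CALL_NEGATIVE
    elif nonoverlap:
        call = CALL_POSITIVE
    elif fpr.fpr_events_per_well == 0:
        call = CALL_TRACE
    else:
        call = CALL_NEGATIVE
    return TargetCall(
        target_id=fpr.target_id,
        fam_droplets=k,
        sample_ci=(sample_estimate.ci_low, sample_estimate.ci_high),
        nc_ci=(nc_estimate.ci_low, nc_estimate.ci_high),
        ci_nonoverlap=bool(nonoverlap),
        fpr=fpr.fpr_events_per_well,
        call=call,
    )


def call_sample(target_calls: list[TargetCall]) -> str:
    """Sample-level MRD status: any positive target wins, then any trace."""
    if not target_calls:
        raise ValueError("no target calls for sample")
    calls = {c.call for c in target_calls}
    if CALL_POSITIVE in calls:
        return CALL_POSITIVE
    if CALL_TRACE in calls:
        return CALL_TRACE
    return CALL_NEGATIVE


def assess_lod(
    series: list[tuple[float, TargetCall | str]],
    target_id: str = "",
) -> LoDResult:
    """LoD from a dilution series: smallest tumor mass called positive with
    every larger mass positive too. Trace-positive does not count as
    detected. A series where a positive reappears below a negative step is
    flagged non-monotone; the LoD then reflects only the uninterrupted run
    of positives from the top.
    """
    if len(series) < 2:
        raise ValueError("need at least two dilution steps")
    masses = [m for m, _ in series]
    if any(b >= a for a, b in zip(masses, masses[1:])):
        raise ValueError("masses must be strictly decreasing")
    steps = [
        (m, c.call if isinstance(c, TargetCall) else str(c)) for m, c in series
    ]
    if not target_id:
        tids = {c.target_id for _, c in series if isinstance(c, TargetCall)}
        target_id = tids.pop() if len(tids) == 1 else ""

    lod = None
    for m, call in steps:
        if call == CALL_POSITIVE:
            lod = m
        else:
            break
    monotone = all(
        call != CALL_POSITIVE for m, call in steps if lod is None or m < lod
    )
    return LoDResult(target_id=target_id, steps=steps, lod_mass_pg=lod, monotone=monotone)
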