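"""Somatic variant filter chains and ddPCR target prioritization.

Turns annotated somatic call sets (Mutect2-style SNV/indels, Manta-style
SVs with a matched normal) into a ranked panel of patient-specific assay
targets. The SNV chain retains PASS calls with tumor alternate allele
count >= 5 whose annotations satisfy
``(MAX_AF <= 0.001 or absent) and (CADD_PHRED >= 20 or absent) and
IMPACT in {HIGH, MODERATE}``; the SV chain retains PASS calls with PR >= 5
and SR >= 5 in the tumor, at most one supporting read in the normal, and
SOMATICSCORE >= 50. Population-frequency and CADD annotations may be
absent without penalty (rare/novel variants are often unscored); a missing
IMPACT or missing SV support field fails the record as unannotated.

Prioritization ranks survivors by gene-list tier (disease-recurrent genes,
then a cancer gene census, then everything else) and within a tier by read
support (alternate allele count for SNVs, min(PR, SR) for SVs), aiming for
>= 2 targets per patient, ideally mixing one SNV and one SV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pysam

SNV = "snv_indel"
SV = "sv"


@dataclass
class VariantRecord:
    """One somatic candidate with the annotations the filter chain tests."""

    kind: str  # SNV or SV
    chrom: str
    pos: int  # 1-based
    ref: str = ""
    alt: str = ""
    end: int | None = None  # SV second breakpoint
    svtype: str | None = None
    filter_status: str = "PASS"
    alt_allele_count: int | None = None
    max_af: float | None = None
    cadd_phred: float | None = None
    impact: str | None = None
    pr_tumor: int | None = None
    sr_tumor: int | None = None
    normal_support: int | None = None
    somaticscore: float | None = None
    gene: str | None = None

    @property
    def support(self) -> int:
        """Read support used for ranking."""
        if self.kind == SNV:
            return self.alt_allele_count or 0
        return min(self.pr_tumor or 0, self.sr_tumor or 0)

    @property
    def locus(self) -> str:
        if self.kind == SNV:
            return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"
        return f"{self.chrom}:{self.pos}-{self.end} {self.svtype or 'SV'}"


@dataclass
class SelectionCriteria:
    """Thresholds of the retention filters and the prioritization."""

    snv_min_alt_count: int = 5
    snv_max_af: float = 0.001
    snv_min_cadd: float = 20.0
    snv_impacts: frozenset = frozenset({"HIGH", "MODERATE"})
    sv_min_pr: int = 5
    sv_min_sr: int = 5
    sv_max_normal_support: int = 1
    sv_min_somaticscore: float = 50.0
    require_pass: bool = True
    min_targets_per_patient: int = 2


def _snv_reject_reason(r: VariantRecord, c: SelectionCriteria) -> str | None:
    if c.require_pass and r.filter_status != "PASS":
        return "not PASS"
    if r.alt_allele_count is None:
        return "unannotated: alternate allele count"
    if r.alt_allele_count < c.snv_min_alt_count:
        return f"alt allele count < {c.snv_min_alt_count}"
    if r.max_af is not None and r.max_af > c.snv_max_af:
        return f"MAX_AF > {c.snv_max_af}"
    if r.cadd_phred is not None and r.cadd_phred < c.snv_min_cadd:
        return f"CADD_PHRED < {c.snv_min_cadd}"
    if r.impact is None:
        return "unannotated: IMPACT"
    if r.impact not in c.snv_impacts:
        return "IMPACT not HIGH/MODERATE"
    return None


def _sv_reject_reason(r: VariantRecord, c: SelectionCriteria) -> str | None:
    if c.require_pass and r.filter_status != "PASS":
        return "not PASS"
    if r.pr_tumor is None:
        return "unannotated: PR"
    if r.sr_tumor is None:
        return "unannotated: SR"
    if r.pr_tumor < c.sv_min_pr:
        return f"PR < {c.sv_min_pr}"
    if r.sr_tumor < c.sv_min_sr:
        return f"SR < {c.sv_min_sr}"
    if r.normal_support is None or r.normal_support > c.sv_max_normal_support:
        return f"normal support > {c.sv_max_normal_support}"
    if r.somaticscore is None or r.somaticscore < c.sv_min_somaticscore:
        return f"SOMATICSCORE < {c.sv_min_somaticscore}"
    return None


def filter_somatic_snv(
    records: list[VariantRecord],
    criteria: SelectionCriteria | None = None,
    explain: bool = False,
):
    """Retain SNV/indel records passing the somatic filter chain.

    Order-preserving; with ``explain=True`` also returns a list of
    (record, reason) rejections.
    """
    c = criteria or SelectionCriteria()
    retained, rejected = [], []
    for r in records:
        if r.kind != SNV:
            raise ValueError(f"expected {SNV} records, got {r.kind}")
        reason = _snv_reject_reason(r, c)
        if reason is None:
            retained.append(r)
        else:
            rejected.append((r, reason))
    return (retained, rejected) if explain else retained


def filter_somatic_sv(
    records: list[VariantRecord],
    criteria: SelectionCriteria | None = None,
    explain: bool = False,
):
    """Retain SV records passing the somatic filter chain (see module doc)."""
    c = criteria or SelectionCriteria()
    retained, rejected = [], []
    for r in records:
        if r.kind != SV:
            raise ValueError(f"expected {SV} records, got {r.kind}")
        reason = _sv_reject_reason(r, c)
        if reason is None:
            retained.append(r)
        else:
            rejected.append((r, reason))
    return (retained, rejected) if explain else retained


# --- prioritization -------------------------------------------------------

TIER_RECURRENT = 0
TIER_CENSUS = 1
TIER_OTHER = 2
_TIER_NAMES = {TIER_RECURRENT: "recurrent", TIER_CENSUS: "census", TIER_OTHER: "other"}


@dataclass
class RankedTarget:
    record: VariantRecord
    tier: int
    support: int
    selected: bool = False

    @property
    def tier_name(self) -> str:
        return _TIER_NAMES[self.tier]


@dataclass
class Panel:
    """Ranked candidates plus the selected assay panel for one patient."""

    ranked: list[RankedTarget]
    selected: list[RankedTarget]
    under_target: bool
    warnings: list[str] = field(default_factory=list)


def load_gene_list(path: str | Path) -> frozenset:
    """One gene symbol per line; '#' comments and blanks ignored."""
    lines = Path(path).read_text().splitlines()
    return frozenset(
        ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")
    )


def bundled_gene_lists() -> dict[str, frozenset]:
    """Editable starter lists shipped with the package.

    ``mb_recurrent``: genes recurrently altered in medulloblastoma;
    ``cancer_census``: a starter subset of well-established cancer genes.
    Replace with full curated lists for production use.
    """
    out = {}
    for name in ("mb_recurrent", "cancer_census"):
        ref = resources.files("ddmrd.data.gene_lists") / f"{name}.txt"
        with resources.as_file(ref) as p:
            out[name] = load_gene_list(p)
    return out


def _tier(record: VariantRecord, gene_lists: dict[str, frozenset]) -> int:
    gene = record.gene
    if gene and gene in gene_lists.get("mb_recurrent", frozenset()):
        return TIER_RECURRENT
    if gene and gene in gene_lists.get("cancer_census", frozenset()):
        return TIER_CENSUS
    return TIER_OTHER


def prioritize_targets(
    records: list[VariantRecord],
    gene_lists: dict[str, frozenset] | None = None,
    min_targets: int = 2,
) -> Panel:
    """Rank retained variants and select an assay panel.

    Rank key: gene-list tier, then read support descending. The selected
    panel takes the best-ranked candidate, then prefers the best candidate
    of the other variant kind (SNV vs SV) when both kinds survive, then
    fills by rank up to ``min_targets``. Fewer survivors than
    ``min_targets`` sets the under-target flag.
    """
    gene_lists = gene_lists if gene_lists is not None else bundled_gene_lists()
    ranked = sorted(
        (RankedTarget(r, _tier(r, gene_lists), r.support) for r in records),
        key=lambda t: (t.tier, -t.support),
    )
    warnings = []
    if not ranked:
        return Panel(ranked=[], selected=[], under_target=True,
                     warnings=["no surviving variants"])

    selected: list[RankedTarget] = [ranked[0]]
    kinds_present = {t.record.kind for t in ranked}
    if len(kinds_present) > 1 and min_targets >= 2:
        other_kind = (kinds_present - {ranked[0].record.kind}).pop()
        best_other = next(t for t in ranked if t.record.kind == other_kind)
        selected.append(best_other)
    for t in ranked:
        if len(selected) >= min_targets:
            break
        if t not in selected:
            selected.append(t)
    for t in selected:
        t.selected = True
    under = len(ranked) < min_targets
    if under:
        warnings.append(
            f"only {len(ranked)} candidate(s) survive; {min_targets} requested"
        )
    return Panel(ranked=ranked, selected=selected, under_target=under,
                 warnings=warnings)


def intersect_timepoints(
    primary: list[VariantRecord],
    relapse: list[VariantRecord],
    sv_window: int = 10,
) -> list[VariantRecord]:
    """Variants shared between primary and relapse call sets.

    SNVs match on exact (chrom, pos, ref, alt); SVs match on type, chrom,
    and both breakpoints agreeing within ``sv_window`` bp. Returns the
    primary-tumor records, preserving order.
    """
    snv_keys = {
        (r.chrom, r.pos, r.ref, r.alt) for r in relapse if r.kind == SNV
    }
    relapse_svs = [r for r in relapse if r.kind == SV]

    def sv_match(a: VariantRecord) -> bool:
        for b in relapse_svs:
            if a.chrom != b.chrom or (a.svtype or "") != (b.svtype or ""):
                continue
            if abs(a.pos - b.pos) <= sv_window and abs(
                (a.end or a.pos) - (b.end or b.pos)
            ) <= sv_window:
                return True
        return False

    shared = []
    for r in primary:
        if r.kind == SNV and (r.chrom, r.pos, r.ref, r.alt) in snv_keys:
            shared.append(r)
        elif r.kind == SV and sv_match(r):
            shared.append(r)
    return shared


# --- VCF readers ----------------------------------------------------------


def _info_scalar(rec, key):
    val = rec.info.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0]
    return val


def read_snv_vcf(path: str | Path, tumor_sample: str | None = None) -> list[VariantRecord]:
    """Read an annotated SNV/indel VCF into :class:`VariantRecord` objects.

    The tumor alternate allele count comes from the tumor sample's AD
    field; ``tumor_sample`` defaults to a sample named TUMOR, else the
    first sample.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        tumor = tumor_sample or ("TUMOR" if "TUMOR" in samples else samples[0] if samples else None)
        for rec in vcf:
            filters = list(rec.filter.keys())
            alt_count = None
            if tumor is not None and "AD" in rec.format:
                ad = rec.samples[tumor].get("AD")
                if ad is not None and len(ad) > 1 and ad[1] is not None:
                    alt_count = int(ad[1])
            impact = _info_scalar(rec, "IMPACT")
            out.append(
                VariantRecord(
                    kind=SNV,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref or "",
                    alt=rec.alts[0] if rec.alts else "",
                    filter_status=filters[0] if filters else "PASS",
                    alt_allele_count=alt_count,
                    max_af=_maybe_float(_info_scalar(rec, "MAX_AF")),
                    cadd_phred=_maybe_float(_info_scalar(rec, "CADD_PHRED")),
                    impact=str(impact) if impact is not None else None,
                    gene=_maybe_str(_info_scalar(rec, "GENE")),
                )
            )
    return out


def read_sv_vcf(
    path: str | Path,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> list[VariantRecord]:
    """Read a somatic SV VCF (Manta-style PR/SR support) into records.

    ``normal_support`` is the sum of alt-supporting PR and SR reads in the
    matched normal sample.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        tumor = tumor_sample or ("TUMOR" if "TUMOR" in samples else samples[0] if samples else None)
        normal = normal_sample or (
            "NORMAL" if "NORMAL" in samples else (samples[1] if len(samples) > 1 else None)
        )

        def alt_reads(rec, sample, key):
            if sample is None or key not in rec.format:
                return None
            val = rec.samples[sample].get(key)
            if val is None or len(val) < 2 or val[1] is None:
                return None
            return int(val[1])

        for rec in vcf:
            filters = list(rec.filter.keys())
            pr_n = alt_reads(rec, normal, "PR") or 0
            sr_n = alt_reads(rec, normal, "SR") or 0
            out.append(
                VariantRecord(
                    kind=SV,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    end=rec.stop,
                    svtype=_maybe_str(_info_scalar(rec, "SVTYPE")),
                    filter_status=filters[0] if filters else "PASS",
                    pr_tumor=alt_reads(rec, tumor, "PR"),
                    sr_tumor=alt_reads(rec, tumor, "SR"),
                    normal_support=pr_n + sr_n,
                    somaticscore=_maybe_float(_info_scalar(rec, "SOMATICSCORE")),
                    gene=_maybe_str(_info_scalar(rec, "GENE")),
                )
            )
    return out


def _maybe_float(v):
    return None if v is None else float(v)


def _maybe_str(v):
    return None if v is None else str(v)
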