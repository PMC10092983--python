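"""Synthetic somatic VCF pairs with known filter-chain truth.

Generates Mutect2-style SNV/indel and Manta-style SV call sets carrying
exactly the annotation fields the retention filters test, together with a
truth table recording which records were constructed to survive. Failing
records violate exactly one randomly chosen criterion, so every branch of
the filter expressions is exercised.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .targets import SelectionCriteria

_CONTIGS = [(f"chr{i}", 248_000_000) for i in list(range(1, 23))] + [
    ("chrX", 156_000_000),
    ("chrY", 57_000_000),
]
_BASES = np.array(list("ACGT"))

# Pools the simulator draws gene symbols from; mixed tiers so that
# prioritization has something to rank.
_GENES_RECURRENT = ["CTNNB1", "PTCH1", "KMT2D", "KDM6A", "SNCAIP", "CSNK2B", "MAX"]
_GENES_CENSUS = ["PIK3CA", "TP53", "BRAF", "SMARCA4", "FBXW7", "PRMT7"]
_GENES_OTHER = ["ZNF536", "SAMD8", "KLHL15", "HEXB", "CAB39L", "FOSL2X", "LOC101"]

_SNV_FAIL_MODES = ("filter", "alt_count", "max_af", "cadd", "impact", "impact_missing")
_SV_FAIL_MODES = ("filter", "pr", "sr", "normal", "somaticscore")


def _snv_header() -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in _CONTIGS:
        h.contigs.add(name, length=length)
    h.filters.add("germline", None, None, "Evidence of germline origin")
    h.filters.add("weak_evidence", None, None, "Insufficient somatic evidence")
    h.info.add("MAX_AF", 1, "Float", "Maximum population allele frequency")
    h.info.add("CADD_PHRED", 1, "Float", "CADD PHRED-scaled deleteriousness score")
    h.info.add("IMPACT", 1, "String", "Predicted consequence impact class")
    h.info.add("GENE", 1, "String", "Gene symbol")
    h.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    h.formats.add("DP", 1, "Integer", "Read depth")
    h.add_sample("TUMOR")
    h.add_sample("NORMAL")
    return h


def _sv_header() -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in _CONTIGS:
        h.contigs.add(name, length=length)
    h.filters.add("MinSomaticScore", None, None, "Somatic score below threshold")
    h.info.add("SVTYPE", 1, "String", "Type of structural variant")
    h.info.add("END", 1, "Integer", "End position of the variant")
    h.info.add("SOMATICSCORE", 1, "Integer", "Somatic variant quality score")
    h.info.add("GENE", 1, "String", "Gene symbol at the breakpoint")
    h.formats.add("PR", ".", "Integer", "Spanning paired-read support (ref, alt)")
    h.formats.add("SR", ".", "Integer", "Split-read support (ref, alt)")
    h.add_sample("TUMOR")
    h.add_sample("NORMAL")
    return h


def _draw_gene(rng: np.random.Generator) -> str:
    pool = [_GENES_RECURRENT, _GENES_CENSUS, _GENES_OTHER][
        rng.choice(3, p=[0.25, 0.25, 0.5])
    ]
    return str(pool[rng.integers(len(pool))])


def simulate_somatic_vcf_pair(
    n_snv: int,
    n_sv: int,
    fraction_passing: float,
    seed: int,
    out_dir: str | Path,
    criteria: SelectionCriteria | None = None,
) -> tuple[Path, Path, pd.DataFrame]:
    """Write a synthetic (SNV VCF, SV VCF) pair plus a truth table.

    A ``fraction_passing`` share of records satisfies every retention
    criterion (boundary values included occasionally); each remaining
    record violates exactly one. Returns the two VCF paths and a DataFrame
    with one row per record: id, kind, should_pass, fail_mode.
    """
    if n_snv < 0 or n_sv < 0:
        raise ValueError("record counts must be non-negative")
    if not 0 <= fraction_passing <= 1:
        raise ValueError("fraction_passing must lie in [0, 1]")
    c = criteria or SelectionCriteria()
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snv_path = out_dir / "somatic_snv.vcf"
    sv_path = out_dir / "somatic_sv.vcf"
    truth_rows = []

    # positions ascending within a contig for valid VCF ordering
    def positions(n):
        contigs = sorted(
            (str(_CONTIGS[i][0]) for i in rng.integers(0, len(_CONTIGS), n)),
            key=lambda s: [x[0] for x in _CONTIGS].index(s),
        )
        pos_by_contig: dict[str, list[int]] = {}
        for ctg in contigs:
            pos_by_contig.setdefault(ctg, [])
        for ctg in pos_by_contig:
            m = contigs.count(ctg)
            # unique positions within a contig so (chrom, pos) keys records
            draw = rng.choice(np.arange(10_000, 2_000_000), size=m, replace=False)
            pos_by_contig[ctg] = sorted(int(p) for p in draw)
        return [(ctg, p) for ctg in pos_by_contig for p in pos_by_contig[ctg]]

    with pysam.VariantFile(str(snv_path), "w", header=_snv_header()) as vcf:
        for i, (ctg, pos) in enumerate(positions(n_snv)):
            should_pass = bool(rng.random() < fraction_passing)
            fail_mode = "" if should_pass else str(
                _SNV_FAIL_MODES[rng.integers(len(_SNV_FAIL_MODES))]
            )
            ref, alt = rng.choice(_BASES, 2, replace=False)
            alt_count = int(rng.integers(c.snv_min_alt_count, 60))
            if rng.random() < 0.1:
                alt_count = c.snv_min_alt_count  # boundary
            max_af = None if rng.random() < 0.5 else float(
                rng.uniform(0, c.snv_max_af)
            )
            cadd = None if rng.random() < 0.3 else float(rng.uniform(c.snv_min_cadd, 45))
            impact = str(rng.choice(["HIGH", "MODERATE"]))
            filt = "PASS"
            if fail_mode == "filter":
                filt = str(rng.choice(["germline", "weak_evidence"]))
            elif fail_mode == "alt_count":
                alt_count = int(rng.integers(0, c.snv_min_alt_count))
            elif fail_mode == "max_af":
                max_af = float(rng.uniform(c.snv_max_af * 1.01, 0.05))
            elif fail_mode == "cadd":
                cadd = float(rng.uniform(0, c.snv_min_cadd * 0.99))
            elif fail_mode == "impact":
                impact = str(rng.choice(["LOW", "MODIFIER"]))
            elif fail_mode == "impact_missing":
                impact = None

            rec = vcf.new_record(
                contig=ctg, start=pos - 1, stop=pos, alleles=(str(ref), str(alt))
            )
            rec.id = f"snv{i}"
            if filt == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add(filt)
            if max_af is not None:
                rec.info["MAX_AF"] = max_af
            if cadd is not None:
                rec.info["CADD_PHRED"] = cadd
            if impact is not None:
                rec.info["IMPACT"] = impact
            rec.info["GENE"] = _draw_gene(rng)
            depth = alt_count + int(rng.integers(20, 80))
            rec.samples["TUMOR"]["AD"] = (depth - alt_count, alt_count)
            rec.samples["TUMOR"]["DP"] = depth
            rec.samples["NORMAL"]["AD"] = (int(rng.integers(20, 80)), 0)
            vcf.write(rec)
            truth_rows.append(
                {"id": f"snv{i}", "kind": "snv_indel", "should_pass": should_pass,
                 "fail_mode": fail_mode, "chrom": ctg, "pos": pos}
            )

    with pysam.VariantFile(str(sv_path), "w", header=_sv_header()) as vcf:
        for i, (ctg, pos) in enumerate(positions(n_sv)):
            should_pass = bool(rng.random() < fraction_passing)
            fail_mode = "" if should_pass else str(
                _SV_FAIL_MODES[rng.integers(len(_SV_FAIL_MODES))]
            )
            svtype = str(rng.choice(["DEL", "DUP", "INV"]))
            end = pos + int(rng.integers(500, 500_000))
            pr = int(rng.integers(c.sv_min_pr, 80))
            sr = int(rng.integers(c.sv_min_sr, 80))
            if rng.random() < 0.1:
                pr, sr = c.sv_min_pr, c.sv_min_sr  # boundary
            normal = int(rng.integers(0, c.sv_max_normal_support + 1))
            score = int(rng.integers(int(c.sv_min_somaticscore), 200))
            filt = "PASS"
            if fail_mode == "filter":
                filt = "MinSomaticScore"
            elif fail_mode == "pr":
                pr = int(rng.integers(0, c.sv_min_pr))
            elif fail_mode == "sr":
                sr = int(rng.integers(0, c.sv_min_sr))
            elif fail_mode == "normal":
                normal = int(rng.integers(c.sv_max_normal_support + 1, 10))
            elif fail_mode == "somaticscore":
                score = int(rng.integers(0, int(c.sv_min_somaticscore)))

            rec = vcf.new_record(
                contig=ctg, start=pos - 1, stop=end, alleles=("N", f"<{svtype}>")
            )
            rec.id = f"sv{i}"
            if filt == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add(filt)
            rec.info["SVTYPE"] = svtype
            rec.info["SOMATICSCORE"] = score
            rec.info["GENE"] = _draw_gene(rng)
            rec.samples["TUMOR"]["PR"] = (int(rng.integers(20, 80)), pr)
            rec.samples["TUMOR"]["SR"] = (int(rng.integers(20, 80)), sr)
            # split the normal's supportive reads between PR and SR
            n_pr = int(rng.integers(0, normal + 1))
            rec.samples["NORMAL"]["PR"] = (int(rng.integers(20, 80)), n_pr)
            rec.samples["NORMAL"]["SR"] = (int(rng.integers(20, 80)), normal - n_pr)
            vcf.write(rec)
            truth_rows.append(
                {"id": f"sv{i}", "kind": "sv", "should_pass": should_pass,
                 "fail_mode": fail_mode, "chrom": ctg, "pos": pos}
            )

    truth = pd.DataFrame(
        truth_rows, columns=["id", "kind", "should_pass", "fail_mode", "chrom", "pos"]
    )
    return snv_path, sv_path, truth
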