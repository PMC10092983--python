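"""Somatic filter chains, prioritization and timepoint intersection."""

import dataclasses

import pytest

from ddmrd import (
    SelectionCriteria,
    VariantRecord,
    filter_somatic_snv,
    filter_somatic_sv,
    intersect_timepoints,
    prioritize_targets,
    read_snv_vcf,
    read_sv_vcf,
    simulate_somatic_vcf_pair,
)
from ddmrd.targets import SNV, SV


def snv(**kw):
    base = dict(
        kind=SNV, chrom="chr1", pos=100, ref="A", alt="T",
        filter_status="PASS", alt_allele_count=10, max_af=None,
        cadd_phred=30.0, impact="MODERATE", gene="TP53",
    )
    base.update(kw)
    return VariantRecord(**base)


def sv(**kw):
    base = dict(
        kind=SV, chrom="chr2", pos=1000, end=5000, svtype="DUP",
        filter_status="PASS", pr_tumor=10, sr_tumor=10,
        normal_support=0, somaticscore=100.0, gene="SNCAIP",
    )
    base.update(kw)
    return VariantRecord(**base)


class TestSNVFilter:
    @pytest.mark.parametrize(
        "kw,kept",
        [
            # boundary values of the retention rule
            (dict(alt_allele_count=5, max_af=None, cadd_phred=25.0,
                  impact="MODERATE"), True),
            (dict(alt_allele_count=4), False),
            (dict(alt_allele_count=5), True),
            (dict(max_af=0.001), True),   # inclusive threshold
            (dict(max_af=0.01), False),
            (dict(max_af=None), True),    # absent annotation tolerated
            (dict(cadd_phred=19.9), False),
            (dict(cadd_phred=20.0), True),
            (dict(cadd_phred=None), True),
            (dict(impact="HIGH"), True),
            (dict(impact="LOW"), False),
            (dict(impact="MODIFIER"), False),
            (dict(filter_status="germline"), False),
        ],
    )
    def test_retention_rule(self, kw, kept):
        out = filter_somatic_snv([snv(**kw)])
        assert (len(out) == 1) is kept

    def test_missing_impact_rejected_with_reason(self):
        retained, rejected = filter_somatic_snv([snv(impact=None)], explain=True)
        assert not retained
        ((_, reason),) = rejected
        assert "unannotated" in reason

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            filter_somatic_snv([sv()])


class TestSVFilter:
    @pytest.mark.parametrize(
        "kw,kept",
        [
            (dict(pr_tumor=5, sr_tumor=5, normal_support=1, somaticscore=50.0), True),
            (dict(pr_tumor=4), False),
            (dict(sr_tumor=4), False),
            (dict(normal_support=1), True),
            (dict(normal_support=2), False),
            (dict(somaticscore=49.0), False),
            (dict(somaticscore=50.0), True),
            (dict(filter_status="MinSomaticScore"), False),
        ],
    )
    def test_retention_rule(self, kw, kept):
        out = filter_somatic_sv([sv(**kw)])
        assert (len(out) == 1) is kept

    def test_missing_support_rejected_with_reason(self):
        retained, rejected = filter_somatic_sv([sv(pr_tumor=None)], explain=True)
        assert not retained
        assert "unannotated" in rejected[0][1]


class TestFilterProperties:
    def test_idempotent_subset_order_independent(self):
        records = [snv(pos=i, alt_allele_count=i) for i in range(1, 20)]
        once = filter_somatic_snv(records)
        assert filter_somatic_snv(once) == once
        assert all(r in records for r in once)
        reversed_out = filter_somatic_snv(records[::-1])
        assert sorted(r.pos for r in reversed_out) == sorted(r.pos for r in once)

    def test_tightening_thresholds_never_adds_records(self):
        records = [snv(pos=i, alt_allele_count=i, cadd_phred=float(i + 15))
                   for i in range(1, 30)]
        loose = set(r.pos for r in filter_somatic_snv(records, SelectionCriteria()))
        tight = set(
            r.pos
            for r in filter_somatic_snv(
                records,
                SelectionCriteria(snv_min_alt_count=10, snv_min_cadd=30.0),
            )
        )
        assert tight <= loose


class TestGeneratedTruth:
    def test_filter_output_equals_truth_table(self, tmp_path):
        snv_path, sv_path, truth = simulate_somatic_vcf_pair(
            100, 60, 0.3, seed=5, out_dir=tmp_path
        )
        kept_snv = {(r.chrom, r.pos) for r in filter_somatic_snv(read_snv_vcf(snv_path))}
        kept_sv = {(r.chrom, r.pos) for r in filter_somatic_sv(read_sv_vcf(sv_path))}
        want_snv = {
            (r.chrom, r.pos)
            for r in truth[(truth.kind == "snv_indel") & truth.should_pass].itertuples()
        }
        want_sv = {
            (r.chrom, r.pos)
            for r in truth[(truth.kind == "sv") & truth.should_pass].itertuples()
        }
        assert kept_snv == want_snv
        assert kept_sv == want_sv

    def test_fraction_passing_one_retains_everything(self, tmp_path):
        snv_path, sv_path, truth = simulate_somatic_vcf_pair(
            40, 20, 1.0, seed=2, out_dir=tmp_path
        )
        assert len(filter_somatic_snv(read_snv_vcf(snv_path))) == 40
        assert len(filter_somatic_sv(read_sv_vcf(sv_path))) == 20

    def test_empty_vcf_has_valid_header(self, tmp_path):
        snv_path, _, truth = simulate_somatic_vcf_pair(0, 0, 0.5, seed=1,
                                                       out_dir=tmp_path)
        assert read_snv_vcf(snv_path) == []
        assert truth.empty


GENE_LISTS = {
    "mb_recurrent": frozenset({"CTNNB1", "SNCAIP"}),
    "cancer_census": frozenset({"TP53", "PIK3CA"}),
}


class TestPrioritize:
    def test_gene_list_tier_dominates_read_support(self):
        census_snv = snv(gene="TP53", alt_allele_count=10)
        intergenic_sv = sv(gene=None, pr_tumor=40, sr_tumor=40)
        panel = prioritize_targets([census_snv, intergenic_sv], GENE_LISTS)
        assert panel.ranked[0].record is census_snv

    def test_same_tier_orders_by_support(self):
        a = snv(pos=1, gene="XYZ1", alt_allele_count=12)
        b = snv(pos=2, gene="XYZ2", alt_allele_count=7)
        panel = prioritize_targets([b, a], GENE_LISTS)
        assert [t.record.pos for t in panel.ranked] == [1, 2]

    def test_single_survivor_sets_under_target_flag(self):
        panel = prioritize_targets([snv()], GENE_LISTS, min_targets=2)
        assert panel.under_target
        assert len(panel.selected) == 1

    def test_mixed_kind_panel_preferred(self):
        records = [
            snv(pos=1, gene="TP53", alt_allele_count=50),
            snv(pos=2, gene="TP53", alt_allele_count=40),
            sv(gene=None, pr_tumor=6, sr_tumor=6),
        ]
        panel = prioritize_targets(records, GENE_LISTS, min_targets=2)
        kinds = {t.record.kind for t in panel.selected}
        assert kinds == {SNV, SV}

    def test_empty_input_warns(self):
        panel = prioritize_targets([], GENE_LISTS)
        assert panel.under_target and panel.warnings


class TestIntersectTimepoints:
    def test_shared_and_private_variants(self):
        shared = snv(pos=100)
        private = snv(pos=200)
        out = intersect_timepoints([shared, private], [snv(pos=100)])
        assert out == [shared]

    def test_sv_breakpoints_match_within_window(self):
        a = sv(pos=1000, end=5000)
        b = sv(pos=1003, end=4998)
        assert intersect_timepoints([a], [b]) == [a]
        far = sv(pos=1030, end=5000)
        assert intersect_timepoints([a], [far], sv_window=10) == []

    def test_sv_type_must_match(self):
        a = sv(svtype="DUP")
        b = sv(svtype="DEL")
        assert intersect_timepoints([a], [b]) == []


def test_bundled_gene_lists_load():
    from ddmrd.targets import bundled_gene_lists

    lists = bundled_gene_lists()
    assert "CTNNB1" in lists["mb_recurrent"]
    assert "PIK3CA" in lists["cancer_census"]


def test_vcf_round_trip_preserves_annotations(tmp_path):
    snv_path, sv_path, truth = simulate_somatic_vcf_pair(30, 15, 0.5, seed=9,
                                                         out_dir=tmp_path)
    snvs = read_snv_vcf(snv_path)
    assert len(snvs) == 30
    assert all(r.kind == SNV and r.alt_allele_count is not None for r in snvs)
    svs = read_sv_vcf(sv_path)
    assert len(svs) == 15
    assert all(r.somaticscore is not None and r.normal_support is not None
               for r in svs)
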