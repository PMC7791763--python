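import pytest

from fhconcord import (
    VariantRecord,
    assign_carrier_status,
    frequency_filter,
    read_variants,
    select_lp_candidates,
    select_vus,
    triage_cohort,
)
from fhconcord.errors import DataError, JoinError, ScopingError
from fhconcord.triage import classify_candidates


def vr(gene="BRCA1", consequence="missense", af_local=None, af_gnomad=None,
       clinvar="absent", has_lp=False, revel=None, zygosity="het",
       pid="P1", pos=100):
    return VariantRecord(
        participant_id=pid, gene=gene, chrom="1", pos=pos, ref="A", alt="G",
        consequence=consequence, zygosity=zygosity, af_local=af_local,
        af_gnomad=af_gnomad, clinvar_assertion=clinvar,
        has_lp_or_p_entry=has_lp, revel=revel,
    )


class TestFrequencyFilter:
    def test_above_threshold_excluded(self):
        assert frequency_filter([vr(af_gnomad=0.05)]) == []

    def test_rare_with_one_source_absent_retained(self):
        v = vr(af_local=0.0005)
        assert frequency_filter([v]) == [v]

    def test_exactly_at_threshold_excluded(self):
        # the rarity criterion is strictly below 1%
        assert frequency_filter([vr(af_gnomad=0.01)]) == []

    def test_both_sources_must_pass(self):
        assert frequency_filter([vr(af_local=0.0001, af_gnomad=0.02)]) == []

    def test_idempotent_and_subset(self):
        variants = [vr(af_gnomad=a, pos=100 + i) for i, a in
                    enumerate([0.001, 0.05, None, 0.009, 0.01])]
        once = frequency_filter(variants)
        assert frequency_filter(once) == once
        assert set(v.key() for v in once) <= set(v.key() for v in variants)

    def test_bad_threshold_rejected(self):
        with pytest.raises(DataError):
            frequency_filter([], threshold=0.0)


class TestCandidateRouting:
    def test_lof_in_haploinsufficient_gene_routes_lof(self, panel):
        out = select_lp_candidates([vr(consequence="stopgain", af_gnomad=0.001)], panel)
        assert [c.route for c in out] == ["lof_candidate"]
        assert not out[0].needs_manual_review

    def test_high_revel_absent_from_database_routes_insilico(self, panel):
        out = select_lp_candidates([vr(revel=0.85, af_gnomad=0.0001)], panel)
        assert [c.route for c in out] == ["insilico_candidate"]

    def test_revel_at_boundary_not_routed(self, panel):
        # in-silico criterion is strictly above 0.7
        assert select_lp_candidates([vr(revel=0.70, af_gnomad=0.0001)], panel) == []
        assert select_lp_candidates([vr(revel=0.69, af_gnomad=0.0001)], panel) == []

    def test_database_entry_takes_priority_over_lof(self, panel):
        out = select_lp_candidates(
            [vr(consequence="stopgain", af_gnomad=0.001, clinvar="pathogenic", has_lp=True)],
            panel,
        )
        assert [c.route for c in out] == ["clinvar_lp_p"]

    def test_database_route_applies_even_to_common_variants(self, panel):
        # criterion has no frequency precondition (exonic and intronic alike)
        out = select_lp_candidates([vr(clinvar="conflicting", has_lp=True, af_gnomad=0.02)], panel)
        assert [c.route for c in out] == ["clinvar_lp_p"]

    def test_lof_without_haploinsufficiency_mechanism_not_routed(self, panel):
        # BLM carries haploinsufficient=no in the default panel
        assert select_lp_candidates([vr(gene="BLM", consequence="stopgain", af_gnomad=0.001)], panel) == []

    def test_lof_with_unknown_haploinsufficiency_goes_to_manual_review(self, panel):
        # EPCAM carries haploinsufficient=unknown in the default panel
        out = select_lp_candidates([vr(gene="EPCAM", consequence="stopgain", af_gnomad=0.001)], panel)
        assert out[0].needs_manual_review
        classified = classify_candidates(out, panel)
        assert classified[0].final_class == "VUS"

    def test_off_panel_gene_is_a_scoping_error(self, panel):
        with pytest.raises(ScopingError, match="NOTAGENE"):
            select_lp_candidates([vr(gene="NOTAGENE")], panel)


class TestVusPool:
    def test_high_revel_vus_is_potential_pathogenic(self, panel):
        out = select_vus([vr(af_gnomad=0.002, revel=0.9, clinvar="vus")], panel)
        assert len(out) == 1 and out[0].potential_pathogenic
        assert out[0].final_class == "VUS"

    def test_low_revel_vus_not_potential(self, panel):
        out = select_vus([vr(af_gnomad=0.002, revel=0.3, clinvar="vus")], panel)
        assert len(out) == 1 and not out[0].potential_pathogenic

    def test_common_variant_fails_frequency_filter(self, panel):
        assert select_vus([vr(consequence="synonymous", af_gnomad=0.02)], panel) == []


class TestCarrierStatus:
    def _classified(self, panel, *variants):
        return classify_candidates(select_lp_candidates(list(variants), panel), panel)

    def test_lp_het_in_dominant_gene_is_carrier(self, panel):
        c = self._classified(panel, vr(clinvar="likely_pathogenic", has_lp=True, af_gnomad=1e-5))
        status = assign_carrier_status("P1", c, panel)
        assert status.is_carrier and status.acmg_sf_carrier

    def test_het_in_recessive_gene_is_recessive_carrier_only(self, panel):
        c = self._classified(panel, vr(gene="MUTYH", clinvar="pathogenic", has_lp=True, af_gnomad=1e-4))
        status = assign_carrier_status("P1", c, panel)
        assert not status.is_carrier
        assert status.recessive_carrier_genes == ["MUTYH"]

    def test_biallelic_recessive_is_carrier(self, panel):
        hom = self._classified(
            panel, vr(gene="MUTYH", clinvar="pathogenic", has_lp=True, zygosity="hom", af_gnomad=1e-4)
        )
        assert assign_carrier_status("P1", hom, panel).is_carrier
        two_het = self._classified(
            panel,
            vr(gene="MUTYH", clinvar="pathogenic", has_lp=True, pos=100, af_gnomad=1e-4),
            vr(gene="MUTYH", clinvar="pathogenic", has_lp=True, pos=200, af_gnomad=1e-4),
        )
        assert assign_carrier_status("P1", two_het, panel).is_carrier

    def test_no_plp_variants_is_noncarrier(self, panel):
        status = assign_carrier_status("P1", [], panel)
        assert not status.is_carrier and not status.acmg_sf_carrier

    def test_non_sf_gene_carrier_not_sf_carrier(self, panel):
        c = self._classified(panel, vr(gene="ATM", clinvar="pathogenic", has_lp=True, af_gnomad=1e-5))
        status = assign_carrier_status("P1", c, panel)
        assert status.is_carrier and not status.acmg_sf_carrier

    def test_foreign_participant_rejected(self, panel):
        c = self._classified(panel, vr(clinvar="pathogenic", has_lp=True, af_gnomad=1e-5))
        with pytest.raises(ScopingError):
            assign_carrier_status("P2", c, panel)


class TestRecordValidation:
    def test_position_and_allele_invariants(self):
        with pytest.raises(DataError):
            vr(pos=0)
        with pytest.raises(DataError):
            VariantRecord("P1", "BRCA1", "1", 5, "A", "A", "missense")

    def test_frequency_and_revel_bounds(self):
        with pytest.raises(DataError):
            vr(af_gnomad=1.5)
        with pytest.raises(DataError):
            vr(revel=-0.1)


def _write_vcf(path, rows, sample="P1"):
    header = (
        "##fileformat=VCFv4.2\n"
        + "".join(f"##contig=<ID={c}>\n" for c in {r[0] for r in rows})
        + '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    )
    body = "".join(
        f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\tGT\t0/1\n" for c, p, r, a in rows
    )
    path.write_text(header + body)


def _write_ann(path, rows):
    lines = ["\t".join(
        ["chrom", "pos", "ref", "alt", "gene", "hgvs_c", "hgvs_p", "consequence",
         "af_local", "af_gnomad", "clinvar_assertion", "has_lp_or_p_entry", "revel"]
    )]
    for c, p, r, a, gene in rows:
        lines.append(f"{c}\t{p}\t{r}\t{a}\t{gene}\t\t\tmissense\t\t0.001\tabsent\tFalse\t")
    path.write_text("\n".join(lines) + "\n")


class TestReadVariants:
    def test_only_panel_genes_returned(self, tmp_path, panel):
        sites = [("1", 100 + i, "A", "G") for i in range(12)]
        genes = ["BRCA1"] * 5 + ["ATM"] * 4 + ["TTN"] * 3  # 3 off-panel
        _write_vcf(tmp_path / "v.vcf", sites)
        _write_ann(tmp_path / "a.tsv", [s + (g,) for s, g in zip(sites, genes)])
        records = read_variants(tmp_path / "v.vcf", tmp_path / "a.tsv", panel)
        assert len(records) == 9
        assert all(r.gene in ("BRCA1", "ATM") for r in records)

    def test_empty_vcf_gives_empty_list(self, tmp_path, panel):
        _write_vcf(tmp_path / "v.vcf", [])
        _write_ann(tmp_path / "a.tsv", [])
        assert read_variants(tmp_path / "v.vcf", tmp_path / "a.tsv", panel) == []

    def test_duplicate_annotation_key_is_join_error(self, tmp_path, panel):
        sites = [("1", 100, "A", "G")]
        _write_vcf(tmp_path / "v.vcf", sites)
        _write_ann(tmp_path / "a.tsv", [sites[0] + ("BRCA1",), sites[0] + ("ATM",)])
        with pytest.raises(JoinError):
            read_variants(tmp_path / "v.vcf", tmp_path / "a.tsv", panel)

    def test_unmatched_annotation_row_is_join_error(self, tmp_path, panel):
        _write_vcf(tmp_path / "v.vcf", [("1", 100, "A", "G")])
        _write_ann(tmp_path / "a.tsv",
                   [("1", 100, "A", "G", "BRCA1"), ("1", 200, "C", "T", "ATM")])
        with pytest.raises(JoinError, match="200"):
            read_variants(tmp_path / "v.vcf", tmp_path / "a.tsv", panel)


def test_triage_is_deterministic(panel):
    variants = [
        vr(clinvar="pathogenic", has_lp=True, af_gnomad=1e-5, pos=100),
        vr(gene="ATM", consequence="stopgain", af_gnomad=0.001, pos=200),
        vr(gene="CHEK2", revel=0.9, af_gnomad=0.0001, pos=300),
        vr(gene="PALB2", revel=0.4, clinvar="vus", af_gnomad=0.004, pos=400),
    ]
    r1 = triage_cohort(variants, panel)
    r2 = triage_cohort(variants, panel)
    assert r1.funnel == r2.funnel
    assert [c.final_class for c in r1.classified] == [c.final_class for c in r2.classified]
    # every routed/classified variant has exactly one route and one class
    for c in r1.classified + r1.vus_pool:
        assert c.route in ("clinvar_lp_p", "lof_candidate", "insilico_candidate", "vus_pool")
        assert c.final_class in ("P", "LP", "VUS", "LB", "B")
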