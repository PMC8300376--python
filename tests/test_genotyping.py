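"""SNP calling from IUPAC consensus and TaqMan allelic discrimination."""

import pytest

import boarmark as bm
from boarmark.genotyping import (ProbeDropoutError, UnexpectedAlleleError,
                                 Zygosity, find_variable_positions)
from boarmark.markers import SequenceRecord


@pytest.fixture(scope="module")
def mc1r_primers(panel):
    return panel.assays["MC1R"].primers


def amplicon_with(backbone, panel, genotypes):
    """PCR product of a sample template carrying the given genotypes."""
    from boarmark.synthetic import _sample_sequences
    mc1r, _ = _sample_sequences(backbone, "s", genotypes, "CC")
    return bm.extract_amplicon(mc1r, panel.assays["MC1R"].primers)


class TestCallSnp:
    def test_homozygous_reference(self, panel, wildtype_amplicon):
        call = bm.call_snp(wildtype_amplicon, panel.locus("MC1R:c.370"), panel)
        assert call.genotype == "GG" and call.zygosity is Zygosity.HOM_REF

    def test_iupac_heterozygote(self, panel, backbone):
        amp = amplicon_with(backbone, panel,
                            {370: "AG", 491: "CC", 727: "GG", 729: "GG"})
        call = bm.call_snp(amp, panel.locus("MC1R:c.370"), panel)
        assert call.genotype == "AG" and call.zygosity is Zygosity.HET

    def test_unexpected_allele_names_locus_and_base(self, panel, backbone):
        seq = list(backbone.mc1r_product)
        seq[backbone.layout.snp_product_offsets[370] - 1] = "C"
        amp = SequenceRecord(id="bad", seq="".join(seq))
        with pytest.raises(UnexpectedAlleleError, match="c.370.*'C'"):
            bm.call_snp(amp, panel.locus("MC1R:c.370"), panel)


class TestCallAll:
    def test_wild_type_pattern(self, panel, backbone):
        amp = amplicon_with(backbone, panel,
                            {370: "GG", 491: "CC", 727: "GG", 729: "GG"})
        g = bm.call_all(amp, panel)
        assert {k: v.genotype for k, v in g.calls.items()} == {
            "MC1R:c.370": "GG", "MC1R:c.491": "CC",
            "MC1R:c.727": "GG", "MC1R:c.729": "GG"}

    def test_duroc_red_pattern(self, panel, backbone):
        amp = amplicon_with(backbone, panel,
                            {370: "GG", 491: "TT", 727: "AA", 729: "GG"})
        g = bm.call_all(amp, panel)
        assert g.genotype("MC1R:c.491") == "TT"
        assert g.genotype("MC1R:c.727") == "AA"

    def test_triple_heterozygote(self, panel, backbone):
        amp = amplicon_with(backbone, panel,
                            {370: "AG", 491: "CT", 727: "AG", 729: "GG"})
        g = bm.call_all(amp, panel)
        for name in ("MC1R:c.370", "MC1R:c.491", "MC1R:c.727"):
            assert g.calls[name].zygosity is Zygosity.HET

    def test_c729_flagged_non_discriminating(self, panel):
        assert panel.locus("MC1R:c.729").informative is False


class TestTaqman:
    def test_c_allele_context(self, panel):
        rec = SequenceRecord(id="c", seq="AAAA" + "CTCACCGGGCTCCA" + "AAAA")
        assert bm.taqman_call(rec, panel.probes) == "CC"

    def test_t_allele_context(self, panel):
        rec = SequenceRecord(id="t", seq="AAAA" + "CTCACTGGGCTCCA" + "AAAA")
        assert bm.taqman_call(rec, panel.probes) == "TT"

    def test_heterozygote_lights_both_probes(self, panel):
        rec = SequenceRecord(id="y", seq="AAAA" + "CTCACYGGGCTCCA" + "AAAA")
        assert bm.taqman_call(rec, panel.probes) == "CT"

    def test_probe_dropout(self, panel):
        rec = SequenceRecord(id="x", seq="ACGT" * 20)
        with pytest.raises(ProbeDropoutError):
            bm.taqman_call(rec, panel.probes)

    def test_agrees_with_snp_call_on_cohort(self, panel, cohort):
        """Probe discrimination equals direct base calling at g.748."""
        locus = panel.locus("NR6A1:g.748")
        for s in cohort.samples:
            amp = bm.extract_amplicon(s.nr6a1_template,
                                      panel.assays["NR6A1"].primers)
            by_probe = bm.taqman_call(amp, panel.probes)
            by_base = bm.call_snp(amp, locus, panel).genotype
            assert by_probe == by_base


def test_cohort_round_trip_recovers_generating_genotypes(panel, cohort):
    """sequence writer -> PCR -> SNP calling reproduces every generating
    genotype exactly, for every sample of the default cohort."""
    for s in cohort.samples:
        amp = bm.extract_amplicon(s.mc1r_template,
                                  panel.assays["MC1R"].primers)
        g = bm.call_all(amp, panel)
        called = {370: g.genotype("MC1R:c.370"),
                  491: g.genotype("MC1R:c.491"),
                  727: g.genotype("MC1R:c.727"),
                  729: g.genotype("MC1R:c.729")}
        assert called == s.genotypes


def test_variable_position_discovery(panel, cohort, wildtype_amplicon):
    amps = [bm.extract_amplicon(s.mc1r_template, panel.assays["MC1R"].primers)
            for s in cohort.samples]
    found = find_variable_positions(amps, wildtype_amplicon, panel)
    assert [v.position for v in found] == [370, 491, 727, 729]
    assert [v.segregating for v in found] == [True, True, True, False]
    assert [v.fixed_difference for v in found] == [False, False, False, True]
    without = find_variable_positions(amps, wildtype_amplicon, panel,
                                      include_fixed_differences=False)
    assert [v.position for v in without] == [370, 491, 727]


def test_genotype_csv_round_trip(panel, cohort, tmp_path):
    genotypes = []
    for s in cohort.samples[:10]:
        amp = bm.extract_amplicon(s.mc1r_template,
                                  panel.assays["MC1R"].primers)
        genotypes.append(bm.call_all(amp, panel, s.sample_id, s.breed))
    from boarmark.genotyping import read_genotype_csv, write_genotype_csv
    path = tmp_path / "genotypes.csv"
    write_genotype_csv(genotypes, path)
    back = read_genotype_csv(path, panel)
    assert [(g.sample_id, {k: c.genotype for k, c in g.calls.items()})
            for g in back] == \
           [(g.sample_id, {k: c.genotype for k, c in g.calls.items()})
            for g in genotypes]
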