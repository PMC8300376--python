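"""Backbone construction and cohort generation."""

import numpy as np
import pytest

import boarmark as bm
from boarmark.rflp import digest
from boarmark.synthetic import BackboneLayout, default_cohort_spec


class TestBackbone:
    def test_same_seed_same_sequences(self, panel):
        a = bm.build_backbone(seed=3, panel=panel)
        b = bm.build_backbone(seed=3, panel=panel)
        assert a.mc1r_template.seq == b.mc1r_template.seq
        assert a.nr6a1_region.seq == b.nr6a1_region.seq

    def test_different_seeds_differ(self, panel):
        a = bm.build_backbone(seed=3, panel=panel)
        b = bm.build_backbone(seed=4, panel=panel)
        assert a.mc1r_template.seq != b.mc1r_template.seq

    def test_bsphi_fragments_by_allele(self, panel, backbone):
        enz = panel.enzymes["BspHI"]
        assert digest(backbone.haplotype_product({370: "A"}), enz) == [200, 472]
        assert digest(backbone.haplotype_product({370: "G"}), enz) == [672]

    def test_bstui_fragments_by_allele(self, panel, backbone):
        enz = panel.enzymes["BstUI"]
        win = backbone.assay_template
        assert digest(win(backbone.haplotype_product({727: "G"}), "BstUI"),
                      enz) == [289, 222, 110]
        assert digest(win(backbone.haplotype_product({727: "A"}), "BstUI"),
                      enz) == [289, 332]

    def test_snp_offsets_follow_reference_anchor(self, panel, backbone):
        # product starts 12 bases 5' of the sequenced window's anchor
        layout = backbone.layout
        for pos in (370, 491, 727, 729):
            assert layout.snp_product_offsets[pos] == \
                bm.ref_to_amplicon_offset(panel, pos) + \
                layout.sequencing_window_offset - 1

    def test_bstui_window_length_is_621(self, backbone):
        assert backbone.layout.bstui_frame_length == 621
        assert len(backbone.bstui_window(backbone.mc1r_product)) == 621


class TestCohortSpec:
    def test_default_composition_sizes(self):
        spec = default_cohort_spec()
        assert {p.name: p.n for p in spec.populations} == {
            "WB": 24, "D": 17, "ZW": 13, "P": 10, "PL": 14, "PLW": 13}
        assert spec.hybrid_count == 5
        assert spec.n_samples == 96

    def test_yaml_round_trip(self, tmp_path):
        spec = default_cohort_spec()
        spec.to_yaml(tmp_path / "spec.yaml")
        back = bm.CohortSpec.from_yaml(tmp_path / "spec.yaml")
        assert back == spec


class TestCohort:
    def test_full_size(self, cohort):
        assert len(cohort) == 96

    def test_single_wild_boar_is_all_reference(self, backbone):
        from boarmark.synthetic import (CohortSpec, GenotypeEntry,
                                        PopulationSpec)
        spec = CohortSpec(populations=(PopulationSpec("WB", "wild_boar", (
            GenotypeEntry(1, "GG", "CC", "GG", "GG", "CC", ("E+", "E+")),)),),
            hybrid_count=0)
        c = bm.generate_cohort(spec, backbone, seed=0)
        assert len(c) == 1
        s = c.samples[0]
        # identical to the backbone except for the 729 G fixed difference
        diffs = [i for i, (a, b) in enumerate(zip(
            s.mc1r_template.seq, backbone.mc1r_template.seq)) if a != b]
        off729 = (backbone.layout.mc1r_flank
                  + backbone.layout.snp_product_offsets[729] - 1)
        assert diffs == [off729]
        assert s.nr6a1_template.seq == backbone.nr6a1_region.seq

    def test_hybrids_carry_iupac_y_at_nr6a1(self, cohort):
        off = cohort.backbone.layout.nr6a1_snp_offset - 1
        hybrids = [s for s in cohort.samples if s.role == "hybrid"]
        assert len(hybrids) == 5
        for s in hybrids:
            assert s.nr6a1_template.seq[off] == "Y"

    def test_marginal_genotype_counts_match_published_table(self, cohort):
        truth = cohort.truth_frame()
        def marg(breed, col):
            return truth[truth.breed == breed][col].value_counts().to_dict()
        assert marg("WB", "g370") == {"GG": 22, "AG": 2}
        assert marg("D", "g370") == {"GG": 15, "AG": 1, "AA": 1}
        assert marg("D", "g491") == {"TT": 14, "CT": 1, "CC": 2}
        assert marg("D", "g727") == {"AA": 14, "AG": 1, "GG": 2}
        assert marg("ZW", "g370") == {"AA": 11, "AG": 2}
        assert marg("P", "g370") == {"AA": 10}
        assert marg("PL", "g370") == {"AA": 14}
        assert marg("PLW", "g370") == {"AA": 13}
        # NR6A1 is fixed by subspecies
        assert set(truth[truth.role == "wild_boar"].nr6a1) == {"CC"}
        assert set(truth[truth.role == "domestic"].nr6a1) == {"TT"}
        assert set(truth[truth.role == "hybrid"].nr6a1) == {"CT"}

    def test_same_seed_same_cohort(self, backbone):
        a = bm.generate_cohort(backbone=backbone, seed=5)
        b = bm.generate_cohort(backbone=backbone, seed=5)
        assert [s.mc1r_template.seq for s in a.samples] == \
               [s.mc1r_template.seq for s in b.samples]
        assert [s.diplotype for s in a.samples] == \
               [s.diplotype for s in b.samples]

    def test_write_outputs(self, cohort, tmp_path):
        cohort.write(tmp_path)
        assert (tmp_path / "mc1r_templates.fasta").exists()
        assert (tmp_path / "truth.csv").exists()
        recs = bm.read_fasta(tmp_path / "mc1r_templates.fasta")
        assert len(recs) == 96

    def test_haplotypes_reproduce_consensus(self, cohort):
        """The phased haplotype pair IUPAC-collapses to the consensus."""
        from boarmark.markers import IUPAC_FOR_PAIR
        layout = cohort.backbone.layout
        f = layout.mc1r_flank
        for s in cohort.samples[:20]:
            h1, h2 = cohort.haplotypes_for(s)
            consensus = s.mc1r_template.seq[f:f + len(h1)]
            for a, b, c in zip(h1, h2, consensus):
                want = a if a == b else IUPAC_FOR_PAIR[frozenset((a, b))]
                assert want == c
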