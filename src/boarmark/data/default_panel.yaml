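# Default dual-marker panel: MC1R (extension locus) PCR-RFLP/sequencing assay
# and NR6A1 g.748C>T TaqMan allelic discrimination.
#
# SNP positions are 1-based on the named reference systems
# (NM_001008690 CDS for MC1R, AB248749 genomic for NR6A1).
panel_name: mc1r-nr6a1-dual-marker
panel_version: "1.0"

mc1r:
  coordinate_system: "NM_001008690 CDS"
  # Reference position of the first base of the sequenced consensus window.
  amplicon_anchor: 181
  # Reference position of the first base of the PCR product (the RFLP
  # substrate).  The product extends 12 bp 5' of the sequenced window so
  # that the BspHI cut arithmetic (200 + 472 = 672) works out.
  product_start: 169
  # Published amplicon length; kept as metadata.  The band arithmetic of the
  # RFLP assay implies a 672 bp product, which is what this package uses.
  reported_amplicon_length: 575
  primers:
    forward: AGTGCCTGGAGGTGTCCATTCAC
    reverse: CGTAGATGAGGGGGTCCAGGATAGA
    max_mismatches: 0
  loci:
    - name: "MC1R:c.370"
      position: 370
      ref: G
      alt: A
      protein_change: p.Asp124Asn
    - name: "MC1R:c.491"
      position: 491
      ref: C
      alt: T
      protein_change: p.Ala164Val
    - name: "MC1R:c.727"
      position: 727
      ref: G
      alt: A
    - name: "MC1R:c.729"
      position: 729
      ref: A
      alt: G
      # monomorphic (GG) in the study cohorts; called but not used for
      # allele-class assignment
      informative: false
  enzymes:
    BspHI: {site: TCATGA, cut_offset: 1, locus: "MC1R:c.370"}
    BstUI: {site: CGCG, cut_offset: 2, locus: "MC1R:c.727"}
  band_keys:
    BspHI:
      - {bands: [672], genotype: GG}
      - {bands: [472, 200], genotype: AA}
      - {bands: [672, 472, 200], genotype: AG}
    BstUI:
      - {bands: [289, 222, 110], genotype: GG}
      - {bands: [332, 289], genotype: AA}
      - {bands: [332, 289, 222, 110], genotype: AG}

nr6a1:
  coordinate_system: "AB248749 genomic"
  product_start: 641
  # Printed as the assay's "sequence length"; not a usable amplicon length
  # for the primer pair, kept as metadata only.
  reported_sequence_length: 18
  primers:
    forward: AGGGCTTCAGAGAGCAACCA
    reverse: TGAAGCTCACCTGGAGGACAGT
    max_mismatches: 0
  locus:
    name: "NR6A1:g.748"
    position: 748
    ref: C
    alt: T
    protein_change: p.Pro192Leu
  probes:
    allele_C: {sequence: TCACCGGGCTCCA, dye: VIC, discriminating_index: 5}
    allele_T: {sequence: CTCACTGGGCTCC, dye: FAM, discriminating_index: 6}
  # Real-time instrument settings of the published assay; metadata only, the
  # in-silico discrimination is exact probe-template matching.
  instrument_metadata:
    fluorescence_threshold_T: 0.47
    fluorescence_threshold_C: 0.28
    ct_window: [18, 28]
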