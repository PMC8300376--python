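"""Synthetic reference backbone and study-structured cohorts.

No sequence data of the original study are deposited, so every pipeline
stage runs on an engineered stand-in: a synthetic MC1R/NR6A1 reference
backbone whose restriction-site arithmetic reproduces the published band
patterns exactly, plus per-breed cohorts whose joint genotypes match the
published per-breed composition.

Backbone geometry (MC1R, 1-based product coordinates; the product is the
672 bp primer-to-primer PCR fragment):

* the sequenced consensus window (575 bp, anchored at reference position
  181) starts at product offset 13, so the product's first base sits at
  reference position 169;
* c.370 -> offset 202, inside the BspHI site TCATGA at 200..205, which
  exists only on 370A chromosomes and cuts after base 200 (fragments
  200 + 472);
* c.491 -> offset 323 (no diagnostic enzyme);
* the BstUI assay digests the 621 bp sub-window at offsets 47..667 (the
  published fragment sums of the two assays disagree, 672 vs 621, so each
  assay carries its own digestion frame): a constitutive CGCG site at
  window offsets 288..291 and a polymorphic one at 510..513 whose last
  base is c.727 (product offset 559); 727A destroys it, merging
  222 + 110 into 332;
* c.729 -> product offset 561; the backbone carries the reference A while
  every cohort chromosome carries G, making the site a fixed difference
  rather than a segregating one.

The NR6A1 region is a 300 bp genomic window (reference 601..900) whose
primer pair brackets the TaqMan probe footprint; g.748 sits at region
offset 148, the sixth base of the probe context CTCAC[C/T]GGGCTCCA.

All filler sequence is drawn from a seeded generator and re-drawn (up to
a retry budget) until no spurious primer site, restriction site or probe
footprint exists on any allele combination; construction then self-checks
that all six published band patterns regenerate before any cohort is
emitted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .markers import (IUPAC_FOR_PAIR, MarkerPanel, SequenceRecord,
                      default_panel, find_primer_sites, revcomp)
from .rflp import digest


class BackboneGenerationError(RuntimeError):
    """Filler could not avoid spurious assay sites within the retry budget."""


@dataclass(frozen=True)
class BackboneLayout:
    """Coordinate plan of the synthetic reference regions."""

    # --- MC1R ---
    mc1r_product_length: int = 672
    mc1r_flank: int = 30                   # template flanks around the product
    sequencing_window_offset: int = 13     # product offset of reference pos 181
    sequencing_window_length: int = 575
    snp_product_offsets: dict = field(default_factory=lambda: {
        370: 202, 491: 323, 727: 559, 729: 561})
    bsphi_cut_after: int = 200             # product offset; site at 200..205
    bstui_frame: tuple[int, int] = (47, 667)   # product offsets, inclusive
    bstui_site1_start: int = 334           # product offset of constitutive CGCG
    bstui_site2_start: int = 556           # product offset; last base is c.727
    # --- NR6A1 ---
    nr6a1_region_length: int = 300
    nr6a1_region_start_ref: int = 601      # reference position of region base 1
    nr6a1_fwd_offset: int = 41
    nr6a1_rev_end_offset: int = 260        # last base of revcomp(reverse)
    nr6a1_probe_offset: int = 143          # CTCAC[C/T]GGGCTCCA starts here
    nr6a1_snp_offset: int = 148
    max_retries: int = 50

    @property
    def bstui_frame_length(self) -> int:
        lo, hi = self.bstui_frame
        return hi - lo + 1


@dataclass
class Backbone:
    """Wild-type reference sequences plus the layout that shaped them."""

    layout: BackboneLayout
    panel: MarkerPanel
    mc1r_template: SequenceRecord      # flank + 672 bp product + flank
    nr6a1_region: SequenceRecord       # 300 bp genomic window
    seed: int

    @property
    def mc1r_product(self) -> str:
        f = self.layout.mc1r_flank
        return self.mc1r_template.seq[f:f + self.layout.mc1r_product_length]

    def bstui_window(self, product: str) -> str:
        lo, hi = self.layout.bstui_frame
        return product[lo - 1:hi]

    def haplotype_product(self, bases: dict[int, str]) -> str:
        """The 672 bp product with given bases at the SNP reference positions."""
        seq = list(self.mc1r_product)
        for pos, base in bases.items():
            seq[self.layout.snp_product_offsets[pos] - 1] = base
        return "".join(seq)

    def assay_template(self, product: str, enzyme_name: str) -> str:
        """The substrate each RFLP assay digests (per-assay frames)."""
        if enzyme_name == "BspHI":
            return product
        if enzyme_name == "BstUI":
            return self.bstui_window(product)
        raise KeyError(enzyme_name)


def _rand_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _place(seq: list[str], start_1based: int, fragment: str) -> None:
    for i, b in enumerate(fragment):
        seq[start_1based - 1 + i] = b


def _assemble_mc1r(rng, layout: BackboneLayout, panel: MarkerPanel) -> str:
    p = panel.assays["MC1R"].primers
    n = layout.mc1r_product_length
    seq = list(_rand_seq(rng, n))
    _place(seq, 1, p.forward)
    _place(seq, n - len(p.reverse) + 1, revcomp(p.reverse))
    # BspHI site TCATGA at 200..205, wild type G at the SNP (=> TCGTGA, no site)
    _place(seq, layout.bsphi_cut_after, "TCGTGA")
    # BstUI sites (CGCG); wild type carries both
    _place(seq, layout.bstui_site1_start, "CGCG")
    _place(seq, layout.bstui_site2_start, "CGCG")
    # guard base between the polymorphic site and c.729 so that a cohort G
    # at c.729 cannot recreate a CGCG overlapping the site
    _place(seq, layout.snp_product_offsets[729] - 1, "A")
    _place(seq, layout.snp_product_offsets[729], "A")       # reference 729A
    _place(seq, layout.snp_product_offsets[491], "C")       # reference 491C
    return "".join(seq)


def _assemble_nr6a1(rng, layout: BackboneLayout, panel: MarkerPanel) -> str:
    p = panel.assays["NR6A1"].primers
    seq = list(_rand_seq(rng, layout.nr6a1_region_length))
    _place(seq, layout.nr6a1_fwd_offset, p.forward)
    rc = revcomp(p.reverse)
    _place(seq, layout.nr6a1_rev_end_offset - len(rc) + 1, rc)
    _place(seq, layout.nr6a1_probe_offset, "CTCACCGGGCTCCA")  # wild C allele
    return "".join(seq)


def _expected_mc1r_bands(g370: str, g727: str) -> dict[str, list[int]]:
    bsphi = [200, 472] if g370 == "A" else [672]
    bstui = [289, 332] if g727 == "A" else [289, 222, 110]
    return {"BspHI": sorted(bsphi, reverse=True),
            "BstUI": sorted(bstui, reverse=True)}


def _validate_backbone(bb: Backbone) -> None:
    layout, panel = bb.layout, bb.panel
    # every haplotype variant must digest to exactly the designed fragments
    for g370, g491, g727, g729 in itertools.product("GA", "CT", "GA", "AG"):
        product = bb.haplotype_product({370: g370, 491: g491,
                                        727: g727, 729: g729})
        want = _expected_mc1r_bands(g370, g727)
        for enz_name, expected in want.items():
            frags = digest(bb.assay_template(product, enz_name),
                           panel.enzymes[enz_name])
            if sorted(frags, reverse=True) != expected:
                raise BackboneGenerationError(
                    f"{enz_name} on ({g370},{g491},{g727},{g729}): "
                    f"fragments {sorted(frags, reverse=True)} != {expected}")
        # exactly one primer site pair on the template carrying this product
        f = layout.mc1r_flank
        tpl = SequenceRecord(id="chk", seq=bb.mc1r_template.seq[:f] + product
                             + bb.mc1r_template.seq[f + len(product):])
        sites = find_primer_sites(tpl, panel.assays["MC1R"].primers)
        if len(sites) != 1:
            raise BackboneGenerationError(
                f"MC1R template has {len(sites)} primer site pairs")
    # NR6A1: unique primer pair; allele-exclusive probe matches
    for allele, probe_in, probe_out in (
            ("C", panel.probes.allele_c_probe, panel.probes.allele_t_probe),
            ("T", panel.probes.allele_t_probe, panel.probes.allele_c_probe)):
        seq = list(bb.nr6a1_region.seq)
        seq[layout.nr6a1_snp_offset - 1] = allele
        s = "".join(seq)
        rec = SequenceRecord(id="chk", seq=s)
        if len(find_primer_sites(rec, panel.assays["NR6A1"].primers)) != 1:
            raise BackboneGenerationError("NR6A1 primer sites not unique")
        if s.count(probe_in) != 1 or probe_out in s:
            raise BackboneGenerationError(
                f"NR6A1 probe footprint not allele-exclusive ({allele})")


def build_backbone(layout: BackboneLayout | None = None, seed: int = 0,
                   panel: MarkerPanel | None = None) -> Backbone:
    """Build (and self-check) the wild-type reference backbone.

    Deterministic given ``seed``.  Filler is re-drawn until the layout
    validates; exhausting ``layout.max_retries`` raises
    :class:`BackboneGenerationError`.
    """
    layout = layout or BackboneLayout()
    panel = panel or default_panel()
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xB0A2,))
    last_err: Exception | None = None
    for attempt, child in enumerate(ss.spawn(layout.max_retries)):
        rng = np.random.default_rng(child)
        product = _assemble_mc1r(rng, layout, panel)
        flanks = (_rand_seq(rng, layout.mc1r_flank),
                  _rand_seq(rng, layout.mc1r_flank))
        mc1r = SequenceRecord(id="MC1R_backbone",
                              seq=flanks[0] + product + flanks[1])
        nr6a1 = SequenceRecord(id="NR6A1_backbone",
                               seq=_assemble_nr6a1(rng, layout, panel))
        bb = Backbone(layout=layout, panel=panel, mc1r_template=mc1r,
                      nr6a1_region=nr6a1, seed=seed)
        try:
            _validate_backbone(bb)
            return bb
        except BackboneGenerationError as err:
            last_err = err
    raise BackboneGenerationError(
        f"no valid filler after {layout.max_retries} attempts: {last_err}")


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeEntry:
    """A block of identical samples within one population."""

    count: int
    g370: str
    g491: str
    g727: str
    g729: str
    nr6a1: str
    diplotype: tuple[str, str]     # intended allele classes (ground truth)

    def genotypes(self) -> dict[int, str]:
        return {370: self.g370, 491: self.g491, 727: self.g727, 729: self.g729}


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    role: str                      # "wild_boar" | "domestic" | "hybrid"
    entries: tuple[GenotypeEntry, ...]

    @property
    def n(self) -> int:
        return sum(e.count for e in self.entries)


@dataclass(frozen=True)
class CohortSpec:
    """Per-breed joint-genotype composition plus the hybrid count."""

    populations: tuple[PopulationSpec, ...]
    hybrid_count: int = 5
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(p.n for p in self.populations) + self.hybrid_count

    def to_yaml(self, path) -> None:
        doc = {
            "hybrid_count": self.hybrid_count,
            "seed": self.seed,
            "populations": [
                {"name": p.name, "role": p.role,
                 "entries": [{"count": e.count, "g370": e.g370, "g491": e.g491,
                              "g727": e.g727, "g729": e.g729,
                              "nr6a1": e.nr6a1,
                              "diplotype": list(e.diplotype)}
                             for e in p.entries]}
                for p in self.populations],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        pops = tuple(
            PopulationSpec(
                name=p["name"], role=p["role"],
                entries=tuple(GenotypeEntry(
                    count=int(e["count"]), g370=e["g370"], g491=e["g491"],
                    g727=e["g727"], g729=e["g729"], nr6a1=e["nr6a1"],
                    diplotype=tuple(e["diplotype"]))
                    for e in p["entries"]))
            for p in doc["populations"])
        return cls(populations=pops, hybrid_count=int(doc["hybrid_count"]),
                   seed=int(doc.get("seed", 0)))


def _entry(count, g370, g491, g727, nr6a1, dip) -> GenotypeEntry:
    return GenotypeEntry(count=count, g370=g370, g491=g491, g727=g727,
                         g729="GG", nr6a1=nr6a1, diplotype=dip)


def default_cohort_spec() -> CohortSpec:
    """The published per-breed composition (joint genotypes reconstructed
    from the per-locus narrative; diplotype column as printed, including
    the ED-vs-EP3 split that the panel SNPs themselves cannot resolve).

    Every sample is 729 GG (the site is monomorphic in the cohorts);
    NR6A1 is CC in wild boar, TT in all domestic breeds, CT in hybrids.
    """
    wb = PopulationSpec("WB", "wild_boar", (
        _entry(22, "GG", "CC", "GG", "CC", ("E+", "E+")),
        _entry(2, "AG", "CC", "GG", "CC", ("E+", "ED")),
    ))
    duroc = PopulationSpec("D", "domestic", (
        _entry(14, "GG", "TT", "AA", "TT", ("e", "e")),
        _entry(1, "AG", "CT", "AG", "TT", ("e", "ED")),
        _entry(1, "GG", "CC", "GG", "TT", ("E+", "E+")),
        _entry(1, "AA", "CC", "GG", "TT", ("ED", "ED")),
    ))
    zw = PopulationSpec("ZW", "domestic", (
        _entry(11, "AA", "CC", "GG", "TT", ("ED", "ED")),
        _entry(1, "AG", "CT", "AG", "TT", ("e", "ED")),
        _entry(1, "AG", "CT", "AG", "TT", ("e", "EP3")),
    ))
    pu = PopulationSpec("P", "domestic", (
        _entry(10, "AA", "CC", "GG", "TT", ("ED", "ED")),
    ))
    pl = PopulationSpec("PL", "domestic", (
        _entry(4, "AA", "CC", "GG", "TT", ("ED", "ED")),
        _entry(10, "AA", "CC", "GG", "TT", ("ED", "EP3")),
    ))
    plw = PopulationSpec("PLW", "domestic", (
        _entry(13, "AA", "CC", "GG", "TT", ("ED", "ED")),
    ))
    return CohortSpec(populations=(wb, duroc, zw, pu, pl, plw),
                      hybrid_count=5)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSample:
    sample_id: str
    breed: str
    role: str
    genotypes: dict[int, str]          # reference position -> e.g. "AG"
    nr6a1: str
    diplotype: tuple[str, str]
    subspecies_truth: str
    mc1r_template: SequenceRecord
    nr6a1_template: SequenceRecord


@dataclass
class Cohort:
    spec: CohortSpec
    backbone: Backbone
    samples: list[SyntheticSample]
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def mc1r_records(self) -> list[SequenceRecord]:
        return [s.mc1r_template for s in self.samples]

    def nr6a1_records(self) -> list[SequenceRecord]:
        return [s.nr6a1_template for s in self.samples]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s.sample_id, "breed": s.breed, "role": s.role,
                "g370": s.genotypes[370], "g491": s.genotypes[491],
                "g727": s.genotypes[727], "g729": s.genotypes[729],
                "nr6a1": s.nr6a1,
                "diplotype": "/".join(s.diplotype),
                "subspecies": s.subspecies_truth,
            })
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        from pathlib import Path
        from .markers import write_fasta
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.mc1r_records(), out / "mc1r_templates.fasta")
        write_fasta(self.nr6a1_records(), out / "nr6a1_templates.fasta")
        self.truth_frame().to_csv(out / "truth.csv", index=False)

    def haplotypes_for(self, sample: SyntheticSample) -> tuple[str, str]:
        """Phased 672 bp product pair implied by the sample's diplotype."""
        from .classify import ALLELE_CLASS_PATTERNS
        haps = []
        for cls in sample.diplotype:
            pat = ALLELE_CLASS_PATTERNS["ED" if cls == "EP3" else cls]
            haps.append(self.backbone.haplotype_product(
                {370: pat[0], 491: pat[1], 727: pat[2],
                 729: sample.genotypes[729][0]}))
        return haps[0], haps[1]


def _consensus_base(genotype: str) -> str:
    a, b = genotype[0], genotype[1]
    if a == b:
        return a
    return IUPAC_FOR_PAIR[frozenset((a, b))]


def _sample_sequences(bb: Backbone, sample_id: str, genotypes: dict[int, str],
                      nr6a1: str) -> tuple[SequenceRecord, SequenceRecord]:
    layout = bb.layout
    f = layout.mc1r_flank
    seq = list(bb.mc1r_template.seq)
    for pos, gt in genotypes.items():
        seq[f + layout.snp_product_offsets[pos] - 1] = _consensus_base(gt)
    mc1r = SequenceRecord(id=f"{sample_id}|MC1R", seq="".join(seq))
    nseq = list(bb.nr6a1_region.seq)
    nseq[layout.nr6a1_snp_offset - 1] = _consensus_base(nr6a1)
    nr = SequenceRecord(id=f"{sample_id}|NR6A1", seq="".join(nseq))
    return mc1r, nr


#: Wild-boar and pooled-domestic haplotype-class pools used to draw the
#: deliberate hybrids' parental chromosomes (chromosome counts of the
#: default composition).
_WILD_POOL = (("E+", 46), ("ED", 2))
_DOMESTIC_POOL = (("E+", 2), ("e", 31), ("ED", 90), ("EP3", 11))


def _draw_class(rng, pool) -> str:
    labels, weights = zip(*pool)
    w = np.array(weights, dtype=float)
    return labels[rng.choice(len(labels), p=w / w.sum())]


def _genotype_from_pair(pair: tuple[str, str]) -> dict[int, str]:
    from .classify import ALLELE_CLASS_PATTERNS
    pats = [ALLELE_CLASS_PATTERNS["ED" if c == "EP3" else c] for c in pair]
    out = {}
    for pos, i in ((370, 0), (491, 1), (727, 2)):
        out[pos] = "".join(sorted((pats[0][i], pats[1][i])))
    out[729] = "GG"
    return out


def generate_cohort(spec: CohortSpec | None = None,
                    backbone: Backbone | None = None,
                    seed: int = 0) -> Cohort:
    """Emit one MC1R and one NR6A1 template per sample, plus ground truth.

    Heterozygous positions are written as IUPAC codes (diploid Sanger
    consensus).  Hybrids pair one wild-boar chromosome with one domestic
    chromosome (classes drawn from the two pools' frequencies) and are
    NR6A1 CT.  Deterministic given ``seed``.
    """
    spec = spec or default_cohort_spec()
    bb = backbone or build_backbone(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0xC0B0,)))
    samples: list[SyntheticSample] = []
    for pop in spec.populations:
        i = 0
        for entry in pop.entries:
            for _ in range(entry.count):
                i += 1
                sid = f"{pop.name}{i:03d}"
                genotypes = entry.genotypes()
                mc1r, nr = _sample_sequences(bb, sid, genotypes, entry.nr6a1)
                truth = ("wild_boar" if pop.role == "wild_boar"
                         else "domestic_pig")
                samples.append(SyntheticSample(
                    sample_id=sid, breed=pop.name, role=pop.role,
                    genotypes=genotypes, nr6a1=entry.nr6a1,
                    diplotype=entry.diplotype, subspecies_truth=truth,
                    mc1r_template=mc1r, nr6a1_template=nr))
    for i in range(spec.hybrid_count):
        sid = f"HYB{i + 1:03d}"
        pair = (_draw_class(rng, _WILD_POOL), _draw_class(rng, _DOMESTIC_POOL))
        genotypes = _genotype_from_pair(pair)
        mc1r, nr = _sample_sequences(bb, sid, genotypes, "CT")
        samples.append(SyntheticSample(
            sample_id=sid, breed="HYB", role="hybrid", genotypes=genotypes,
            nr6a1="CT", diplotype=pair, subspecies_truth="hybrid",
            mc1r_template=mc1r, nr6a1_template=nr))
    return Cohort(spec=spec, backbone=bb, samples=samples, seed=seed)


# ---------------------------------------------------------------------------
# Structured-population testbed for the admixture model
# ---------------------------------------------------------------------------

def generate_structured_pops(n_pops: int, n_samples: int, allele_freqs,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw haplotype pairs from per-population allele frequencies.

    ``allele_freqs`` has shape ``(n_pops, n_alleles)`` with rows summing
    to 1; ``n_samples`` is the per-population sample count.  Returns a
    ``(n_pops * n_samples, 1, 2)`` genotype array and the true population
    label of every sample.  Deterministic given ``seed``.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    if freqs.shape[0] != n_pops:
        raise ValueError("allele_freqs must have one row per population")
    if not np.allclose(freqs.sum(axis=1), 1.0):
        raise ValueError("allele frequencies must sum to 1 per population")
    rng = np.random.default_rng(seed)
    genotypes = np.empty((n_pops * n_samples, 1, 2), dtype=int)
    labels = np.repeat(np.arange(n_pops), n_samples)
    for p in range(n_pops):
        draws = rng.choice(freqs.shape[1], size=(n_samples, 2), p=freqs[p])
        genotypes[p * n_samples:(p + 1) * n_samples, 0, :] = draws
    return genotypes, labels
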