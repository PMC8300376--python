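"""Marker-panel data model, FASTA I/O and in-silico PCR.

The panel bundles everything the two assays need as *data*: SNP loci on
their published reference coordinate systems, PCR primers, restriction
enzymes with band keys for the gel read-out, and the TaqMan probe pair.
Diploid Sanger consensus sequences are carried as plain IUPAC strings;
heterozygous positions are encoded with two-base ambiguity codes
(R = A/G, Y = C/T, ...).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

# IUPAC nucleotide codes admitted in diploid consensus sequences.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: unordered base pair -> two-base ambiguity code.
IUPAC_FOR_PAIR: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_EXPANSION.items() if len(v) == 2
}

ALLOWED_ALPHABET = frozenset(IUPAC_EXPANSION)
STRICT_ALPHABET = frozenset("ACGT")


class FastaParseError(ValueError):
    """Malformed FASTA entry (bad alphabet, empty sequence, ...)."""


class NoProductError(RuntimeError):
    """The primer pair finds no site pair on the template."""


class NonSpecificAmplificationError(RuntimeError):
    """The primer pair finds more than one site pair on the template."""

    def __init__(self, template_id: str, n_sites: int):
        self.n_sites = n_sites
        super().__init__(
            f"non-specific amplification on {template_id!r}: "
            f"{n_sites} primer site pairs found"
        )


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def base_matches(template_base: str, probe_base: str) -> bool:
    """Match with IUPAC expansion on the template side only.

    An ambiguity code on the template (a heterozygous consensus position)
    matches any base it covers; the probe/primer base must be concrete.
    """
    try:
        return probe_base in IUPAC_EXPANSION[template_base]
    except KeyError:
        raise FastaParseError(f"unknown template base {template_base!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the IUPAC alphabet.

    ``diploid_consensus`` flags that two-base ambiguity codes encode
    heterozygous positions of a directly sequenced diploid template.
    """

    id: str
    seq: str
    diploid_consensus: bool = True

    def __post_init__(self):
        if not self.id:
            raise FastaParseError("sequence record without an id")
        if not self.seq:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALLOWED_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNP on a named 1-based reference coordinate system."""

    name: str
    position: int
    ref_base: str
    alt_base: str
    coordinate_system: str
    informative: bool = True

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.name}: position must be >= 1")
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.name}: ref and alt bases are identical")
        for b in (self.ref_base, self.alt_base):
            if b not in STRICT_ALPHABET:
                raise ValueError(f"{self.name}: allele {b!r} not in ACGT")

    @property
    def het_code(self) -> str:
        """IUPAC code covering exactly {ref, alt}."""
        return IUPAC_FOR_PAIR[frozenset((self.ref_base, self.alt_base))]


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primers, both written 5'->3'."""

    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or set(p) - STRICT_ALPHABET:
                raise ValueError(f"{name} primer must be a non-empty ACGT string")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition site and top-strand cut offset.

    ``cut_offset`` counts bases from the site start to the cut, so a
    fragment boundary falls after base ``site_start + cut_offset - 1``
    (1-based).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        if set(self.recognition_site) - STRICT_ALPHABET:
            raise ValueError(f"{self.name}: site must be an ACGT string")
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError(f"{self.name}: cut offset outside the site")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition_site == revcomp(self.recognition_site)


@dataclass(frozen=True)
class ProbeSet:
    """Allele-specific TaqMan probe pair for a biallelic SNP."""

    allele_c_probe: str
    allele_t_probe: str
    c_discriminating_index: int
    t_discriminating_index: int

    def __post_init__(self):
        for p in (self.allele_c_probe, self.allele_t_probe):
            if set(p) - STRICT_ALPHABET:
                raise ValueError("probe sequences must be ACGT strings")


@dataclass
class GeneAssay:
    """Per-gene slice of the panel: primers plus coordinate conventions."""

    gene: str
    coordinate_system: str
    primers: PrimerPair
    product_start: int  # reference position of the PCR product's first base
    metadata: dict = field(default_factory=dict)


@dataclass
class MarkerPanel:
    """The two assay definitions as one data object."""

    mc1r_loci: list[SnpLocus]
    nr6a1_locus: SnpLocus
    assays: dict[str, GeneAssay]
    enzymes: dict[str, Enzyme]
    enzyme_locus: dict[str, str]           # enzyme name -> locus name
    band_keys: dict[str, list[tuple[frozenset[int], str]]]
    probes: ProbeSet
    amplicon_anchor: int = 181             # sequenced-window anchor (MC1R)
    name: str = "mc1r-nr6a1-dual-marker"
    version: str = "1.0"

    def __post_init__(self):
        known = {l.name for l in self.mc1r_loci} | {self.nr6a1_locus.name}
        for enz, locus in self.enzyme_locus.items():
            if locus not in known:
                raise ValueError(f"band key for {enz} references unknown locus {locus}")

    # -- lookup helpers -------------------------------------------------

    @property
    def loci(self) -> dict[str, SnpLocus]:
        d = {l.name: l for l in self.mc1r_loci}
        d[self.nr6a1_locus.name] = self.nr6a1_locus
        return d

    def locus(self, name: str) -> SnpLocus:
        return self.loci[name]

    def gene_of(self, locus: SnpLocus) -> str:
        return "MC1R" if locus in self.mc1r_loci else "NR6A1"

    def offset_in_product(self, locus: SnpLocus) -> int:
        """1-based offset of a panel locus within its gene's PCR product."""
        assay = self.assays[self.gene_of(locus)]
        off = locus.position - assay.product_start + 1
        if off < 1:
            raise ValueError(
                f"{locus.name} at {locus.position} lies before the product start"
            )
        return off


def ref_to_amplicon_offset(panel: MarkerPanel, position: int) -> int:
    """Map an MC1R reference position onto the sequenced window (1-based).

    The sequenced consensus window is anchored at reference position
    ``panel.amplicon_anchor`` (181 by default), so the anchor maps to 1.
    """
    if position < panel.amplicon_anchor:
        raise ValueError(
            f"position {position} precedes the amplicon anchor "
            f"{panel.amplicon_anchor}"
        )
    return position - panel.amplicon_anchor + 1


def amplicon_offset_to_ref(panel: MarkerPanel, offset: int) -> int:
    """Inverse of :func:`ref_to_amplicon_offset`."""
    if offset < 1:
        raise ValueError("amplicon offsets are 1-based")
    return offset + panel.amplicon_anchor - 1


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; order is preserved.  Raises
    :class:`FastaParseError` naming the offending record on an empty
    sequence or a character outside the IUPAC alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _match_positions(template: str, probe: str, max_mismatches: int) -> list[int]:
    """1-based start positions where `probe` matches the template plus strand."""
    hits = []
    n, m = len(template), len(probe)
    for start in range(n - m + 1):
        mismatches = 0
        for t, p in zip(template[start:start + m], probe):
            if not base_matches(t, p):
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            hits.append(start + 1)
    return hits


def find_primer_sites(template: SequenceRecord,
                      primers: PrimerPair) -> list[tuple[int, int]]:
    """Find (forward_start, reverse_start) site pairs on a template.

    The forward primer is matched on the plus strand; the reverse primer is
    matched as its reverse complement strictly downstream of the forward
    site (the designed-PCR orientation).  Positions are 1-based template
    coordinates of each primer's 5'-most template base; pairs are reported
    in 5'->3' order.
    """
    fwd_hits = _match_positions(template.seq, primers.forward,
                                primers.max_mismatches)
    rev_hits = _match_positions(template.seq, revcomp(primers.reverse),
                                primers.max_mismatches)
    pairs = []
    for f in fwd_hits:
        for r in rev_hits:
            if r >= f + len(primers.forward):
                pairs.append((f, r))
    return sorted(pairs)


def extract_amplicon(template: SequenceRecord, primers: PrimerPair,
                     gene: str | None = None) -> SequenceRecord:
    """Extract the unique primer-to-primer (inclusive) PCR product.

    Raises :class:`NoProductError` when no site pair exists and
    :class:`NonSpecificAmplificationError` (with the site count) when the
    reaction would yield more than one product.
    """
    sites = find_primer_sites(template, primers)
    if not sites:
        raise NoProductError(f"no product on template {template.id!r}")
    if len(sites) > 1:
        raise NonSpecificAmplificationError(template.id, len(sites))
    f, r = sites[0]
    end = r + len(primers.reverse) - 1
    tag = f"|{gene}_amplicon" if gene else "|amplicon"
    return SequenceRecord(id=template.id + tag, seq=template.seq[f - 1:end])


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

def _locus_from_config(d: dict, coordinate_system: str) -> SnpLocus:
    return SnpLocus(
        name=d["name"], position=int(d["position"]),
        ref_base=d["ref"], alt_base=d["alt"],
        coordinate_system=coordinate_system,
        informative=bool(d.get("informative", True)),
    )


def panel_from_config(cfg: dict) -> MarkerPanel:
    """Build a :class:`MarkerPanel` from a parsed YAML/JSON mapping."""
    mc = cfg["mc1r"]
    nr = cfg["nr6a1"]
    mc1r_loci = [_locus_from_config(d, mc["coordinate_system"]) for d in mc["loci"]]
    nr_locus = _locus_from_config(nr["locus"], nr["coordinate_system"])

    assays = {
        "MC1R": GeneAssay(
            gene="MC1R", coordinate_system=mc["coordinate_system"],
            primers=PrimerPair(**mc["primers"]),
            product_start=int(mc["product_start"]),
            metadata={"reported_amplicon_length": mc.get("reported_amplicon_length")},
        ),
        "NR6A1": GeneAssay(
            gene="NR6A1", coordinate_system=nr["coordinate_system"],
            primers=PrimerPair(**nr["primers"]),
            product_start=int(nr["product_start"]),
            metadata={
                "reported_sequence_length": nr.get("reported_sequence_length"),
                **nr.get("instrument_metadata", {}),
            },
        ),
    }
    enzymes, enzyme_locus = {}, {}
    for name, e in mc["enzymes"].items():
        enzymes[name] = Enzyme(name=name, recognition_site=e["site"],
                               cut_offset=int(e["cut_offset"]))
        enzyme_locus[name] = e["locus"]
    band_keys = {
        enz: [(frozenset(entry["bands"]), entry["genotype"]) for entry in entries]
        for enz, entries in mc["band_keys"].items()
    }
    probes = ProbeSet(
        allele_c_probe=nr["probes"]["allele_C"]["sequence"],
        allele_t_probe=nr["probes"]["allele_T"]["sequence"],
        c_discriminating_index=int(nr["probes"]["allele_C"]["discriminating_index"]),
        t_discriminating_index=int(nr["probes"]["allele_T"]["discriminating_index"]),
    )
    return MarkerPanel(
        mc1r_loci=mc1r_loci, nr6a1_locus=nr_locus, assays=assays,
        enzymes=enzymes, enzyme_locus=enzyme_locus, band_keys=band_keys,
        probes=probes, amplicon_anchor=int(mc["amplicon_anchor"]),
        name=cfg.get("panel_name", "custom"),
        version=str(cfg.get("panel_version", "0")),
    )


def load_panel(path=None) -> MarkerPanel:
    """Load a marker panel from YAML; with no path, the packaged default."""
    if path is None:
        ref = importlib.resources.files("boarmark.data") / "default_panel.yaml"
        cfg = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    return panel_from_config(cfg)


def default_panel() -> MarkerPanel:
    return load_panel(None)
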