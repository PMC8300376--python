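"""Diploid SNP calling from IUPAC consensus sequences and in-silico TaqMan.

Direct Sanger sequencing of a diploid PCR product yields one consensus
string in which a heterozygous position appears as the two-base IUPAC
code (R for A/G, Y for C/T).  ``call_snp`` reads the base at a panel
locus and converts it into an unordered diploid genotype;
``taqman_call`` models allelic discrimination as exact probe-template
matching with IUPAC expansion on the template side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .markers import (IUPAC_EXPANSION, MarkerPanel, ProbeSet, SequenceRecord,
                      SnpLocus, base_matches)


class UnexpectedAlleleError(ValueError):
    """Observed base incompatible with the locus' ref/alt alleles."""

    def __init__(self, locus: str, base: str):
        self.locus, self.base = locus, base
        super().__init__(f"unexpected allele at {locus}: observed {base!r}")


class ProbeDropoutError(RuntimeError):
    """Neither allele-specific probe matches the target sequence."""


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass(frozen=True)
class LocusCall:
    """Unordered diploid call at one panel locus."""

    locus: str
    alleles: tuple[str, str]     # sorted alphabetically
    zygosity: Zygosity

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def genotype(self) -> str:
        """Two-character genotype string, e.g. ``"AG"``."""
        return "".join(self.alleles)


@dataclass
class MultilocusGenotype:
    """Per-sample calls at the panel loci."""

    sample_id: str
    breed_label: str
    calls: dict[str, LocusCall] = field(default_factory=dict)

    def genotype(self, locus_name: str) -> str:
        return self.calls[locus_name].genotype


def call_snp(amplicon: SequenceRecord, locus: SnpLocus,
             panel: MarkerPanel) -> LocusCall:
    """Call the diploid genotype at one locus from a consensus amplicon.

    The amplicon is the primer-to-primer PCR product; the locus is located
    via the panel's product coordinates.  A plain base yields a
    homozygote, the ref/alt two-base IUPAC code a heterozygote; anything
    else raises :class:`UnexpectedAlleleError`.
    """
    off = panel.offset_in_product(locus)
    if off > len(amplicon.seq):
        raise ValueError(f"{locus.name}: offset {off} beyond amplicon end")
    base = amplicon.seq[off - 1]
    if base == locus.ref_base:
        return LocusCall(locus.name, (locus.ref_base,) * 2, Zygosity.HOM_REF)
    if base == locus.alt_base:
        return LocusCall(locus.name, (locus.alt_base,) * 2, Zygosity.HOM_ALT)
    if IUPAC_EXPANSION.get(base) == frozenset((locus.ref_base, locus.alt_base)):
        return LocusCall(locus.name, (locus.ref_base, locus.alt_base),
                         Zygosity.HET)
    raise UnexpectedAlleleError(locus.name, base)


def call_all(amplicon: SequenceRecord, panel: MarkerPanel,
             sample_id: str | None = None,
             breed_label: str = "") -> MultilocusGenotype:
    """Call every MC1R panel locus on one amplicon.

    The c.729 call is retained (its ``informative`` flag on the panel
    locus marks it non-discriminating for allele-class assignment).
    """
    sid = sample_id or amplicon.id
    g = MultilocusGenotype(sample_id=sid, breed_label=breed_label)
    for locus in panel.mc1r_loci:
        g.calls[locus.name] = call_snp(amplicon, locus, panel)
    return g


def taqman_call(target_seq: SequenceRecord, probes: ProbeSet) -> str:
    """In-silico allelic discrimination: returns ``"CC"``, ``"CT"`` or ``"TT"``.

    Each probe is matched by exact containment against the target with
    IUPAC expansion on the template side, so a heterozygous Y at the
    discriminating position lights up both probes.  Neither probe matching
    raises :class:`ProbeDropoutError`.
    """
    def probe_hits(probe: str) -> bool:
        t = target_seq.seq
        m = len(probe)
        return any(
            all(base_matches(tb, pb) for tb, pb in zip(t[i:i + m], probe))
            for i in range(len(t) - m + 1)
        )

    c = probe_hits(probes.allele_c_probe)
    t = probe_hits(probes.allele_t_probe)
    if c and t:
        return "CT"
    if c:
        return "CC"
    if t:
        return "TT"
    raise ProbeDropoutError(
        f"probe dropout on {target_seq.id!r}: neither allele probe matches"
    )


# ---------------------------------------------------------------------------
# Cohort-level SNP discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariablePosition:
    """A reference position at which the cohort differs from the backbone."""

    position: int                 # reference coordinate (e.g. 370)
    reference_base: str
    observed_bases: tuple[str, ...]
    segregating: bool             # more than one base state among samples
    fixed_difference: bool        # all samples differ identically from ref


def find_variable_positions(amplicons, reference: SequenceRecord,
                            panel: MarkerPanel, gene: str = "MC1R",
                            include_fixed_differences: bool = True,
                            ) -> list[VariablePosition]:
    """Column-wise SNP discovery against the wild-type amplicon.

    All amplicons share the reference's coordinate frame (the assay is a
    designed PCR; there are no indels), so alignment is positional.  A
    column is reported when any sample's base (IUPAC-expanded) is not
    exactly the reference base.  Positions are mapped back onto the
    panel's reference coordinate system.  A fixed difference (every sample
    carries the same non-reference base, as c.729 does here) is included
    unless ``include_fixed_differences`` is false.
    """
    start = panel.assays[gene].product_start
    out = []
    for i, ref_base in enumerate(reference.seq):
        column = {a.seq[i] for a in amplicons if i < len(a.seq)}
        if column == {ref_base}:
            continue
        states: set[str] = set()
        for b in column:
            states |= IUPAC_EXPANSION[b]
        segregating = len(states) > 1
        fixed = len(states) == 1 and ref_base not in states
        if fixed and not include_fixed_differences:
            continue
        out.append(VariablePosition(
            position=start + i, reference_base=ref_base,
            observed_bases=tuple(sorted(column)),
            segregating=segregating, fixed_difference=fixed,
        ))
    return out


# ---------------------------------------------------------------------------
# Genotype table I/O
# ---------------------------------------------------------------------------

def genotypes_to_frame(genotypes, nr6a1_calls: dict[str, str] | None = None
                       ) -> pd.DataFrame:
    """One row per sample, one column per locus (values like ``"AG"``)."""
    rows = []
    for g in genotypes:
        row = {"sample_id": g.sample_id, "breed": g.breed_label}
        for name, call in g.calls.items():
            row[name] = call.genotype
        if nr6a1_calls is not None:
            row["NR6A1:g.748"] = nr6a1_calls.get(g.sample_id, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_genotype_csv(genotypes, path,
                       nr6a1_calls: dict[str, str] | None = None) -> None:
    genotypes_to_frame(genotypes, nr6a1_calls).to_csv(path, index=False)


def read_genotype_csv(path, panel: MarkerPanel) -> list[MultilocusGenotype]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        g = MultilocusGenotype(sample_id=str(row["sample_id"]),
                               breed_label=str(row.get("breed", "")))
        for locus in panel.mc1r_loci:
            if locus.name not in df.columns:
                continue
            gt = str(row[locus.name])
            alleles = tuple(sorted(gt))
            if alleles[0] == alleles[1]:
                zyg = (Zygosity.HOM_REF if alleles[0] == locus.ref_base
                       else Zygosity.HOM_ALT)
            else:
                zyg = Zygosity.HET
            g.calls[locus.name] = LocusCall(locus.name, alleles, zyg)
        out.append(g)
    return out
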