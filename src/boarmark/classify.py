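"""Extension-locus allele nomenclature and the dual-marker decision rule.

The three discriminating MC1R SNPs define three distinguishable allele
classes:

======  =======  =======  =======  =================================
class   c.370    c.491    c.727    meaning
======  =======  =======  =======  =================================
E+      G        C        G        wild type (wild boar)
e       G        T        A        recessive red (Duroc)
ED      A        C        G        dominant black / black spotting
======  =======  =======  =======  =================================

"ED" here is a merged class: the dominant-black and black-spotting
alleles (ED1, ED2, EP2 and EP3) are not separable by these three SNPs,
so the classifier reports the class with its ambiguity members attached.
EP3 in particular has no distinguishing pattern at the panel loci and is
flagged unresolvable-by-panel; a ground-truth EP3 can only enter results
through an externally supplied diplotype column.

The subspecies verdict combines the NR6A1 g.748C>T genotype (C = wild
boar lineage, T = domestic lineage) with the MC1R diplotype: NR6A1 draws
the wild/domestic line, MC1R flags admixed profiles on either side, and
a heterozygous CT is a first-generation hybrid regardless of MC1R.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .genotyping import MultilocusGenotype

#: The three discriminating loci, in panel order.
DISCRIMINATING_LOCI = ("MC1R:c.370", "MC1R:c.491", "MC1R:c.727")

#: SNP pattern per distinguishable allele class (base at 370, 491, 727).
ALLELE_CLASS_PATTERNS: dict[str, tuple[str, str, str]] = {
    "E+": ("G", "C", "G"),
    "e": ("G", "T", "A"),
    "ED": ("A", "C", "G"),
}

#: Alleles folded into the merged ED class.
ED_AMBIGUITY_MEMBERS = ("ED1", "ED2", "EP2", "EP3")

#: Class labels whose carriers belong to the domestic gene pool.
DOMESTIC_CLASSES = frozenset({"e", "ED", "EP3"})

#: Canonical ordering used to normalise unordered class pairs.
_CLASS_ORDER = {"E+": 0, "e": 1, "ED": 2, "EP3": 3}


def normalize_pair(pair) -> tuple[str, str]:
    """Order a class pair canonically (the pair is unordered)."""
    return tuple(sorted(pair, key=lambda c: _CLASS_ORDER.get(c, 99)))


def pair_label(pair) -> str:
    return "/".join(normalize_pair(pair))


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of allele-class labels for one sample.

    When several phasings of a multi-heterozygous genotype are consistent
    with defined allele classes, ``phase_ambiguous`` is set and
    ``candidate_pairs`` lists every consistent pair.  When no phasing
    matches, the pair is ``("unrecognized", "unrecognized")`` and the raw
    haplotype patterns of one arbitrary phasing are attached.
    """

    sample_id: str
    pair: tuple[str, str]
    breed_label: str = ""
    provenance: str = "sequence"
    phase_ambiguous: bool = False
    candidate_pairs: tuple[tuple[str, str], ...] = ()
    unrecognized_patterns: tuple[tuple[str, str, str], ...] = ()

    @property
    def label(self) -> str:
        return pair_label(self.pair)

    @property
    def is_recognized(self) -> bool:
        return "unrecognized" not in self.pair

    def contains(self, cls: str) -> bool:
        return cls in self.pair


@dataclass(frozen=True)
class SubspeciesCall:
    """Combined verdict for one sample."""

    sample_id: str
    nr6a1: str                    # "CC" | "CT" | "TT"
    mc1r_flag: str                # wild_type | domestic_type | admixed | unresolved
    verdict: str                  # wild_boar | domestic_pig | hybrid |
    #                               admixed_wild_boar | admixed_domestic
    breed_label: str = ""


class MissingLocusError(ValueError):
    pass


def _phasings(genotype: MultilocusGenotype):
    """All distinct phasings into two haplotype 3-mers (unordered)."""
    allele_pairs = []
    for name in DISCRIMINATING_LOCI:
        if name not in genotype.calls:
            raise MissingLocusError(
                f"sample {genotype.sample_id!r}: no call at {name}")
        allele_pairs.append(genotype.calls[name].alleles)
    seen = set()
    for bits in itertools.product((0, 1), repeat=len(allele_pairs)):
        hap1 = tuple(p[b] for p, b in zip(allele_pairs, bits))
        hap2 = tuple(p[1 - b] for p, b in zip(allele_pairs, bits))
        key = tuple(sorted((hap1, hap2)))
        if key not in seen:
            seen.add(key)
            yield key


_PATTERN_TO_CLASS = {v: k for k, v in ALLELE_CLASS_PATTERNS.items()}


def classify_mc1r(genotype: MultilocusGenotype) -> Diplotype:
    """Map a multilocus MC1R genotype onto an allele-class diplotype.

    Every phasing of the genotype into two haplotypes is enumerated; a
    phasing is *consistent* when both haplotype patterns match a defined
    allele class.  A unique consistent pair is returned as is; several
    are returned phase-ambiguous; none yields an ``unrecognized`` pair
    carrying the raw patterns.
    """
    consistent = []
    raw = []
    for hap1, hap2 in _phasings(genotype):
        raw.append((hap1, hap2))
        c1 = _PATTERN_TO_CLASS.get(hap1)
        c2 = _PATTERN_TO_CLASS.get(hap2)
        if c1 is not None and c2 is not None:
            pair = normalize_pair((c1, c2))
            if pair not in consistent:
                consistent.append(pair)
    kw = dict(sample_id=genotype.sample_id, breed_label=genotype.breed_label)
    if len(consistent) == 1:
        return Diplotype(pair=consistent[0], **kw)
    if consistent:
        return Diplotype(pair=consistent[0], phase_ambiguous=True,
                         candidate_pairs=tuple(consistent), **kw)
    return Diplotype(pair=("unrecognized", "unrecognized"),
                     unrecognized_patterns=tuple(raw), **kw)


def mc1r_flag(diplotype: Diplotype) -> str:
    """Summarise a diplotype as wild_type / domestic_type / admixed / unresolved."""
    if not diplotype.is_recognized or diplotype.phase_ambiguous:
        return "unresolved"
    wild = [c == "E+" for c in diplotype.pair]
    domestic = [c in DOMESTIC_CLASSES for c in diplotype.pair]
    if all(wild):
        return "wild_type"
    if all(domestic):
        return "domestic_type"
    if any(wild) and any(domestic):
        return "admixed"
    return "unresolved"


def decide_subspecies(nr6a1_call: str, diplotype: Diplotype) -> SubspeciesCall:
    """Dual-marker decision: NR6A1 splits the subspecies, MC1R flags admixture.

    ======  =============  ====================
    NR6A1   MC1R flag      verdict
    ======  =============  ====================
    CC      wild_type      wild_boar
    CC      domestic_type  admixed_wild_boar
    CC      admixed        admixed_wild_boar
    CC      unresolved     wild_boar
    TT      wild_type      admixed_domestic
    TT      domestic_type  domestic_pig
    TT      admixed        admixed_domestic
    TT      unresolved     domestic_pig
    CT      any            hybrid
    ======  =============  ====================
    """
    if nr6a1_call not in ("CC", "CT", "TT"):
        raise ValueError(f"invalid NR6A1 call {nr6a1_call!r}")
    flag = mc1r_flag(diplotype)
    if nr6a1_call == "CT":
        verdict = "hybrid"
    elif nr6a1_call == "CC":
        verdict = ("admixed_wild_boar" if flag in ("domestic_type", "admixed")
                   else "wild_boar")
    else:
        verdict = ("admixed_domestic" if flag in ("wild_type", "admixed")
                   else "domestic_pig")
    return SubspeciesCall(sample_id=diplotype.sample_id, nr6a1=nr6a1_call,
                          mc1r_flag=flag, verdict=verdict,
                          breed_label=diplotype.breed_label)


def summarize_cohort(diplotypes, calls) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency tables: breed x diplotype and breed x verdict.

    Returns a pair of DataFrames whose cell values are sample counts;
    both are empty (zero totals) on empty input.
    """
    dip_rows = [{"breed": d.breed_label, "diplotype": d.label}
                for d in diplotypes]
    ver_rows = [{"breed": c.breed_label, "verdict": c.verdict} for c in calls]
    dip = (pd.crosstab(pd.Series([r["breed"] for r in dip_rows], dtype=object),
                       pd.Series([r["diplotype"] for r in dip_rows], dtype=object))
           if dip_rows else pd.DataFrame())
    ver = (pd.crosstab(pd.Series([r["breed"] for r in ver_rows], dtype=object),
                       pd.Series([r["verdict"] for r in ver_rows], dtype=object))
           if ver_rows else pd.DataFrame())
    for df in (dip, ver):
        df.index.name = "breed"
        df.columns.name = None
    return dip, ver
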