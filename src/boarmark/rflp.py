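"""In-silico restriction digestion and gel band-pattern interpretation.

The PCR-RFLP read-out for the extension locus: BspHI reports c.370G>A
(the A allele creates a site, 672 -> 472 + 200) and BstUI reports
c.727G>A (the G allele carries a second site, 289 + 222 + 110; the A
allele destroys it, merging 222 + 110 into 332).  Heterozygotes show the
union of both haplotypes' fragments.  c.491C>T has no diagnostic enzyme
and is typed only by sequencing or probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genotyping import LocusCall, Zygosity
from .markers import Enzyme, STRICT_ALPHABET, revcomp


class UninterpretableGelError(ValueError):
    """A band pattern that matches no key entry."""

    def __init__(self, pattern, nearest):
        self.pattern = pattern
        self.nearest = nearest
        near = "; ".join(f"{sorted(b, reverse=True)} -> {g}" for b, g in nearest)
        super().__init__(
            f"uninterpretable gel pattern {sorted(pattern, reverse=True)}; "
            f"nearest key entries: {near}"
        )


@dataclass(frozen=True)
class BandPattern:
    """Multiset of restriction-fragment lengths, gel-ordered (descending).

    ``resolution_bp`` is the merge tolerance within which co-migrating
    bands are indistinguishable; 0 means exact lengths.
    """

    fragments: tuple[int, ...]
    resolution_bp: int = 0

    def __post_init__(self):
        if any(f < 1 for f in self.fragments):
            raise ValueError("fragment lengths must be >= 1")
        object.__setattr__(self, "fragments",
                           tuple(sorted(self.fragments, reverse=True)))

    def bands(self) -> tuple[int, ...]:
        """Distinct band lengths after merging within the resolution."""
        merged: list[int] = []
        for f in self.fragments:           # descending
            if merged and merged[-1] - f <= self.resolution_bp:
                continue                    # co-migrates with the previous band
            merged.append(f)
        return tuple(merged)

    def matches(self, key_bands, resolution_bp: int | None = None) -> bool:
        res = self.resolution_bp if resolution_bp is None else resolution_bp
        mine = self.bands()
        theirs = tuple(sorted(key_bands, reverse=True))
        if len(mine) != len(theirs):
            return False
        return all(abs(a - b) <= res for a, b in zip(mine, theirs))


def cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """0-based positions after which the enzyme cuts the top strand.

    The plus strand is scanned for the recognition site; for a
    non-palindromic site the minus strand is scanned as well (as the
    site's reverse complement, with the cut mirrored).  Palindromic sites
    (both enzymes shipped here) need only the plus-strand scan.
    """
    if set(seq) - STRICT_ALPHABET:
        raise ValueError("digestion requires an unambiguous ACGT haplotype "
                         "sequence; digest diploids per haplotype")
    site = enzyme.recognition_site
    m = len(site)
    cuts = set()
    for i in range(len(seq) - m + 1):
        if seq[i:i + m] == site:
            cuts.add(i + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        rc = revcomp(site)
        for i in range(len(seq) - m + 1):
            if seq[i:i + m] == rc:
                cuts.add(i + (m - enzyme.cut_offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths, 5'->3', from a complete digestion of one strand.

    With no site present the whole molecule is returned as one fragment.
    Fragment lengths always sum to the sequence length.
    """
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def diploid_band_pattern(hap1: str, hap2: str, enzyme: Enzyme,
                         resolution_bp: int = 0) -> BandPattern:
    """Gel pattern of a diploid sample: union of both haplotypes' fragments.

    Equal-length fragments from the two chromosomes co-migrate and are a
    single band; ``resolution_bp`` widens the merge window.
    """
    if len(hap1) != len(hap2):
        raise ValueError("haplotypes must have equal length")
    frags = sorted(set(digest(hap1, enzyme)) | set(digest(hap2, enzyme)),
                   reverse=True)
    return BandPattern(fragments=tuple(frags), resolution_bp=resolution_bp)


def bands_to_genotype(pattern: BandPattern, band_key, locus_name: str,
                      ref_base: str, alt_base: str) -> LocusCall:
    """Decode a gel pattern into a per-locus genotype via the assay's key.

    ``band_key`` is a list of ``(frozenset_of_lengths, genotype_string)``
    entries, e.g. ``({672}, "GG")``.  An unmatched pattern raises
    :class:`UninterpretableGelError` listing the nearest key entries.
    """
    for bands, genotype in band_key:
        if pattern.matches(bands):
            alleles = tuple(sorted(genotype))
            if genotype == 2 * ref_base:
                zyg = Zygosity.HOM_REF
            elif genotype == 2 * alt_base:
                zyg = Zygosity.HOM_ALT
            else:
                zyg = Zygosity.HET
            return LocusCall(locus=locus_name, alleles=alleles, zygosity=zyg)
    mine = set(pattern.bands())
    nearest = sorted(band_key,
                     key=lambda e: len(mine.symmetric_difference(e[0])))[:2]
    raise UninterpretableGelError(mine, nearest)


def genotype_from_gel(pattern: BandPattern, panel, enzyme_name: str) -> LocusCall:
    """Panel-aware convenience wrapper around :func:`bands_to_genotype`."""
    locus = panel.locus(panel.enzyme_locus[enzyme_name])
    return bands_to_genotype(pattern, panel.band_keys[enzyme_name],
                             locus.name, locus.ref_base, locus.alt_base)


@dataclass
class GelLane:
    """One sample x enzyme row of the band-pattern CSV export."""

    sample_id: str
    enzyme: str
    pattern: BandPattern

    def as_row(self) -> dict:
        return {"sample_id": self.sample_id, "enzyme": self.enzyme,
                "bands": ",".join(str(b) for b in self.pattern.bands())}
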