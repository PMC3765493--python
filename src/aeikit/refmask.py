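"""Bias-attenuating reference genome construction.

Aligners score a read base that differs from the reference as a mismatch,
so reads carrying the non-reference allele at a heterozygous SNP are
systematically under-mapped ("reference bias").  Two remedies are provided
here: genome-wide IUPAC ambiguity masking, which replaces every catalogued
SNP position with the two-base ambiguity character so that either allele
matches, and targeted allele switching, which substitutes the variant
allele into the reference at a chosen panel of sites so that the bias can
be measured from the reference-allele counts of the two alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Two-base IUPAC ambiguity characters keyed by the unordered base pair.
_IUPAC2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: Reverse map: ambiguity character -> the set of bases it covers.
IUPAC_BASES = {code: set(pair) for pair, code in _IUPAC2.items()}

REGION_CLASSES = (
    "exonic",
    "UTR",
    "intronic",
    "intergenic",
    "upstream_downstream",
    "ncRNA_exonic",
)


class InvalidBaseError(ValueError):
    """A nucleotide outside {A, C, G, T} where a canonical base is required."""


class InvalidPairError(ValueError):
    """Ref and alt allele are identical (no ambiguity to encode)."""


@dataclass(frozen=True)
class VariantSite:
    """A catalogued biallelic SNV.

    Coordinates are 1-based throughout the package (VCF/dbSNP convention);
    BED inputs are converted on read.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_id: str = ""
    gene: str = ""
    region_class: str = "intergenic"

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise InvalidBaseError(
                f"{self.site_id or self.chrom + ':' + str(self.pos)}: alleles must "
                f"be single A/C/G/T bases, got {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise InvalidPairError(
                f"{self.chrom}:{self.pos}: ref and alt allele are both {self.ref_allele!r}"
            )
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: positions are 1-based (pos >= 1)")

    def with_annotation(self, gene: str, region_class: str) -> "VariantSite":
        if region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {region_class!r}")
        return replace(self, gene=gene, region_class=region_class)


@dataclass
class ReferenceGenome:
    """In-memory nucleotide sequences plus a provenance tag.

    ``provenance`` records how the genome was derived: ``standard`` (plain
    A/C/G/T/N), ``iupac_masked`` (catalogued SNPs replaced by ambiguity
    characters) or ``allele_switched`` (variant alleles substituted in).
    """

    sequences: Mapping[str, str]
    provenance: str = "standard"

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base_at(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


@dataclass(frozen=True)
class SkippedSite:
    """Audit record for a catalog site that was not applied to the genome."""

    site: VariantSite
    reason: str
    observed_base: str = ""


def iupac_code(ref_base: str, alt_base: str) -> str:
    """Two-base IUPAC ambiguity character for an unordered base pair.

    Symmetric in its arguments: ``iupac_code("C", "G") == iupac_code("G", "C")``.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in VALID_BASES:
        raise InvalidBaseError(f"not a canonical base: {ref_base!r}")
    if alt_base not in VALID_BASES:
        raise InvalidBaseError(f"not a canonical base: {alt_base!r}")
    if ref_base == alt_base:
        raise InvalidPairError(f"identical alleles {ref_base!r}: no ambiguity to encode")
    return _IUPAC2[frozenset((ref_base, alt_base))]


def _check_bounds(genome: ReferenceGenome, site: VariantSite) -> None:
    if site.chrom not in genome:
        raise KeyError(f"chromosome {site.chrom!r} not present in genome")
    if site.pos > genome.chrom_length(site.chrom):
        raise IndexError(
            f"{site.chrom}:{site.pos} beyond chromosome end "
            f"({genome.chrom_length(site.chrom)} bp)"
        )


def mask_reference(
    genome: ReferenceGenome,
    catalog: Iterable[VariantSite],
    strict: bool = False,
) -> tuple[ReferenceGenome, list[SkippedSite]]:
    """Replace every catalogued SNP position with its IUPAC ambiguity character.

    Positions whose genome base disagrees with the catalogued reference
    allele are skipped with a warning (public catalogs routinely contain
    strand or build discrepancies); ``strict=True`` upgrades the skip to an
    error.  Sites beyond the chromosome end always raise.

    Returns the masked genome (provenance ``iupac_masked``) and the audit
    list of skipped sites.
    """
    if genome.provenance != "standard":
        raise ValueError(f"expected a standard genome, got provenance {genome.provenance!r}")
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.sequences.items()}
    skipped: list[SkippedSite] = []
    for site in catalog:
        _check_bounds(genome, site)
        observed = chr(buffers[site.chrom][site.pos - 1])
        if observed != site.ref_allele:
            msg = (
                f"{site.chrom}:{site.pos} genome base {observed} != catalogued "
                f"ref {site.ref_allele}; site skipped"
            )
            if strict:
                raise ValueError(msg)
            log.warning(msg)
            skipped.append(SkippedSite(site, "ref_mismatch", observed))
            continue
        buffers[site.chrom][site.pos - 1] = ord(iupac_code(site.ref_allele, site.alt_allele))
    masked = ReferenceGenome(
        {name: buf.decode("ascii") for name, buf in buffers.items()},
        provenance="iupac_masked",
    )
    if skipped:
        log.warning("mask_reference: %d site(s) skipped (ref mismatch)", len(skipped))
    return masked, skipped


def switch_alleles(
    genome: ReferenceGenome,
    targets: Iterable[VariantSite],
    strict: bool = False,
) -> tuple[ReferenceGenome, list[SkippedSite]]:
    """Substitute the variant allele into the reference at each target site.

    Applying the operation twice with ref/alt swapped on the second pass
    restores the original genome (involution).
    """
    if genome.provenance != "standard":
        raise ValueError(f"expected a standard genome, got provenance {genome.provenance!r}")
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.sequences.items()}
    skipped: list[SkippedSite] = []
    for site in targets:
        _check_bounds(genome, site)
        observed = chr(buffers[site.chrom][site.pos - 1])
        if observed != site.ref_allele:
            msg = (
                f"{site.chrom}:{site.pos} genome base {observed} != catalogued "
                f"ref {site.ref_allele}; site skipped"
            )
            if strict:
                raise ValueError(msg)
            log.warning(msg)
            skipped.append(SkippedSite(site, "ref_mismatch", observed))
            continue
        buffers[site.chrom][site.pos - 1] = ord(site.alt_allele)
    switched = ReferenceGenome(
        {name: buf.decode("ascii") for name, buf in buffers.items()},
        provenance="allele_switched",
    )
    return switched, skipped


def resolve_mask(genome: ReferenceGenome, catalog: Iterable[VariantSite]) -> ReferenceGenome:
    """Undo IUPAC masking by resolving each catalogued position to its ref allele.

    ``resolve_mask(mask_reference(g, c)[0], c)`` reproduces ``g`` exactly for
    any catalog that masked cleanly.
    """
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.sequences.items()}
    for site in catalog:
        code = chr(buffers[site.chrom][site.pos - 1])
        if code in IUPAC_BASES and IUPAC_BASES[code] == {site.ref_allele, site.alt_allele}:
            buffers[site.chrom][site.pos - 1] = ord(site.ref_allele)
    return ReferenceGenome(
        {name: buf.decode("ascii") for name, buf in buffers.items()},
        provenance="standard",
    )
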