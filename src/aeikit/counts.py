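"""Per-site allelic read counts: pileup, depth filters, gene annotation,
and merging of nearby SNPs into single observations.

Ratio mathematics downstream uses only the informative depth
(``ref_count + var_count``); reads carrying a third base are tallied in
``other_count`` and excluded from ratios.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam
from intervaltree import IntervalTree

from .refmask import VariantSite

log = logging.getLogger(__name__)

#: Retention rule for a site to enter ratio analysis: each allele must be
#: supported by at least 3 reads (6 informative reads total) and the lower
#: expressed allele must account for at least 5% of informative reads.
MIN_PER_ALLELE = 3
MIN_MINOR_FRACTION = 0.05

#: Pileup defaults.  Reads below MAPQ 1 (ambiguous placements) and bases
#: below quality 13 (error probability > 5%) are ignored.
DEFAULT_MIN_MAPQ = 1
DEFAULT_MIN_BASEQ = 13


@dataclass(frozen=True)
class AllelicCount:
    """Reference/variant/other read tallies for one sample at one site."""

    site: VariantSite
    sample_id: str
    ref_count: int
    var_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_count, self.var_count, self.other_count) < 0:
            raise ValueError(f"negative count at {self.site.chrom}:{self.site.pos}")

    @property
    def informative_depth(self) -> int:
        return self.ref_count + self.var_count

    @property
    def minor_fraction(self) -> float:
        depth = self.informative_depth
        return min(self.ref_count, self.var_count) / depth if depth else 0.0


@dataclass(frozen=True)
class GeneInterval:
    """A gene feature interval; coordinates are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    gene: str
    feature: str = "exonic"  # exonic | UTR | ncRNA_exonic


def pileup_counts(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    sites: Sequence[VariantSite],
    sample_id: str,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> list[AllelicCount]:
    """Tally reads supporting the ref, alt, or another base at each site.

    Every aligned, non-secondary read overlapping a site contributes to
    exactly one of ``ref_count``/``var_count``/``other_count`` according to
    its base at that position; reads with a deletion or clip at the
    position contribute to none.  Sites on chromosomes absent from the
    alignment file yield zero counts with a warning.
    """
    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments), "r") if own_handle else alignments

    by_chrom: dict[str, dict[int, list[int]]] = {}
    for idx, site in enumerate(sites):
        by_chrom.setdefault(site.chrom, {}).setdefault(site.pos - 1, []).append(idx)

    known_chroms = set(af.references or [])
    for chrom in by_chrom:
        if known_chroms and chrom not in known_chroms:
            log.warning("pileup_counts: chromosome %r absent from alignments", chrom)

    ref_n = [0] * len(sites)
    var_n = [0] * len(sites)
    other_n = [0] * len(sites)

    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            positions = by_chrom.get(read.reference_name)
            if not positions:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                idxs = positions.get(rpos)
                if idxs is None:
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos]
                for i in idxs:
                    if base == sites[i].ref_allele:
                        ref_n[i] += 1
                    elif base == sites[i].alt_allele:
                        var_n[i] += 1
                    else:
                        other_n[i] += 1
    finally:
        if own_handle:
            af.close()

    return [
        AllelicCount(site, sample_id, ref_n[i], var_n[i], other_n[i])
        for i, site in enumerate(sites)
    ]


def filter_sites(
    counts: Iterable[AllelicCount],
    min_per_allele: int = MIN_PER_ALLELE,
    min_minor_fraction: float = MIN_MINOR_FRACTION,
) -> list[AllelicCount]:
    """Retain sites where both alleles are adequately supported.

    A count passes when ``ref_count >= min_per_allele``,
    ``var_count >= min_per_allele``, and the minor allele accounts for at
    least ``min_minor_fraction`` of informative reads.  Order is preserved
    and the operation is idempotent.
    """
    return [
        c
        for c in counts
        if c.ref_count >= min_per_allele
        and c.var_count >= min_per_allele
        and c.minor_fraction >= min_minor_fraction
    ]


def _interval_trees(intervals: Iterable[GeneInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        # IntervalTree is half-open; store [start, end+1) so 1-based
        # inclusive endpoints are hit.
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv)
    return trees


def annotate_sites(
    sites: Sequence[VariantSite],
    gene_intervals: Iterable[GeneInterval],
) -> list[VariantSite]:
    """Assign each site a gene symbol and region class by interval overlap.

    Sites overlapping no interval become ``intergenic``.  A site inside
    intervals of several genes yields one annotated copy per gene (with a
    warning) so gene-level combination stays computable for each.
    """
    trees = _interval_trees(gene_intervals)
    annotated: list[VariantSite] = []
    for site in sites:
        tree = trees.get(site.chrom)
        hits = sorted(tree[site.pos], key=lambda h: h.data.gene) if tree else []
        genes_seen: dict[str, str] = {}
        for hit in hits:
            iv: GeneInterval = hit.data
            # UTR labels win over plain exonic for the same gene.
            if iv.gene not in genes_seen or iv.feature == "UTR":
                genes_seen[iv.gene] = iv.feature
        if not genes_seen:
            annotated.append(site.with_annotation("", "intergenic"))
            continue
        if len(genes_seen) > 1:
            log.warning(
                "site %s:%d overlaps %d genes (%s); emitting one copy per gene",
                site.chrom, site.pos, len(genes_seen), ",".join(sorted(genes_seen)),
            )
        for gene, feature in sorted(genes_seen.items()):
            annotated.append(site.with_annotation(gene, feature))
    return annotated


def exonic_only(sites: Iterable[VariantSite]) -> list[VariantSite]:
    """Sites eligible for ratio analysis: exonic (including UTR and ncRNA exons)."""
    keep = {"exonic", "UTR", "ncRNA_exonic"}
    return [s for s in sites if s.region_class in keep]


@dataclass(frozen=True)
class SiteObservation:
    """One folded allelic ratio anchored at a genomic position."""

    chrom: str
    pos: int
    folded_ratio: float
    n_sites: int = 1


def merge_windows(
    observations: Sequence[SiteObservation],
    window_bp: int = 100,
) -> list[SiteObservation]:
    """Average folded ratios of SNPs within a window into one observation.

    SNPs close enough to sit on the same sequenced fragment are not
    independent, so they are clustered greedily left to right: a new
    cluster starts when a site lies more than ``window_bp`` from the first
    site of the current cluster.  Each cluster contributes one observation
    (arithmetic mean of member folded ratios) anchored at the first site.
    Input must be position-sorted within one gene and sample.
    """
    merged: list[SiteObservation] = []
    cluster: list[SiteObservation] = []
    for obs in observations:
        if cluster and (obs.chrom != cluster[0].chrom or obs.pos - cluster[0].pos > window_bp):
            merged.append(_collapse(cluster))
            cluster = []
        if cluster and obs.pos < cluster[-1].pos:
            raise ValueError("observations must be sorted by position")
        cluster.append(obs)
    if cluster:
        merged.append(_collapse(cluster))
    return merged


def _collapse(cluster: list[SiteObservation]) -> SiteObservation:
    mean = sum(o.folded_ratio for o in cluster) / len(cluster)
    return SiteObservation(
        chrom=cluster[0].chrom,
        pos=cluster[0].pos,
        folded_ratio=mean,
        n_sites=sum(o.n_sites for o in cluster),
    )


def read_gene_intervals_gff(path: str | os.PathLike) -> list[GeneInterval]:
    """Gene intervals from GFF3 exon and UTR features (1-based inclusive,
    as in the format itself).  The gene symbol is taken from the
    ``gene_id``, ``gene_name``, ``gene`` or ``Name`` attribute."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    feature_map = {
        "exon": "exonic",
        "five_prime_UTR": "UTR",
        "three_prime_UTR": "UTR",
        "UTR": "UTR",
    }
    intervals: list[GeneInterval] = []
    for ftype, label in feature_map.items():
        for feat in db.features_of_type(ftype):
            gene = ""
            for key in ("gene_id", "gene_name", "gene", "Name"):
                if key in feat.attributes:
                    gene = feat.attributes[key][0]
                    break
            intervals.append(GeneInterval(feat.seqid, feat.start, feat.end, gene, label))
    return intervals


def read_gene_intervals(path: str | os.PathLike) -> list[GeneInterval]:
    """Dispatch on extension: .gff/.gff3/.gtf → GFF reader, else BED."""
    if str(path).endswith((".gff", ".gff3", ".gtf")):
        return read_gene_intervals_gff(path)
    return read_gene_intervals_bed(path)


def read_gene_intervals_bed(path: str | os.PathLike) -> list[GeneInterval]:
    """Gene intervals from BED (0-based half-open, converted to 1-based
    inclusive).  The name column carries the gene symbol, optionally with a
    feature label as ``GENE|UTR``.
    """
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            gene, _, feature = name.partition("|")
            intervals.append(
                GeneInterval(chrom, start0 + 1, end0, gene, feature or "exonic")
            )
    return intervals
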