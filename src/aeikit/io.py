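"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA and SAM parsing is delegated to pysam, VCF parsing to cyvcf2.  Count
tables, site catalogs and audit files travel as TSV via pandas.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .refmask import ReferenceGenome, SkippedSite, VariantSite

log = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "site_id", "gene", "region_class",
    "sample", "ref_count", "var_count", "other_count",
]


def read_fasta(path: str | os.PathLike, provenance: str = "standard") -> ReferenceGenome:
    sequences: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            sequences[entry.name] = entry.sequence
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    return ReferenceGenome(sequences, provenance=provenance)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 60) -> None:
    """Write FASTA with fixed line width (default 60) and uppercase bases."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sites_vcf(path: str | os.PathLike) -> list[VariantSite]:
    """Biallelic SNVs from a VCF; indels and multiallelic records are skipped.

    Skip counts are logged — the masking strategy is defined only for
    biallelic single-nucleotide substitutions.
    """
    import cyvcf2

    sites: list[VariantSite] = []
    n_skipped = 0
    for rec in cyvcf2.VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in "ACGT" or rec.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        sites.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                site_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            )
        )
    if n_skipped:
        log.info("read_sites_vcf: skipped %d non-biallelic/non-SNV record(s)", n_skipped)
    return sites


def read_sites_tsv(path: str | os.PathLike) -> list[VariantSite]:
    """Site catalog from a 3+ column TSV: chrom, pos (1-based), ref>alt.

    A fourth column, if present, is taken as the site identifier.
    """
    sites: list[VariantSite] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, pos, alleles = fields[0], int(fields[1]), fields[2]
            ref, alt = alleles.split(">")
            site_id = fields[3] if len(fields) > 3 else f"{chrom}:{pos}"
            sites.append(VariantSite(chrom, pos, ref, alt, site_id))
    return sites


def read_sites(path: str | os.PathLike) -> list[VariantSite]:
    """Dispatch on extension: .vcf → VCF reader, anything else → TSV reader."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_sites_vcf(path)
    return read_sites_tsv(path)


def write_skipped_sites(skipped: Sequence[SkippedSite], path: str | os.PathLike) -> None:
    rows = [
        {
            "chrom": s.site.chrom,
            "pos": s.site.pos,
            "ref": s.site.ref_allele,
            "alt": s.site.alt_allele,
            "site_id": s.site.site_id,
            "reason": s.reason,
            "observed_base": s.observed_base,
        }
        for s in skipped
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "site_id", "reason", "observed_base"]).to_csv(
        path, sep="\t", index=False
    )


def counts_to_frame(counts: Iterable) -> pd.DataFrame:
    """Flatten AllelicCount records into the canonical count-table layout."""
    rows = []
    for c in counts:
        rows.append(
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "ref": c.site.ref_allele,
                "alt": c.site.alt_allele,
                "site_id": c.site.site_id,
                "gene": c.site.gene,
                "region_class": c.site.region_class,
                "sample": c.sample_id,
                "ref_count": c.ref_count,
                "var_count": c.var_count,
                "other_count": c.other_count,
            }
        )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def frame_to_counts(frame: pd.DataFrame) -> list:
    """Inverse of :func:`counts_to_frame`."""
    from .counts import AllelicCount

    counts = []
    for row in frame.itertuples(index=False):
        site = VariantSite(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            site_id=getattr(row, "site_id", "") or "",
            gene=getattr(row, "gene", "") or "",
            region_class=getattr(row, "region_class", "intergenic") or "intergenic",
        )
        counts.append(
            AllelicCount(
                site=site,
                sample_id=str(row.sample),
                ref_count=int(row.ref_count),
                var_count=int(row.var_count),
                other_count=int(getattr(row, "other_count", 0)),
            )
        )
    return counts


def read_counts_tsv(path: str | os.PathLike) -> list:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return frame_to_counts(frame)
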