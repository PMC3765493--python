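"""Ground-truthed synthetic fixtures: toy genomes, SNP catalogs, aligned
reads with a tunable reference-bias model, and editing-site panels.

The bias model is deliberately minimal: after reads are assigned to the
two alleles of a heterozygous site, each variant-carrying read is lost
independently with probability ``bias_beta``, mimicking an aligner that
rejects reads mismatching the reference.  Under this model the expected
observed ref/var ratio is ``true_ratio / (1 - bias_beta)``, which gives
every downstream estimate a closed-form oracle.  Alignment against an
IUPAC-masked reference is modelled as ``bias_beta = 0`` — the ambiguity
character matches both alleles at zero penalty (a documented assumption;
real aligner scoring of ambiguity characters is not simulated).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .counts import GeneInterval
from .refmask import ReferenceGenome, VariantSite

#: Default per-site true editing fractions for the two-condition panel;
#: twelve sites spanning low to near-complete editing, the range seen at
#: well-characterised brain A-to-I sites.
DEFAULT_EDITING_FRACTIONS = (
    0.60, 0.99, 0.32, 0.89, 0.21, 0.45, 0.62, 0.98, 0.68, 0.44, 0.25, 0.55,
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generators.

    Defaults mirror the targeted allele-switch panel scale (58 genes,
    ~187 SNPs), an informative depth inside the reported 24-409 reads/SNP
    range, and a variant-read loss probability of 0.33, which reproduces
    the observed ~1.5x inflation of standard-alignment ratios
    (1/(1-0.33) ≈ 1.49).
    """

    n_genes: int = 58
    snps_per_gene: tuple[int, int] = (1, 6)  # inclusive range
    #: ref/var fold: a single value for every gene, or a mapping
    #: gene -> fold (genes not listed default to the balanced 1.0)
    true_ratio: float | Mapping[str, float] = 1.0
    depth: float = 60.0  # mean informative reads per site
    bias_beta: float = 0.33  # P(variant-carrying read lost)
    n_samples: int = 9
    seed: int = 0
    fixed_depth: bool = False  # exact `depth` reads per site instead of Poisson
    read_length: int = 50
    gene_span_bp: int = 2000
    editing_fractions: Sequence[float] = DEFAULT_EDITING_FRACTIONS
    editing_n_samples: tuple[int, int] = (10, 13)  # (regions, dlpfc)
    editing_depth: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias_beta < 1.0:
            raise ValueError("bias_beta must lie in [0, 1)")
        ratios = (
            self.true_ratio.values()
            if isinstance(self.true_ratio, Mapping)
            else [self.true_ratio]
        )
        if any(r < 0 for r in ratios):
            raise ValueError("true_ratio must be >= 0")

    def ratio_for(self, gene: str) -> float:
        if isinstance(self.true_ratio, Mapping):
            return float(self.true_ratio.get(gene, 1.0))
        return float(self.true_ratio)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def make_toy_genome(
    cfg: SimulationConfig,
) -> tuple[ReferenceGenome, list[VariantSite], list[GeneInterval]]:
    """Random toy chromosome with tiled gene intervals and a het-SNP catalog.

    Genes are laid end to end on a single chromosome, each spanning
    ``gene_span_bp``; every gene receives a number of SNPs drawn uniformly
    from ``snps_per_gene``, placed away from gene edges so simulated reads
    always fit.
    """
    rng = cfg.rng(stream=1)
    lo, hi = cfg.snps_per_gene
    margin = cfg.read_length + 1
    chrom = "chr1"
    length = cfg.n_genes * cfg.gene_span_bp + 2 * margin
    seq = "".join(rng.choice(list("ACGT"), size=length))
    genome = ReferenceGenome({chrom: seq}, provenance="standard")

    sites: list[VariantSite] = []
    intervals: list[GeneInterval] = []
    for g in range(cfg.n_genes):
        gene = f"GENE{g + 1:03d}"
        start = margin + g * cfg.gene_span_bp + 1  # 1-based
        end = start + cfg.gene_span_bp - 1
        intervals.append(GeneInterval(chrom, start, end, gene, "exonic"))
        n_snps = int(rng.integers(lo, hi + 1))
        # SNPs are spaced more than a read length apart so each simulated
        # read overlaps exactly one catalogued site (keeps planted counts
        # and pileup tallies identical); jitter stays below the slot gap.
        slot_gap = cfg.read_length + 10
        slots = np.arange(start + margin, end - margin, slot_gap)
        chosen = sorted(rng.choice(slots, size=n_snps, replace=False))
        positions = [int(p + rng.integers(0, 9)) for p in chosen]
        for k, pos in enumerate(positions):
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            sites.append(
                VariantSite(chrom, int(pos), ref, str(alt),
                            site_id=f"snp_{gene}_{k + 1}", gene=gene,
                            region_class="exonic")
            )
    return genome, sites, intervals


def simulate_counts(
    cfg: SimulationConfig,
    sites: Sequence[VariantSite] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial allele sampling with variant-read loss, per site and sample.

    Per site and sample: total informative reads ~ Poisson(depth) (or fixed),
    each read is reference with probability ``true_ratio/(1+true_ratio)``,
    then each variant read is deleted with probability ``bias_beta``.
    Returns (counts, truth); truth carries the pre-loss variant count and
    the closed-form expected observed ratio ``true_ratio/(1-bias_beta)``.
    """
    if sites is None:
        _, sites, _ = make_toy_genome(cfg)
    rng = cfg.rng(stream=2)
    count_rows, truth_rows = [], []
    for s in range(cfg.n_samples):
        sample = f"S{s + 1}"
        for site in sites:
            ratio = cfg.ratio_for(site.gene)
            p_ref = ratio / (1.0 + ratio)
            total = int(cfg.depth) if cfg.fixed_depth else int(rng.poisson(cfg.depth))
            ref_n = int(rng.binomial(total, p_ref)) if total else 0
            var_pre = total - ref_n
            var_n = int(rng.binomial(var_pre, 1.0 - cfg.bias_beta)) if var_pre else 0
            count_rows.append(
                dict(chrom=site.chrom, pos=site.pos, ref=site.ref_allele,
                     alt=site.alt_allele, site_id=site.site_id, gene=site.gene,
                     region_class=site.region_class, sample=sample,
                     ref_count=ref_n, var_count=var_n, other_count=0)
            )
            truth_rows.append(
                dict(chrom=site.chrom, pos=site.pos, site_id=site.site_id,
                     gene=site.gene, sample=sample, true_ratio=ratio,
                     var_count_pre_bias=var_pre,
                     expected_observed_ratio=ratio / (1.0 - cfg.bias_beta))
            )
    return pd.DataFrame(count_rows), pd.DataFrame(truth_rows)


def simulate_reads(
    cfg: SimulationConfig,
    genome: ReferenceGenome,
    sites: Sequence[VariantSite],
    out_sam: str | os.PathLike,
    mode: str = "standard",
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Emit placed reads (SAM) carrying planted alleles at each site.

    Each read covers exactly one catalogued site, with the site base set to
    the sampled allele and all other bases copied from the genome.  In
    ``standard`` mode variant-carrying reads are dropped with probability
    ``bias_beta``; in ``masked`` mode the loss probability is forced to 0.
    The random draws are identical in both modes for the same seed, so at
    every site masked-mode var_count >= standard-mode var_count.

    Returns the truth table of planted (post-drop) counts.
    """
    if mode not in ("standard", "masked"):
        raise ValueError(f"mode must be 'standard' or 'masked', got {mode!r}")
    rng = cfg.rng(stream=3)
    L = cfg.read_length
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()
        ],
    }
    truth_rows = []
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        read_no = 0
        for site in sites:
            chrom_len = genome.chrom_length(site.chrom)
            if L > chrom_len:
                raise ValueError(f"read length {L} exceeds chromosome {site.chrom}")
            ratio = cfg.ratio_for(site.gene)
            p_ref = ratio / (1.0 + ratio)
            total = int(cfg.depth) if cfg.fixed_depth else int(rng.poisson(cfg.depth))
            kept_ref = kept_var = 0
            for _ in range(total):
                # All draws happen in both modes so the stream is shared:
                # the mode decides only whether the drop is applied.
                is_ref = rng.random() < p_ref
                drop_draw = rng.random()
                start_lo = max(1, site.pos - L + 1)
                start_hi = min(site.pos, chrom_len - L + 1)
                start = int(rng.integers(start_lo, start_hi + 1))  # 1-based
                if not is_ref and mode == "standard" and drop_draw < cfg.bias_beta:
                    continue
                offset = site.pos - start
                seq = list(genome[site.chrom][start - 1 : start - 1 + L])
                seq[offset] = site.ref_allele if is_ref else site.alt_allele
                read_no += 1
                a = pysam.AlignedSegment()
                a.query_name = f"read{read_no}_{site.site_id}"
                a.query_sequence = "".join(seq)
                a.flag = 0
                a.reference_id = ref_ids[site.chrom]
                a.reference_start = start - 1  # SAM object API is 0-based
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                out.write(a)
                if is_ref:
                    kept_ref += 1
                else:
                    kept_var += 1
            truth_rows.append(
                dict(chrom=site.chrom, pos=site.pos, site_id=site.site_id,
                     gene=site.gene, sample=sample_id, mode=mode,
                     ref_count=kept_ref, var_count=kept_var)
            )
    return pd.DataFrame(truth_rows)


def simulate_editing_panel(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition editing panel with shared true fractions per site.

    Per site and sample, depth ~ Poisson(editing_depth) and the edited read
    count is Binomial(depth, true_fraction).  Because both condition groups
    share the true fractions, the cross-condition correlation of mean
    edited fractions tends to 1 as depth grows.  Returns (counts, truth);
    counts has one row per (condition, sample, site).
    """
    rng = cfg.rng(stream=4)
    n_a, n_b = cfg.editing_n_samples
    conditions = (("regions", n_a), ("dlpfc", n_b))
    rows, truth_rows = [], []
    for i, frac in enumerate(cfg.editing_fractions):
        chrom, pos = "chr1", 1000 + i * 500
        truth_rows.append(dict(chrom=chrom, pos=pos, site_index=i, true_fraction=frac))
        for condition, n in conditions:
            for s in range(n):
                total = int(rng.poisson(cfg.editing_depth))
                edited = int(rng.binomial(total, frac)) if total else 0
                rows.append(
                    dict(condition=condition, sample=f"{condition}_{s + 1}",
                         chrom=chrom, pos=pos, site_index=i,
                         edited_count=edited, total_count=total)
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
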