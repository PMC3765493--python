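"""End-to-end orchestration: mask → count → AEI call → editing survey.

Each stage writes its table under the output directory before the next
stage starts, so a failed run leaves every completed stage inspectable and
re-running a later stage never mutates earlier outputs.  The run log
echoes every configuration value so each threshold applied is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import io
from .counts import (
    AllelicCount,
    annotate_sites,
    exonic_only,
    filter_sites,
    merge_windows,
    pileup_counts,
    read_gene_intervals_bed,
    SiteObservation,
)
from .editing import (
    filter_editing_sites,
    reference_error_exclusion,
    summarize_site,
)
from .refmask import VariantSite, mask_reference
from .stats import combine_gene, fold_ratio

log = logging.getLogger(__name__)

_THRESHOLD_RANGES = {
    "min_per_allele": (0, 1000),
    "min_minor_fraction": (0.0, 0.5),
    "window_bp": (0, 100000),
    "aei_threshold": (1.0, 100.0),
    "stringent_threshold": (1.0, 100.0),
    "min_avg_depth": (0.0, 1e6),
    "ci_level": (0.5, 0.999),
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and bookkeeping for one pipeline run."""

    genome_fasta: str = ""
    sites: str = ""  # VCF or TSV catalog
    sam: str = ""
    genes_bed: str = ""
    sample_id: str = "S1"
    editing_counts: str = ""  # optional long-format editing count TSV
    out_dir: str = "aeikit_out"
    seed: int = 0
    min_per_allele: int = 3
    min_minor_fraction: float = 0.05
    window_bp: int = 100
    aei_threshold: float = 2.0
    stringency: str = "permissive"  # permissive | stringent2sd | sdthird
    stringent_threshold: float = 1.5
    min_support_regions: int = 5
    min_support_dlpfc: int = 8
    min_avg_depth: float = 10.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.stringency not in ("permissive", "stringent2sd", "sdthird"):
            raise ValueError(f"unknown stringency mode {self.stringency!r}")
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside documented range [{lo}, {hi}]")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Parse a key=value config file; unknown keys are rejected."""
        known = {f.name: f.type for f in dc_fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def aei_table(
    counts: Iterable[AllelicCount],
    window_bp: int = 100,
    aei_threshold: float = 2.0,
    stringent_threshold: float = 1.5,
) -> pd.DataFrame:
    """Fold, merge and combine filtered counts into per-gene AEI calls.

    Sites must already carry gene annotation; counts are grouped by
    (gene, sample), folded, merged within ``window_bp`` windows, and
    combined.  Returns one row per gene x sample with all summary fields
    and the three call flags.
    """
    groups: dict[tuple[str, str], list[AllelicCount]] = {}
    for c in counts:
        if not c.site.gene:
            continue
        groups.setdefault((c.site.gene, c.sample_id), []).append(c)
    rows = []
    for (gene, sample), cs in sorted(groups.items()):
        cs = sorted(cs, key=lambda c: (c.site.chrom, c.site.pos))
        obs = [
            SiteObservation(c.site.chrom, c.site.pos,
                            fold_ratio(c.ref_count, c.var_count).folded_ratio)
            for c in cs
        ]
        merged = merge_windows(obs, window_bp=window_bp)
        g = combine_gene(
            [m.folded_ratio for m in merged], gene=gene, sample_id=sample,
            permissive_threshold=aei_threshold,
            stringent_2sd_threshold=stringent_threshold,
            sdthird_threshold=aei_threshold,
        )
        rows.append(
            dict(gene=gene, sample=sample, n_sites=len(cs), n_obs=g.n_obs,
                 mean_folded=g.mean_folded, sd_folded=g.sd_folded,
                 mean_log10=g.mean_log10, het_q=g.het_q,
                 call_permissive=g.call_permissive,
                 call_stringent_2sd=g.call_stringent_2sd,
                 call_stringent_sdthird=g.call_stringent_sdthird)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "n_sites", "n_obs", "mean_folded", "sd_folded",
                 "mean_log10", "het_q", "call_permissive", "call_stringent_2sd",
                 "call_stringent_sdthird"],
    )


def editing_survey_table(
    editing_counts: pd.DataFrame,
    min_support: dict[str, int],
    min_avg_depth: float = 10.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Retention-filtered editing survey from a long-format count table.

    ``editing_counts`` columns: condition, sample, chrom, pos,
    edited_count, total_count.  Applies the support/depth filters and the
    reference-error exclusion; returns one row per (site, condition) with
    retention status.
    """
    summaries = []
    for (chrom, pos, condition), grp in editing_counts.groupby(
        ["chrom", "pos", "condition"], sort=True
    ):
        site = VariantSite(str(chrom), int(pos), "A", "G",
                           site_id=f"{chrom}:{pos}", region_class="exonic")
        counts = {
            str(r.sample): (int(r.edited_count), int(r.total_count))
            for r in grp.itertuples(index=False)
        }
        summaries.append(summarize_site(site, str(condition), counts))
    retained, excluded = filter_editing_sites(summaries, min_support, min_avg_depth)

    # Reference-error exclusion evaluated on the pooled per-sample fractions
    # of each retained site (both conditions together).
    fractions_by_site: dict[str, list[float]] = {}
    for s in retained:
        fractions_by_site.setdefault(s.site.site_id, []).extend(s.fractions.tolist())
    ref_error = {
        sid: reference_error_exclusion(fr, confidence=ci_level)
        for sid, fr in fractions_by_site.items()
        if len(fr) >= 2
    }

    rows = []
    for s in retained + excluded:
        reason = s.excluded_reason
        if reason == "none" and ref_error.get(s.site.site_id, False):
            reason = "reference_error"
        rows.append(
            dict(chrom=s.site.chrom, pos=s.site.pos, condition=s.condition,
                 n_samples_with_variant=s.n_samples_with_variant,
                 avg_depth=s.avg_depth, pct_edited=s.mean_fraction_pct,
                 sem_pct=s.sem_fraction_pct, excluded_reason=reason)
        )
    frame = pd.DataFrame(rows).sort_values(["chrom", "pos", "condition"])
    return frame.reset_index(drop=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage and write per-stage outputs plus a JSON
    summary.  Deterministic given the config (the pipeline itself draws no
    randomness; the seed is recorded for provenance of simulated inputs)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in dc_fields(cfg):
        log.info("config %s = %r", f.name, getattr(cfg, f.name))
    summary: dict = {"config": {f.name: getattr(cfg, f.name) for f in dc_fields(cfg)}}

    try:
        stage = "mask"
        if cfg.genome_fasta and cfg.sites:
            genome = io.read_fasta(cfg.genome_fasta)
            catalog = io.read_sites(cfg.sites)
            masked, skipped = mask_reference(genome, catalog)
            io.write_fasta(masked, out / "masked.fa")
            io.write_skipped_sites(skipped, out / "mask_skipped.tsv")
            summary["mask"] = {"n_sites": len(catalog), "n_skipped": len(skipped)}

        stage = "count"
        counts = []
        if cfg.sam and cfg.sites:
            catalog = io.read_sites(cfg.sites)
            if cfg.genes_bed:
                intervals = read_gene_intervals_bed(cfg.genes_bed)
                catalog = exonic_only(annotate_sites(catalog, intervals))
            counts = pileup_counts(cfg.sam, catalog, cfg.sample_id)
            io.counts_to_frame(counts).to_csv(out / "counts.tsv", sep="\t", index=False)
            summary["count"] = {"n_sites": len(counts)}

        stage = "filter"
        if counts:
            kept = filter_sites(counts, cfg.min_per_allele, cfg.min_minor_fraction)
            io.counts_to_frame(kept).to_csv(out / "counts_filtered.tsv", sep="\t", index=False)
            summary["filter"] = {"n_in": len(counts), "n_retained": len(kept)}
            counts = kept

        stage = "aei_call"
        if counts:
            table = aei_table(counts, cfg.window_bp, cfg.aei_threshold,
                              cfg.stringent_threshold)
            table.to_csv(out / "aei_calls.tsv", sep="\t", index=False)
            call_col = {
                "permissive": "call_permissive",
                "stringent2sd": "call_stringent_2sd",
                "sdthird": "call_stringent_sdthird",
            }[cfg.stringency]
            summary["aei_call"] = {
                "n_gene_sample": int(len(table)),
                "n_called": int(table[call_col].sum()) if len(table) else 0,
                "mode": cfg.stringency,
            }

        stage = "edit_survey"
        if cfg.editing_counts:
            editing = pd.read_csv(cfg.editing_counts, sep="\t")
            table = editing_survey_table(
                editing,
                {"regions": cfg.min_support_regions, "dlpfc": cfg.min_support_dlpfc},
                cfg.min_avg_depth, cfg.ci_level,
            )
            table.to_csv(out / "editing_survey.tsv", sep="\t", index=False)
            summary["edit_survey"] = {
                "n_rows": int(len(table)),
                "n_retained": int((table["excluded_reason"] == "none").sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
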