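"""Survey of A-to-I RNA editing at catalogued sites.

Editing appears in RNA-seq as an A→G mismatch against the genome at a
position with no underlying DNA variant.  For each catalogued site the
module computes per-sample edited fractions, applies the retention filters
(minimum number of supporting samples per condition group and minimum
average depth), excludes probable reference-sequence errors (sites whose
across-sample confidence interval reaches 100% variant), and compares the
extent and variability of editing between two condition groups, e.g. many
brain regions of one individual versus one region across many individuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .refmask import VariantSite

log = logging.getLogger(__name__)

#: Default retention rule: at least this many samples with variant reads in
#: each condition group, and average depth strictly above 10 reads.
DEFAULT_MIN_AVG_DEPTH = 10.0


def editing_fraction(edited_count: int, total_count: int) -> float:
    """Fraction of reads carrying the edited base at one site in one sample."""
    if total_count <= 0:
        raise ValueError("site uncovered in this sample (total_count == 0)")
    if not 0 <= edited_count <= total_count:
        raise ValueError(f"edited_count {edited_count} outside [0, {total_count}]")
    return edited_count / total_count


@dataclass(frozen=True)
class EditingSiteSummary:
    """Per-site editing summary across the samples of one condition group."""

    site: VariantSite
    condition: str
    per_sample: Mapping[str, tuple[int, int, float]]  # sample -> (edited, total, fraction)
    homology_flag: bool = False
    excluded_reason: str = "none"

    @property
    def n_samples_with_variant(self) -> int:
        return sum(1 for e, _t, _f in self.per_sample.values() if e > 0)

    @property
    def avg_depth(self) -> float:
        totals = [t for _e, t, _f in self.per_sample.values()]
        return float(np.mean(totals)) if totals else 0.0

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray([f for _e, _t, f in self.per_sample.values()], dtype=float)

    @property
    def mean_fraction_pct(self) -> float:
        return float(self.fractions.mean() * 100.0) if len(self.per_sample) else float("nan")

    @property
    def sem_fraction_pct(self) -> float:
        f = self.fractions
        if f.size < 2:
            return float("nan")
        return float(f.std(ddof=1) / math.sqrt(f.size) * 100.0)


def summarize_site(
    site: VariantSite,
    condition: str,
    counts: Mapping[str, tuple[int, int]],
    homology_flag: bool = False,
) -> EditingSiteSummary:
    """Build a summary from per-sample (edited, total) counts, dropping
    uncovered samples from the means."""
    per_sample = {
        sample: (e, t, editing_fraction(e, t))
        for sample, (e, t) in counts.items()
        if t > 0
    }
    return EditingSiteSummary(site, condition, per_sample, homology_flag=homology_flag)


def filter_editing_sites(
    summaries: Sequence[EditingSiteSummary],
    min_support: Mapping[str, int],
    min_avg_depth: float = DEFAULT_MIN_AVG_DEPTH,
) -> tuple[list[EditingSiteSummary], list[EditingSiteSummary]]:
    """Apply the retention rule across condition groups.

    ``summaries`` holds one entry per (site, condition); a site is retained
    only if in *every* condition it shows variant reads in at least
    ``min_support[condition]`` samples and its average depth is strictly
    greater than ``min_avg_depth``.  Sites carrying a homology flag
    (pseudogene / ambiguous mapping, supplied as input) are excluded.

    Returns (retained, excluded); excluded summaries carry
    ``excluded_reason`` in {low_support, low_depth, homology_flag}.
    Monotone: raising either threshold never adds sites.
    """
    by_site: dict[tuple[str, int], list[EditingSiteSummary]] = {}
    for s in summaries:
        by_site.setdefault((s.site.chrom, s.site.pos), []).append(s)

    retained: list[EditingSiteSummary] = []
    excluded: list[EditingSiteSummary] = []
    for _key, group in by_site.items():
        reason = "none"
        for s in group:
            need = min_support.get(s.condition, 0)
            if s.homology_flag:
                reason = "homology_flag"
                break
            if s.n_samples_with_variant < need:
                reason = "low_support"
                break
            if not s.avg_depth > min_avg_depth:
                reason = "low_depth"
                break
        for s in group:
            if reason == "none":
                retained.append(s)
            else:
                excluded.append(replace(s, excluded_reason=reason))
    return retained, excluded


def reference_error_exclusion(
    fractions: Sequence[float],
    confidence: float = 0.95,
    method: str = "t",
    counts: Sequence[tuple[int, int]] | None = None,
) -> bool:
    """Flag sites where the reference base itself is probably wrong.

    When every sample expresses (nearly) only the variant allele, the
    "editing" signal is better explained by an error in the reference
    sequence for this population.  A two-sided confidence interval for the
    mean variant fraction across samples is built; the site is excluded
    (returns True) when the interval's upper bound reaches 100%.

    ``method="t"`` (default) uses a t-interval on the per-sample fractions;
    ``method="binomial"`` pools the raw counts (supply ``counts``) and uses
    an exact Clopper-Pearson interval.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < 2:
        log.warning("reference_error_exclusion: single sample, not evaluable; retained")
        return False
    if method == "t":
        mean = f.mean()
        sem = f.std(ddof=1) / math.sqrt(f.size)
        tmult = sps.t.ppf(0.5 + confidence / 2.0, df=f.size - 1)
        upper = mean + tmult * sem
        return bool(upper >= 1.0)
    if method == "binomial":
        if counts is None:
            raise ValueError("binomial method requires raw (edited, total) counts")
        edited = sum(e for e, _t in counts)
        total = sum(t for _e, t in counts)
        lo, hi = sps.binomtest(edited, total).proportion_ci(confidence, method="exact")
        return bool(hi >= 1.0)
    raise ValueError(f"unknown CI method {method!r}")


def cross_condition_correlation(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, r²) of per-site mean editing between two
    condition groups over the same sites in the same order."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired sites in matching order")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one condition; correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def variability_comparison(
    per_site_sems_a: Sequence[float],
    per_site_sems_b: Sequence[float],
    paired: bool = True,
    method: str = "wilcoxon",
) -> tuple[float, float, pd.DataFrame]:
    """Compare editing variability between two condition groups.

    The per-site SEMs of the edited fraction are the variability measure.
    Default is a paired two-sided Wilcoxon signed-rank test (exact null for
    small site panels, robust to the heavy tails of SEMs at n ~ 12); an
    F-type variance-ratio test on the pooled SEMs is available with
    ``method="f"``.  Returns (statistic, p_value, per-site table).
    """
    a = np.asarray(per_site_sems_a, dtype=float)
    b = np.asarray(per_site_sems_b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length SEM lists")
    table = pd.DataFrame({"sem_a": a, "sem_b": b, "diff": a - b})
    if method == "wilcoxon":
        if np.all(a == b):
            return float("nan"), 1.0, table
        res = sps.wilcoxon(a, b, zero_method="wilcox", method="auto")
        return float(res.statistic), float(res.pvalue), table
    if method == "f":
        stat = float(np.var(a, ddof=1) / np.var(b, ddof=1))
        dfn, dfd = a.size - 1, b.size - 1
        p = 2.0 * min(sps.f.cdf(stat, dfn, dfd), sps.f.sf(stat, dfn, dfd))
        return stat, float(min(p, 1.0)), table
    raise ValueError(f"unknown method {method!r}")
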