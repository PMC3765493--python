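"""Allelic-ratio mathematics and AEI calling.

Haplotype phase is unknown, so a 2-fold and a 0.5-fold ratio at two SNPs of
the same gene carry the same information: both are folded onto the >=1
scale via ``10**abs(log10(ratio))`` before any within-gene combination.
Gene-level summaries (mean, SD, heterogeneity) then feed a permissive rule
(mean fold >= 2 with >= 2 observations) and two stringent variants used to
prioritise genes likely to harbour cis-acting regulatory variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class AllelicRatio:
    """Raw, log, folded and logit representations of one ref/var observation."""

    ref_count: int
    var_count: int
    raw_ratio: float
    log10_ratio: float
    folded_ratio: float
    logit_score: float


def fold_ratio(ref_count: int, var_count: int) -> AllelicRatio:
    """Fold a ref/var count pair onto the orientation-free >=1 scale.

    ``folded_ratio = 10**|log10(ref/var)|`` and
    ``logit_score = ln(max/min)``; both are symmetric under swapping the
    two counts and are 1 (respectively 0) exactly when the counts agree.
    """
    if ref_count <= 0 or var_count <= 0:
        raise ValueError(
            f"undefined allelic ratio for counts ({ref_count}, {var_count}): "
            "both alleles need at least one read (enforced upstream by filter_sites)"
        )
    raw = ref_count / var_count
    # fold via max/min so the result is bit-identical under swapping counts
    major_over_minor = max(ref_count, var_count) / min(ref_count, var_count)
    return AllelicRatio(
        ref_count=ref_count,
        var_count=var_count,
        raw_ratio=raw,
        log10_ratio=math.log10(raw),
        folded_ratio=10 ** math.log10(major_over_minor),
        logit_score=math.log(major_over_minor),
    )


def fold_raw(raw_ratio: float) -> float:
    """Fold an already-formed positive ratio onto the >=1 scale."""
    if raw_ratio <= 0:
        raise ValueError(f"ratio must be positive, got {raw_ratio}")
    return 10 ** abs(math.log10(raw_ratio))


@dataclass(frozen=True)
class GeneAEI:
    """Gene x sample combination of merged folded-ratio observations.

    ``het_q`` is an equal-weight heterogeneity statistic — the sum of
    squared deviations of the observation log10 ratios around their mean —
    a stand-in for an inverse-variance-weighted Cochran's Q (observation
    variances are unavailable after window merging).
    """

    gene: str
    sample_id: str
    n_obs: int
    mean_folded: float
    sd_folded: float | None  # None when n_obs == 1
    mean_log10: float
    het_q: float
    call_permissive: bool = False
    call_stringent_2sd: bool = False
    call_stringent_sdthird: bool = False


def combine_gene(
    folded_ratios: Sequence[float],
    gene: str = "",
    sample_id: str = "",
    permissive_threshold: float = 2.0,
    permissive_min_obs: int = 2,
    stringent_2sd_threshold: float = 1.5,
    sdthird_threshold: float = 2.0,
) -> GeneAEI:
    """Combine the merged folded ratios of one gene x sample.

    Mean and SD (n-1 denominator) are taken on the linear fold scale;
    heterogeneity on the log10 scale.  The three call flags are evaluated
    at the supplied thresholds.
    """
    if len(folded_ratios) == 0:
        raise ValueError("combine_gene requires at least one observation")
    if min(folded_ratios) < 1.0 - 1e-12:
        raise ValueError("folded ratios must be >= 1; fold raw ratios first")
    arr = np.asarray(folded_ratios, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else None
    logs = np.log10(arr)
    het_q = float(((logs - logs.mean()) ** 2).sum())
    g = GeneAEI(
        gene=gene,
        sample_id=sample_id,
        n_obs=n,
        mean_folded=mean,
        sd_folded=sd,
        mean_log10=float(logs.mean()),
        het_q=het_q,
    )
    return GeneAEI(
        **{
            **g.__dict__,
            "call_permissive": call_permissive(g, permissive_threshold, permissive_min_obs),
            "call_stringent_2sd": call_stringent_2sd(g, stringent_2sd_threshold),
            "call_stringent_sdthird": call_stringent_sdthird(g, sdthird_threshold),
        }
    )


def call_permissive(g: GeneAEI, threshold: float = 2.0, min_obs: int = 2) -> bool:
    """Permissive AEI call: mean folded ratio >= threshold with >= min_obs
    merged observations (single-SNP genes are never called)."""
    return g.n_obs >= min_obs and g.mean_folded >= threshold


def call_stringent_2sd(g: GeneAEI, threshold: float = 1.5) -> bool:
    """Stringent call: mean folded ratio minus two SDs still >= threshold.

    Genes with a single observation have no SD and are ineligible (False).
    """
    if g.n_obs < 2 or g.sd_folded is None:
        return False
    return g.mean_folded - 2.0 * g.sd_folded >= threshold


def call_stringent_sdthird(g: GeneAEI, threshold: float = 2.0) -> bool:
    """Stringent call: within-gene SD no more than one-third of the mean
    folded ratio, and mean folded ratio >= threshold."""
    if g.n_obs < 2 or g.sd_folded is None:
        return False
    return g.sd_folded <= g.mean_folded / 3.0 and g.mean_folded >= threshold


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of corrected versus standard log10 allelic ratios."""

    slope: float
    intercept: float
    r_squared: float
    aic: float
    n: int

    def predicted_fold(self, standard_fold: float) -> float:
        """Corrected fold ratio the fitted line predicts for a given
        standard-alignment fold ratio."""
        return 10 ** (self.intercept + self.slope * math.log10(standard_fold))


def compare_methods_regression(pairs: Sequence[tuple[float, float]]) -> ModelFit:
    """Regress corrected log10 folded ratios on standard-alignment ones.

    Quantifies how much a bias-attenuating alignment shrinks allelic
    ratios: a slope below 1 (with intercept near 0) means the corrected
    method reports systematically smaller fold differences.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: no variance in standard-alignment ratios")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ModelFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        aic=float(res.aic),
        n=len(pairs),
    )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit predicting a confirmed-AEI label."""

    params: pd.Series
    bse: pd.Series
    aic: float | None
    feature_names: list[str]
    separation: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(features[self.feature_names], has_constant="add")
        linpred = X.to_numpy() @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-linpred))


def logistic_aei_predictor(
    features: pd.DataFrame,
    labels: Sequence[bool] | np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> LogisticFit:
    """Fit a logistic model predicting whether an orthogonal assay confirms
    AEI (>= 1.5-fold) from RNA-seq summaries such as the logit score, the
    number of additional SNPs in the gene (as an interaction with the logit
    score), and within-gene heterogeneity.

    Supports model comparison across feature sets via AIC.  Perfect
    separation is flagged and AIC reported as unavailable.
    """
    y = np.asarray(labels, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 labelled records")
    if y.min() == y.max():
        raise ValueError("degenerate fit: all labels identical")
    names = list(feature_names) if feature_names is not None else list(features.columns)
    X = features[names]
    if X.isna().any().any():
        raise ValueError("missing feature values")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        import warnings

        with warnings.catch_warnings():
            # separation is detected below from the standard errors
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
    except Exception:  # PerfectSeparationError or convergence failure
        return LogisticFit(
            params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float),
            aic=None,
            feature_names=names,
            separation=True,
        )
    separated = bool(np.any(res.bse > 1e3)) or not res.mle_retvals.get("converged", True)
    return LogisticFit(
        params=pd.Series(res.params, index=Xc.columns),
        bse=pd.Series(res.bse, index=Xc.columns),
        aic=None if separated else float(res.aic),
        feature_names=names,
        separation=separated,
    )


def snapshot_normalize(cdna_ratio: float, gdna_ratio: float) -> float:
    """Normalise a cDNA peak-height ratio to its genomic-DNA counterpart.

    The gDNA ratio measures the same two alleles at a true 1:1 template
    ratio, so dividing by it cancels dye and incorporation biases; the
    result estimates the allelic mRNA ratio directly.
    """
    if cdna_ratio <= 0 or gdna_ratio <= 0:
        raise ValueError("peak-height ratios must be positive")
    return cdna_ratio / gdna_ratio


def concordance_counts(
    a_folded: Sequence[float],
    b_folded: Sequence[float],
    threshold: float = 1.5,
) -> tuple[int, int, int, int]:
    """Agreement of two fold-ratio series around a call threshold.

    Returns (both_above, a_above_total, both_below, a_below_total): of the
    observations where series A is >= threshold, how many of B agree; and
    likewise below threshold.
    """
    a = np.asarray(a_folded, dtype=float)
    b = np.asarray(b_folded, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be paired")
    above = a >= threshold
    both_above = int((b[above] >= threshold).sum())
    both_below = int((b[~above] < threshold).sum())
    return both_above, int(above.sum()), both_below, int((~above).sum())
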