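"""Expression preprocessing: filtering, normalization, variable-feature
selection and scaling.

The chain mirrors the standard single-cell toolkit conventions the method
builds on: quality filters on sparsely expressed isoforms/samples, a
restriction to isoforms of multi-isoform genes (single-isoform genes are
already handled by gene-level differential expression), per-sample
LogNormalize with natural log, mean-variance-plot (mvp) dispersion-based
feature selection, and per-feature z-scaling with clipping.  The output is
the samples-by-features matrix E consumed by the PCA step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, IsoformExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Bookkeeping of the filter chain and mvp selection."""

    n_transcripts_in: int = 0
    n_transcripts_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_multi_isoform_transcripts: int = 0
    n_variable_features: int = 0
    feature_means: pd.Series | None = field(default=None, repr=False)
    feature_dispersions: pd.Series | None = field(default=None, repr=False)
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {k: getattr(self, k) for k in
                ("n_transcripts_in", "n_transcripts_out", "n_samples_in",
                 "n_samples_out", "n_multi_isoform_transcripts",
                 "n_variable_features")}
        return pd.DataFrame({"count": rows})


def filter_matrix(expr: IsoformExpressionMatrix,
                  min_samples_per_isoform: int = 3,
                  min_isoforms_per_sample: int = 200,
                  ) -> IsoformExpressionMatrix:
    """Drop sparsely expressed isoforms, then sparsely expressing samples.

    "Expressed" means value > 0.  Isoforms positive in fewer than
    ``min_samples_per_isoform`` samples are removed first; samples
    expressing fewer than ``min_isoforms_per_sample`` of the remaining
    isoforms are removed second (single pass, in that order).
    """
    if min_samples_per_isoform < 0 or min_isoforms_per_sample < 0:
        raise ValueError("thresholds must be non-negative")
    pos = expr.values.to_numpy() > 0
    keep_iso = pos.sum(axis=1) >= min_samples_per_isoform
    keep_smp = pos[keep_iso].sum(axis=0) >= min_isoforms_per_sample
    if not keep_iso.any() or not keep_smp.any():
        raise ValueError("filtering produced an empty expression matrix")
    values = expr.values.loc[keep_iso, expr.values.columns[keep_smp]]
    return IsoformExpressionMatrix(values, expr.gene_ids.loc[values.index])


def restrict_to_multi_isoform_genes(expr: IsoformExpressionMatrix,
                                    annotation: GeneAnnotation | None = None,
                                    ) -> IsoformExpressionMatrix:
    """Keep only transcripts whose gene has >= 2 transcripts in the matrix.

    Multi-isoform status is defined relative to the supplied matrix (and its
    transcript-to-gene map), not to an external gene model.
    """
    counts = expr.gene_ids.value_counts()
    multi = expr.gene_ids.map(counts) >= 2
    if not multi.any():
        raise ValueError("no multi-isoform genes: empty expression matrix")
    return expr.subset_transcripts(expr.transcript_ids[multi])


def log_normalize(expr_values: pd.DataFrame,
                  scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Per-sample LogNormalize: y_ij = ln(1 + x_ij / sum_i(x_ij) * scale).

    Natural logarithm; strictly monotone within each sample.  A sample with
    zero total expression is a hard error.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    colsum = expr_values.sum(axis=0)
    if (colsum <= 0).any():
        bad = colsum.index[colsum <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total expression")
    return np.log1p(expr_values / colsum * scale_factor)


def select_variable_features_mvp(norm_values: pd.DataFrame,
                                 n_bins: int = 20,
                                 mean_cutoff_lo: float = 0.1,
                                 mean_cutoff_hi: float = 8.0,
                                 dispersion_cutoff: float = 1.0,
                                 report: PreprocessReport | None = None,
                                 ) -> list[str]:
    """Mean-variance-plot feature selection on log-normalized values.

    Per feature, the dispersion is the variance/mean ratio on the
    back-transformed (expm1) scale and the mean metric is log1p of the
    back-transformed mean (the mean.var.plot convention, which keeps the
    mean axis roughly uniform so binning genuinely controls for the
    mean-variability relationship).  Features are binned into ``n_bins``
    equal-width bins of the mean metric and the log-dispersion is z-scored
    within each bin.  Selected are features with scaled dispersion >=
    ``dispersion_cutoff`` and mean metric within [lo, hi], returned in
    input order.  Bins with < 2 usable features contribute no z-scores and
    their features are excluded with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    back = np.expm1(norm_values.to_numpy())
    raw_mean = back.mean(axis=1)
    var = back.var(axis=1, ddof=1) if back.shape[1] > 1 else np.zeros(len(raw_mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(raw_mean > 0, var / raw_mean, np.nan)
    mean = np.log1p(raw_mean)
    # guard against numerically-nonzero variance of constant features
    usable = np.isfinite(dispersion) & (dispersion > 1e-12)
    if report is not None:
        report.feature_means = pd.Series(mean, index=norm_values.index)
        report.feature_dispersions = pd.Series(dispersion, index=norm_values.index)
    if not usable.any():
        warnings.warn("all features constant: no variable features selected")
        return []
    log_disp = np.full(len(mean), np.nan)
    log_disp[usable] = np.log(dispersion[usable])

    lo, hi = mean[usable].min(), mean[usable].max()
    width = (hi - lo) / n_bins if hi > lo else 1.0
    bin_idx = np.clip(((mean - lo) / width).astype(int), 0, n_bins - 1)

    z = np.full(len(mean), np.nan)
    n_thin_bins = 0
    for b in range(n_bins):
        members = usable & (bin_idx == b)
        if members.sum() < 2:
            n_thin_bins += int(members.sum() > 0)
            continue
        vals = log_disp[members]
        sd = vals.std(ddof=1)
        if sd == 0:
            z[members] = 0.0
        else:
            z[members] = (vals - vals.mean()) / sd
    if n_thin_bins:
        warnings.warn(f"{n_thin_bins} mvp bin(s) had fewer than 2 features; "
                      "their features were excluded from selection")
    selected = np.isfinite(z) & (z >= dispersion_cutoff) \
        & (mean >= mean_cutoff_lo) & (mean <= mean_cutoff_hi)
    return list(norm_values.index[selected])


def scale_features(norm_values: pd.DataFrame, feature_subset,
                   clip_max: float = 10.0) -> pd.DataFrame:
    """Per-feature z-scaling (sample sd, ddof=1) with symmetric clipping.

    Features with zero standard deviation are dropped with a warning.
    Returns a features-by-samples matrix with per-feature mean 0 and sd 1
    before clipping to [-clip_max, clip_max].
    """
    sub = norm_values.loc[list(feature_subset)]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) "
                      "with zero standard deviation")
    sub = sub.loc[keep]
    scaled = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return scaled.clip(lower=-clip_max, upper=clip_max)


def preprocess(expr: IsoformExpressionMatrix,
               annotation: GeneAnnotation | None = None,
               min_samples_per_isoform: int = 3,
               min_isoforms_per_sample: int = 200,
               scale_factor: float = 10_000.0,
               n_bins: int = 20,
               mean_cutoff_lo: float = 0.1,
               mean_cutoff_hi: float = 8.0,
               dispersion_cutoff: float = 1.0,
               clip_max: float = 10.0,
               ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full chain: filter -> multi-isoform -> LogNormalize -> mvp -> scale.

    Returns the scaled features-by-samples matrix E' (transpose of the PCA
    input E) and a :class:`PreprocessReport`.
    """
    report = PreprocessReport(
        n_transcripts_in=expr.n_transcripts, n_samples_in=expr.n_samples,
        parameters=dict(min_samples_per_isoform=min_samples_per_isoform,
                        min_isoforms_per_sample=min_isoforms_per_sample,
                        scale_factor=scale_factor, n_bins=n_bins,
                        mean_cutoff_lo=mean_cutoff_lo,
                        mean_cutoff_hi=mean_cutoff_hi,
                        dispersion_cutoff=dispersion_cutoff,
                        clip_max=clip_max))
    filtered = filter_matrix(expr, min_samples_per_isoform,
                             min_isoforms_per_sample)
    multi = restrict_to_multi_isoform_genes(filtered, annotation)
    report.n_multi_isoform_transcripts = multi.n_transcripts
    norm = log_normalize(multi.values, scale_factor)
    features = select_variable_features_mvp(
        norm, n_bins, mean_cutoff_lo, mean_cutoff_hi, dispersion_cutoff,
        report=report)
    if not features:
        raise ValueError("mvp selected no variable features")
    scaled = scale_features(norm, features, clip_max)
    report.n_variable_features = len(scaled)
    report.n_transcripts_out = len(scaled)
    report.n_samples_out = scaled.shape[1]
    return scaled, report
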