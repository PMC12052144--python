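"""Chromatin-accessibility co-analysis.

Links mutation status and target isoform expression to the accessibility of
overlapping ATAC peaks (unequal-variance t-tests for the mutation side,
which typically has few samples; Kendall tau-b for the expression side),
combines per-peak p-values with the harmonic mean p-value overall, per
direction and per genomic region class, and compares the pairwise-peak HMP
distributions of called gene-target pairs against seeded random pairs with
a two-sample KS test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import harmonic_mean_p, kendall_tau
from .io_formats import GeneAnnotation, IsoformExpressionMatrix, PeakMatrix
from .scan import GeneMutationStatus

logger = logging.getLogger(__name__)


@dataclass
class PeakAssociationRecord:
    peak_id: str
    region_class: str
    test_kind: str          # "mutation_t" | "isoform_kendall"
    statistic: float
    p: float
    direction: int          # sign of the fold change / tau
    context: str = ""       # gene or transcript the peak was tested against


@dataclass
class PairHmpRecord:
    isomas_gene: str
    target: str
    n_peak_pairs: int
    hmp: float
    pool: str               # "isomas_pair" | "random_pair"


def map_peaks_to_loci(peak_matrix: PeakMatrix,
                      annotation: GeneAnnotation) -> pd.DataFrame:
    """Map peaks to transcripts by genomic interval intersection.

    Peaks are 0-based half-open; transcript spans (1-based inclusive
    start/end, falling back to a TSS point) are converted to half-open
    before the overlap test, so a touching boundary does not count.
    Returns one row per (peak_id, transcript_id, gene_id) overlap.
    """
    tr = annotation.transcripts
    start = tr["start"] if "start" in tr.columns else tr["tss"]
    end = tr["end"] if "end" in tr.columns else tr["tss"]
    loci = pd.DataFrame({
        "chrom": tr["chrom"],
        "lo": start.astype(int) - 1,   # half-open 0-based
        "hi": end.astype(int),
        "gene_id": tr["gene_id"],
    })
    rows = []
    for chrom, peaks in peak_matrix.peaks.groupby("chrom", sort=True):
        sub = loci[loci["chrom"] == chrom]
        if sub.empty:
            continue
        ps = peaks["start"].to_numpy()[:, None]
        pe = peaks["end"].to_numpy()[:, None]
        overlaps = (ps < sub["hi"].to_numpy()) & (sub["lo"].to_numpy() < pe)
        pi, ti = np.nonzero(overlaps)
        for a, b in zip(pi, ti):
            rows.append((peaks.index[a], sub.index[b], sub["gene_id"].iloc[b]))
    return pd.DataFrame(rows, columns=["peak_id", "transcript_id", "gene_id"])


def peaks_of_gene(mapping: pd.DataFrame, gene_id: str) -> list[str]:
    return sorted(mapping.loc[mapping["gene_id"] == gene_id, "peak_id"].unique())


def peaks_of_transcript(mapping: pd.DataFrame, transcript_id: str) -> list[str]:
    return sorted(mapping.loc[mapping["transcript_id"] == transcript_id,
                              "peak_id"].unique())


def _hmp_summary(records: list[PeakAssociationRecord]) -> dict[str, float]:
    """Pooled, per-direction and per-region-class HMPs for a record list."""
    out: dict[str, float] = {}
    ps = [r.p for r in records]
    if ps:
        out["Pooled"] = harmonic_mean_p(ps)
    for label, keep in (("Positive", lambda r: r.direction > 0),
                        ("Negative", lambda r: r.direction < 0)):
        sub = [r.p for r in records if keep(r)]
        if sub:
            out[label] = harmonic_mean_p(sub)
    for cls in sorted({r.region_class for r in records}):
        out[cls] = harmonic_mean_p([r.p for r in records
                                    if r.region_class == cls])
    return out


def mutation_accessibility_test(peak_matrix: PeakMatrix,
                                status: GeneMutationStatus,
                                peak_ids,
                                ) -> tuple[list[PeakAssociationRecord], dict]:
    """Per-peak Welch t-test of accessibility between mutant and wildtype.

    Both groups need >= 2 samples; underpowered peaks are skipped and
    counted in the summary.  Direction is the sign of the mutant-minus-
    wildtype mean difference.
    """
    records: list[PeakAssociationRecord] = []
    n_skipped = 0
    mut_mask = status.status
    for pid in peak_ids:
        x = peak_matrix.values.loc[pid].to_numpy(dtype=float)
        mut, wt = x[mut_mask], x[~mut_mask]
        if mut.size < 2 or wt.size < 2:
            n_skipped += 1
            continue
        t, p = stats.ttest_ind(mut, wt, equal_var=False)
        if np.isnan(p):
            p, t = 1.0, 0.0
        records.append(PeakAssociationRecord(
            peak_id=pid,
            region_class=str(peak_matrix.peaks.loc[pid, "region_class"]),
            test_kind="mutation_t", statistic=float(t),
            p=float(min(max(p, np.finfo(float).tiny), 1.0)),
            direction=int(np.sign(mut.mean() - wt.mean())),
            context=status.gene))
    summary = _hmp_summary(records)
    summary["n_skipped"] = n_skipped
    return records, summary


def isoform_accessibility_correlation(expr: IsoformExpressionMatrix,
                                      peak_matrix: PeakMatrix,
                                      transcript_id: str, peak_ids,
                                      ) -> tuple[list[PeakAssociationRecord], dict]:
    """Kendall tau-b between a transcript's expression and each peak.

    Computed on the shared samples (>= 3 required); constant vectors make
    tau undefined and the peak is skipped.
    """
    shared = [s for s in expr.sample_ids if s in set(peak_matrix.values.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    e = expr.values.loc[transcript_id, shared].to_numpy(dtype=float)
    records: list[PeakAssociationRecord] = []
    n_skipped = 0
    for pid in peak_ids:
        a = peak_matrix.values.loc[pid, shared].to_numpy(dtype=float)
        tau, p = kendall_tau(e, a)
        if not np.isfinite(p):
            n_skipped += 1
            continue
        records.append(PeakAssociationRecord(
            peak_id=pid,
            region_class=str(peak_matrix.peaks.loc[pid, "region_class"]),
            test_kind="isoform_kendall", statistic=tau,
            p=float(max(p, np.finfo(float).tiny)),
            direction=int(np.sign(tau)), context=transcript_id))
    summary = _hmp_summary(records)
    summary["n_skipped"] = n_skipped
    return records, summary


def pairwise_peak_hmp(peaks_of_mutant_gene, peaks_of_target,
                      peak_matrix: PeakMatrix, isomas_gene: str = "",
                      target: str = "", pool: str = "isomas_pair",
                      ) -> PairHmpRecord:
    """HMP over Kendall p-values of all peak pairs between two loci.

    Every (peak_i, peak_j) combination across the two peak sets is
    correlated; when the two loci share peaks (gene == target), self-pairs
    are excluded.  An empty side yields an undefined (NaN) HMP, flagged by
    n_peak_pairs = 0.
    """
    a_ids, b_ids = list(peaks_of_mutant_gene), list(peaks_of_target)
    if not a_ids or not b_ids:
        logger.warning("empty peak set for pair (%s, %s)", isomas_gene, target)
        return PairHmpRecord(isomas_gene, target, 0, float("nan"), pool)
    ps = []
    for pa in a_ids:
        xa = peak_matrix.values.loc[pa].to_numpy(dtype=float)
        for pb in b_ids:
            if pa == pb:
                continue  # self-pair rule
            xb = peak_matrix.values.loc[pb].to_numpy(dtype=float)
            _, p = kendall_tau(xa, xb)
            if np.isfinite(p):
                ps.append(max(p, np.finfo(float).tiny))
    if not ps:
        return PairHmpRecord(isomas_gene, target, 0, float("nan"), pool)
    return PairHmpRecord(isomas_gene, target, len(ps),
                         harmonic_mean_p(ps), pool)


def draw_random_pairs(candidate_genes, candidate_targets, exclude_pairs,
                      n_pairs: int, seed: int) -> list[tuple[str, str]]:
    """Seeded uniform sampling of non-called (gene, target) pairs.

    Samples without replacement from the product of candidate genes and
    targets, excluding every called pair, matched in count to the called
    pool by default.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(candidate_genes)
    targets = sorted(candidate_targets)
    excluded = set(exclude_pairs)
    total = len(genes) * len(targets)
    if total == 0:
        return []
    picked: list[tuple[str, str]] = []
    seen: set[int] = set()
    # rejection sampling is fine: the excluded set is tiny vs the product
    while len(picked) < n_pairs and len(seen) < total:
        idx = int(rng.integers(total))
        if idx in seen:
            continue
        seen.add(idx)
        pair = (genes[idx // len(targets)], targets[idx % len(targets)])
        if pair in excluded:
            continue
        picked.append(pair)
    return picked


def compare_pair_pools(isomas_hmps, random_hmps,
                       min_pool: int = 10) -> tuple[float, float] | None:
    """Two-sample KS test on log10(HMP) of the called vs random pair pools.

    Returns (D, p), or None with a warning when either pool is smaller than
    ``min_pool``.
    """
    a = np.log10(np.asarray([h for h in isomas_hmps if np.isfinite(h)]))
    b = np.log10(np.asarray([h for h in random_hmps if np.isfinite(h)]))
    if a.size < min_pool or b.size < min_pool:
        logger.warning("pair pool too small for KS comparison (%d vs %d)",
                       a.size, b.size)
        return None
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
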