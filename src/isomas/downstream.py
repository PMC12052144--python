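"""Characterization of called associations.

Dual-direction (isoform switch) detection with harmonic-mean-p aggregation,
cis/trans hypergeometric tests on the +/-1 Mb TSS window, chromosome
preference via a KS test on 24-bin frequency vectors, inter-cancer overlap
coefficients, and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import harmonic_mean_p, hypergeom_upper_tail, ks_binned_frequencies
from .io_formats import CHROMOSOMES, GeneAnnotation, IsoformExpressionMatrix
from .scan import GeneMutationStatus, direct_isoform_test_all

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000  # cis-region: +/- 1 Mb of the TSS
TRANS_CONSISTENT_P = 0.999  # upper-tail p above this flags trans-consistency


@dataclass
class DualDirectionRecord:
    """One iSoMAs-gene / target-gene dual-direction assessment."""

    isomas_gene: str
    target_gene: str
    up_isoforms: list = field(default_factory=list)    # (transcript, p, log2fc)
    down_isoforms: list = field(default_factory=list)
    is_dual: bool = False
    hmp: float = float("nan")


def detect_dual_direction(expr: IsoformExpressionMatrix,
                          status: GeneMutationStatus,
                          target_transcripts,
                          alpha: float = 0.05,
                          epsilon: float = 1.0,
                          ) -> tuple[list[DualDirectionRecord], dict]:
    """Detect dual-direction associations among one gene's targets.

    For every gene represented in the top-k target transcript list, all of
    that gene's isoforms in the expression matrix are tested directly
    (Wilcoxon on FPKM + pseudocounted log2FC).  A target gene is dual when
    the mutation is significantly (p < alpha) positively associated with at
    least one isoform and negatively with at least one other.  The HMP is
    computed over the significant isoforms only; the per-iSoMAs-gene mHMP
    is the plain mean of the dual genes' HMPs, reported as -log10(mHMP).
    """
    target_genes = pd.unique(expr.gene_ids.loc[
        expr.gene_ids.index.intersection(pd.Index(target_transcripts))])
    records: list[DualDirectionRecord] = []
    member_of = expr.gene_ids[expr.gene_ids.isin(set(target_genes))]
    if len(member_of) == 0:
        return records, {"n_dual_genes": 0, "mHMP": float("nan"),
                         "neg_log10_mHMP": float("nan")}
    tests = direct_isoform_test_all(expr, status, member_of.index, epsilon)
    for gene in target_genes:
        isos = member_of.index[member_of == gene]
        sub = tests.loc[isos]
        sig = sub[sub["p"] < alpha]
        up = sig[sig["log2fc"] > 0]
        down = sig[sig["log2fc"] < 0]
        rec = DualDirectionRecord(
            isomas_gene=status.gene, target_gene=str(gene),
            up_isoforms=[(t, float(r["p"]), float(r["log2fc"]))
                         for t, r in up.iterrows()],
            down_isoforms=[(t, float(r["p"]), float(r["log2fc"]))
                           for t, r in down.iterrows()],
            is_dual=bool(len(up) >= 1 and len(down) >= 1),
        )
        if len(sig):
            rec.hmp = harmonic_mean_p(sig["p"].to_numpy())
        records.append(rec)
    dual_hmps = [r.hmp for r in records if r.is_dual and np.isfinite(r.hmp)]
    mhmp = float(np.mean(dual_hmps)) if dual_hmps else float("nan")
    aggregate = {
        "n_dual_genes": int(sum(r.is_dual for r in records)),
        "mHMP": mhmp,
        "neg_log10_mHMP": float(-np.log10(mhmp)) if np.isfinite(mhmp) else float("nan"),
    }
    return records, aggregate


@dataclass
class CisEnrichmentResult:
    gene: str
    k: int   # targets in the cis window
    m: int   # universe isoforms in the cis window
    q: int   # annotated targets
    N: int   # annotated universe size
    p: float
    trans_consistent: bool


def cis_enrichment_test(isomas_gene: str, target_transcripts,
                        annotation: GeneAnnotation,
                        universe_transcripts,
                        window_bp: int = CIS_WINDOW_BP,
                        ) -> CisEnrichmentResult | None:
    """Upper-tail hypergeometric test for cis concentration of targets.

    The universe is the annotated subset of the PCA input isoforms; m counts
    universe isoforms whose TSS lies within +/- window_bp of the iSoMAs
    gene's TSS on the same chromosome, q the annotated targets, k the
    targets inside the window.  p > 0.999 flags consistency with the
    opposite (trans) null at the 0.001 level.  Returns None (with a
    warning) when the iSoMAs gene has no annotated TSS.
    """
    if isomas_gene not in annotation.genes.index:
        logger.warning("iSoMAs gene %r is unannotated; cis test skipped",
                       isomas_gene)
        return None
    gchrom = annotation.genes.loc[isomas_gene, "chrom"]
    gtss = int(annotation.genes.loc[isomas_gene, "tss"])
    universe = annotation.annotated(universe_transcripts)
    if universe.empty:
        logger.warning("no annotated universe isoforms; cis test skipped")
        return None
    ann = annotation.transcripts.loc[universe]
    in_cis = (ann["chrom"] == gchrom) & (np.abs(ann["tss"] - gtss) <= window_bp)
    targets = annotation.annotated(target_transcripts).intersection(universe)
    k = int(in_cis.loc[targets].sum())
    m = int(in_cis.sum())
    q = len(targets)
    N = len(universe)
    p = hypergeom_upper_tail(k, N, m, q)
    return CisEnrichmentResult(isomas_gene, k, m, q, N, p,
                               trans_consistent=p > TRANS_CONSISTENT_P)


def chromosome_preference_test(target_transcripts, annotation: GeneAnnotation,
                               universe_transcripts, method: str = "ks",
                               n_permutations: int = 1000,
                               seed: int | None = 0) -> tuple[float, float, int]:
    """Compare target vs universe chromosome frequency profiles.

    Both transcript sets are binned into the ordered 24-chromosome axis
    (1..22, X, Y) as relative-frequency vectors and summarized by the
    maximum CDF gap D.  ``method='ks'`` converts D to a p-value with the
    asymptotic two-sample KS distribution (effective sizes = annotated
    counts) — treating the discrete chromosome axis as continuous, exactly
    as practitioners apply the test to such frequency vectors.
    ``method='permutation'`` instead draws size-matched target sets from
    the universe (seeded) and reports the fraction with D at least as
    large, which respects the discreteness.  Also returns the number of
    distinct chromosomes the targets span.
    """
    targets = annotation.annotated(target_transcripts)
    if targets.empty:
        raise ValueError("no annotated target transcripts")
    universe = annotation.annotated(universe_transcripts)
    order = pd.CategoricalDtype(CHROMOSOMES, ordered=True)
    t_chrom = annotation.transcripts.loc[targets, "chrom"].astype(order)
    u_chrom = annotation.transcripts.loc[universe, "chrom"].astype(order)
    t_counts = t_chrom.value_counts(sort=False).to_numpy()
    u_counts = u_chrom.value_counts(sort=False).to_numpy()
    span = int((t_counts > 0).sum())
    d, p = ks_binned_frequencies(t_counts, u_counts, len(targets), len(universe))
    if method == "ks":
        return d, p, span
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    codes = u_chrom.cat.codes.to_numpy()
    u_cdf = np.cumsum(u_counts) / u_counts.sum()
    hits = 0
    for _ in range(n_permutations):
        draw = rng.choice(codes, size=len(targets), replace=False)
        counts = np.bincount(draw, minlength=len(CHROMOSOMES))
        d_perm = np.max(np.abs(np.cumsum(counts) / len(targets) - u_cdf))
        hits += d_perm >= d - 1e-12
    return d, (hits + 1) / (n_permutations + 1), span


def overlap_coefficient(set_a, set_b) -> float:
    """Szymkiewicz-Simpson coefficient |A & B| / min(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def target_overlap_between_cancers(targets_a: dict[str, list],
                                   targets_b: dict[str, list],
                                   top_k: int = 100) -> float | None:
    """Mean per-shared-gene target overlap between two cohorts' results.

    Step 1: intersect the two cohorts' called gene sets; step 2: per shared
    gene count overlapping top-k targets (transcript identity); step 3:
    average over the shared genes.  Returns None when no genes are shared.
    """
    if not targets_a or not targets_b:
        raise ValueError("both result sets must be nonempty")
    shared = set(targets_a) & set(targets_b)
    if not shared:
        return None
    overlaps = [len(set(targets_a[g][:top_k]) & set(targets_b[g][:top_k]))
                for g in sorted(shared)]
    return float(np.mean(overlaps))


@dataclass
class EnrichmentResult:
    set_name: str
    N: int
    m: int
    q: int
    k: int
    p: float
    n_dropped: int = 0  # query genes outside the background


def hypergeometric_enrichment(query_genes, gene_set, background,
                              set_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a query against one gene set.

    The gene set must lie inside the background (trim before calling);
    query genes outside the background are dropped with a count.  An empty
    (post-trim) query returns p = 1 by convention.
    """
    bg = set(background)
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene set must be a subset of the background")
    query = set(query_genes)
    n_dropped = len(query - bg)
    query &= bg
    N, m, q = len(bg), len(gs), len(query)
    if q == 0:
        logger.warning("empty query after background trimming for %r", set_name)
        return EnrichmentResult(set_name, N, m, 0, 0, 1.0, n_dropped)
    k = len(query & gs)
    return EnrichmentResult(set_name, N, m, q, k,
                            hypergeom_upper_tail(k, N, m, q), n_dropped)
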