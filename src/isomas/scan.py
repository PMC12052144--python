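"""The core association scan.

For every qualifying somatically mutated gene, samples are split into
wildtype and mutant groups by SNV status and a two-sided Wilcoxon rank-sum
test compares the PC scores of the two groups along each of the K PC
coordinates.  A gene is called when it passes a two-layer significance
test: (1) the minimum Bonferroni-corrected p-value across the K PCs falls
below alpha_pc (with K=50 and alpha_pc=0.05 the raw threshold is exactly
0.001), and (2) the Bonferroni-corrected minimum survives a BH correction
at FDR < alpha_fdr across all tested genes.  The first significant PC then
ranks the input isoforms by loading magnitude into the gene's target list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, wilcoxon_rank_sum, wilcoxon_rank_sum_matrix
from .io_formats import IsoformExpressionMatrix, MutationTable
from .pca import PcaModel


@dataclass
class GeneMutationStatus:
    """Binary mutant indicator for one gene over the analysis samples."""

    gene: str
    status: np.ndarray  # boolean, True = mutant

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=bool)
        if self.n_mutant < 1:
            raise ValueError(f"gene {self.gene!r} has no mutant samples")

    @property
    def n_mutant(self) -> int:
        return int(self.status.sum())

    @property
    def n_wildtype(self) -> int:
        return int((~self.status).sum())


def qualifying_genes(mutations: MutationTable, samples,
                     min_mutant_fraction: float = 0.02,
                     variant_filter=None) -> list[str]:
    """Genes whose SNV mutant-sample fraction is >= the threshold (inclusive).

    Only SNV (variant_type == SNP) records count; duplicate (gene, sample)
    records count the sample once.  The fraction is computed on the supplied
    (already intersected) sample set.
    """
    samples = list(samples)
    if not samples:
        return []
    rec = mutations.snv_records(variant_filter)
    rec = rec[rec["sample"].isin(set(samples))]
    counts = rec.drop_duplicates(["gene", "sample"]).groupby("gene").size()
    frac = counts / len(samples)
    return sorted(frac.index[frac >= min_mutant_fraction])


def differential_pc_score_test(model: PcaModel,
                               status: GeneMutationStatus) -> np.ndarray:
    """Length-K vector of two-sided Wilcoxon p-values, one per PC."""
    if status.status.size != len(model.sample_ids):
        raise ValueError("status vector length does not match model samples")
    if status.n_mutant == 0 or status.n_wildtype == 0:
        raise ValueError("both mutant and wildtype groups must be nonempty")
    S = model.scores.to_numpy()
    return wilcoxon_rank_sum_matrix(S[status.status], S[~status.status])


def call_isomas_genes(pvalues_by_gene: dict[str, np.ndarray], K: int,
                      alpha_pc: float = 0.05, alpha_fdr: float = 0.05,
                      status_counts: dict[str, tuple[int, int]] | None = None,
                      ) -> pd.DataFrame:
    """Apply the two-layer significance test across all tested genes.

    Layer 1 (per gene): pass iff K * P_min < alpha_pc (Bonferroni over PCs).
    Layer 2 (across genes): BH on the Bonferroni-adjusted minima of all
    tested genes; a gene is called iff it passes both layers.  The selected
    PC is the smallest PC index with K * p_pc < alpha_pc.

    Returns a DataFrame indexed by gene with P_min, P_min_bonf, q,
    selected_pc (1-based, <NA> when not called), is_isomas, group sizes and
    the per-PC raw p-values.
    """
    genes = list(pvalues_by_gene)
    if not genes:
        return pd.DataFrame(columns=["P_min", "P_min_bonf", "q", "selected_pc",
                                     "is_isomas", "n_mutant", "n_wildtype"])
    pmat = np.vstack([np.asarray(pvalues_by_gene[g], dtype=float) for g in genes])
    if pmat.shape[1] != K:
        raise ValueError(f"p-value vectors have length {pmat.shape[1]}, expected K={K}")
    p_min = pmat.min(axis=1)
    p_bonf = np.minimum(1.0, K * p_min)
    layer1 = p_bonf < alpha_pc
    q = benjamini_hochberg(p_bonf)
    called = layer1 & (q < alpha_fdr)

    selected = np.full(len(genes), -1)
    sig = K * pmat < alpha_pc
    for i in np.flatnonzero(called):
        selected[i] = int(np.argmax(sig[i]))  # first significant PC (0-based)
    out = pd.DataFrame({
        "P_min": p_min,
        "P_min_bonf": p_bonf,
        "q": q,
        "selected_pc": pd.array([s + 1 if s >= 0 else pd.NA for s in selected],
                                dtype="Int64"),
        "is_isomas": called,
    }, index=pd.Index(genes, name="gene"))
    if status_counts is not None:
        out["n_mutant"] = [status_counts[g][0] for g in genes]
        out["n_wildtype"] = [status_counts[g][1] for g in genes]
    for k in range(K):
        out[f"p_PC_{k+1}"] = pmat[:, k]
    return out


def rank_targets(model: PcaModel, selected_pc: int, top_k: int = 100,
                 rank_mode: str = "abs") -> pd.DataFrame:
    """Rank input isoforms on the selected PC into the target list.

    ``selected_pc`` is 1-based.  ``rank_mode='abs'`` sorts by |loading|
    descending (ties broken by feature index), retaining the signed loading
    so positive/negative target subsets are recoverable.
    ``rank_mode='signed-top-bottom'`` takes the top ceil(k/2) most positive
    and bottom floor(k/2) most negative loadings instead.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not (1 <= selected_pc <= model.K):
        raise ValueError(f"selected_pc {selected_pc} out of range 1..{model.K}")
    col = model.loadings.iloc[:, selected_pc - 1]
    p = len(col)
    if top_k > p:
        warnings.warn(f"top_k={top_k} exceeds {p} features; returning all")
        top_k = p
    if np.all(col.to_numpy() == 0):
        warnings.warn("all-zero loading column: ranking is input order")
    if rank_mode == "abs":
        order = np.lexsort((np.arange(p), -np.abs(col.to_numpy())))[:top_k]
    elif rank_mode == "signed-top-bottom":
        vals = col.to_numpy()
        n_pos = int(np.ceil(top_k / 2))
        n_neg = top_k - n_pos
        pos = np.lexsort((np.arange(p), -vals))[:n_pos]
        neg = np.lexsort((np.arange(p), vals))[:n_neg]
        order = np.concatenate([pos, neg[::-1]])
    else:
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    out = pd.DataFrame({
        "transcript_id": col.index[order],
        "loading": col.to_numpy()[order],
    })
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["direction"] = np.sign(out["loading"]).astype(int)
    return out


def direct_isoform_test(expr: IsoformExpressionMatrix,
                        status: GeneMutationStatus, transcript_id: str,
                        epsilon: float = 1.0) -> tuple[float, float]:
    """Direct per-isoform test: Wilcoxon p on FPKM plus a pseudocounted
    log2 fold change log2((mean_mut + eps) / (mean_wt + eps))."""
    if transcript_id not in expr.transcript_ids:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    x = expr.values.loc[transcript_id].to_numpy(dtype=float)
    mut, wt = x[status.status], x[~status.status]
    if mut.size == 0 or wt.size == 0:
        raise ValueError("both groups must be nonempty")
    p = wilcoxon_rank_sum(mut, wt)
    log2fc = float(np.log2((mut.mean() + epsilon) / (wt.mean() + epsilon)))
    return p, log2fc


def direct_isoform_test_all(expr: IsoformExpressionMatrix,
                            status: GeneMutationStatus,
                            transcript_ids=None,
                            epsilon: float = 1.0) -> pd.DataFrame:
    """Vectorized direct test over many transcripts (p, log2fc per row)."""
    ids = expr.transcript_ids if transcript_ids is None else pd.Index(transcript_ids)
    X = expr.values.loc[ids].to_numpy(dtype=float).T  # samples x transcripts
    mut, wt = X[status.status], X[~status.status]
    p = wilcoxon_rank_sum_matrix(mut, wt)
    log2fc = np.log2((mut.mean(axis=0) + epsilon) / (wt.mean(axis=0) + epsilon))
    return pd.DataFrame({"p": p, "log2fc": log2fc}, index=ids)


@dataclass
class ScanResult:
    """Bundle of one cohort's scan outputs."""

    genes: pd.DataFrame                      # call table from call_isomas_genes
    targets: dict[str, pd.DataFrame]         # per called gene, ranked targets
    model: PcaModel
    statuses: dict[str, GeneMutationStatus]

    @property
    def isomas_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_isomas"]])

    def targets_table(self, gene_ids: pd.Series | None = None) -> pd.DataFrame:
        """Long-format target table across all called genes."""
        frames = []
        for gene, tgt in self.targets.items():
            t = tgt.copy()
            t.insert(0, "gene", gene)
            if gene_ids is not None:
                t["target_gene"] = t["transcript_id"].map(gene_ids).to_numpy()
            frames.append(t)
        if not frames:
            return pd.DataFrame(columns=["gene", "rank", "transcript_id",
                                         "loading", "direction"])
        return pd.concat(frames, ignore_index=True)


def scan(model: PcaModel, mutations: MutationTable,
         min_mutant_fraction: float = 0.02, alpha_pc: float = 0.05,
         alpha_fdr: float = 0.05, top_k: int = 100, rank_mode: str = "abs",
         variant_filter=None) -> ScanResult:
    """Run the full association scan against a fitted PCA model.

    Tests every qualifying gene (SNV mutant fraction >= threshold on the
    model's samples) along all K PCs, applies the two-layer correction, and
    ranks target isoforms for each called gene on its first significant PC.
    The scan performs exactly G x K rank-sum tests — its cost is independent
    of the original isoform dimensionality.
    """
    samples = list(model.sample_ids)
    genes = qualifying_genes(mutations, samples, min_mutant_fraction,
                             variant_filter)
    pvals: dict[str, np.ndarray] = {}
    statuses: dict[str, GeneMutationStatus] = {}
    counts: dict[str, tuple[int, int]] = {}
    for gene in genes:
        st = GeneMutationStatus(
            gene, mutations.mutant_status(gene, samples,
                                          variant_filter=variant_filter))
        if st.n_wildtype == 0:
            continue  # cannot form two groups
        statuses[gene] = st
        counts[gene] = (st.n_mutant, st.n_wildtype)
        pvals[gene] = differential_pc_score_test(model, st)
    table = call_isomas_genes(pvals, model.K, alpha_pc, alpha_fdr, counts)
    targets = {
        gene: rank_targets(model, int(table.loc[gene, "selected_pc"]),
                           top_k, rank_mode)
        for gene in table.index[table["is_isomas"]]
    }
    return ScanResult(table, targets, model, statuses)
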