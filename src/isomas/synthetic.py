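"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the scan assumes in real tumor cohorts:
multi-isoform genes with log-normal FPKM baselines and per-sample library
size factors, sparse binary gene-level somatic mutation status, planted
mutation-to-target-isoform-set expression shifts (including dual-direction
isoform switches and cis-clustered target placement), optional correlated
chromatin-accessibility peaks, and a genome annotation over the 24 nuclear
chromosomes.  Every cohort carries a :class:`SyntheticTruth` for
parameter-recovery evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (GeneAnnotation, IsoformExpressionMatrix,
                         MutationTable, PeakMatrix, REGION_CLASSES)

# approximate chromosome lengths (bp), hg-like scale
_CHROM_LENGTHS = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000, "X": 155_000_000, "Y": 59_000_000,
}


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    Defaults describe a mid-sized tumor cohort: 300 samples, 800 genes with
    a 1-5 isoform distribution peaking at 2-3 (matching the genome-wide
    ratio of ~2.5 transcripts per gene), log-normal FPKM baselines around
    e^2 ~ 7 FPKM with per-isoform natural-log sd of 0.18-0.42 (moderate
    within-cohort biological variability; high-variability isoforms arise
    from the planted subgroup structure, not from the baseline), rare exact
    zeros (bulk data), two drivers mutated in 10% of samples with 50 target
    isoforms shifted by 1.5 log2 units, and a background of passenger genes
    mutated at 5-15% prevalence.
    """

    n_samples: int = 300
    n_genes: int = 800
    isoform_count_probs: tuple = (0.20, 0.30, 0.25, 0.15, 0.10)  # 1..5 isoforms
    baseline_log_mean: float = 2.0   # natural-log FPKM mean
    baseline_log_sd: float = 0.3     # per-isoform log-sd scale
    library_size_sd: float = 0.2     # log-normal per-sample factor
    dropout: float = 0.02
    n_drivers: int = 2
    mutation_prevalence: float = 0.10
    targets_per_driver: int = 50
    effect_size: float = 1.5         # log2 fold on mutant samples
    dual_fraction: float = 0.3       # fraction of target genes planted dual
    n_cis_drivers: int = 0
    cis_window: int = 1_000_000
    n_passenger_genes: int = 200
    passenger_prevalence: tuple = (0.05, 0.15)
    simulate_peaks: bool = False
    peaks_per_gene: tuple = (1, 3)
    accessibility_coupling: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for p in (self.dropout, self.mutation_prevalence, self.dual_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one cohort."""

    drivers: list
    mutant_samples: dict                     # driver -> list of sample ids
    targets: dict                            # driver -> DataFrame(transcript, gene, sign)
    dual_genes: dict = field(default_factory=dict)  # driver -> list of genes
    cis_drivers: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.drivers:
            for _, r in self.targets[d].iterrows():
                rows.append((d, r["transcript_id"], r["gene_id"], r["sign"],
                             r["gene_id"] in set(self.dual_genes.get(d, [])),
                             d in self.cis_drivers))
        return pd.DataFrame(rows, columns=["driver", "transcript_id",
                                           "gene_id", "sign", "is_dual_gene",
                                           "is_cis_driver"])


def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[IsoformExpressionMatrix, MutationTable,
                               GeneAnnotation, SyntheticTruth]:
    """Generate one cohort: expression, mutations, annotation, truth.

    Identical configs (same seed) produce identical outputs.  With
    effect_size = 0 the mutant and wildtype target distributions coincide
    (a null cohort).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    iso_counts = rng.choice(np.arange(1, len(cfg.isoform_count_probs) + 1),
                            size=cfg.n_genes, p=cfg.isoform_count_probs)
    transcripts, tr_gene = [], []
    for g, c in zip(genes, iso_counts):
        for j in range(c):
            transcripts.append(f"{g}.{j + 1}")
            tr_gene.append(g)
    n_tr = len(transcripts)

    # --- annotation: genes placed uniformly over length-weighted chromosomes
    chroms = list(_CHROM_LENGTHS)
    weights = np.array([_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    gene_chrom = rng.choice(chroms, size=cfg.n_genes, p=weights / weights.sum())
    gene_tss = np.array([rng.integers(1_000_000, _CHROM_LENGTHS[c] - 1_000_000)
                         for c in gene_chrom])
    gene_strand = rng.choice(["+", "-"], size=cfg.n_genes)

    # --- drivers, passengers, targets
    shuffled = [str(g) for g in rng.permutation(genes)]
    drivers = shuffled[:cfg.n_drivers]
    cis_drivers = drivers[:cfg.n_cis_drivers]
    non_driver_genes = [g for g in shuffled[cfg.n_drivers:]]
    passengers = non_driver_genes[:cfg.n_passenger_genes]

    gene_index = {g: i for i, g in enumerate(genes)}
    iso_of_gene: dict[str, list[str]] = {}
    for t, g in zip(transcripts, tr_gene):
        iso_of_gene.setdefault(g, []).append(t)

    # targets are drawn from multi-isoform genes only: the scan's input
    # universe excludes single-isoform genes by construction
    available = [g for g in non_driver_genes if len(iso_of_gene[g]) >= 2]
    truth_targets: dict[str, pd.DataFrame] = {}
    dual_genes: dict[str, list] = {}
    for d in drivers:
        t = cfg.targets_per_driver
        n_dual = int(round(cfg.dual_fraction * t / 2))
        if t - n_dual > len(available):
            raise ValueError("config demands more targets than available isoforms")
        chosen_dual = available[:n_dual]
        del available[:n_dual]
        rows = []
        for g in chosen_dual:
            isos = iso_of_gene[g]
            rows.append((isos[0], g, +1))
            rows.append((isos[1], g, -1))
        n_single = t - 2 * n_dual
        singles = []
        while len(singles) < n_single:
            g = available.pop(0)
            singles.append(g)
        for g in singles:
            sign = int(rng.choice([-1, 1]))
            rows.append((iso_of_gene[g][0], g, sign))
        truth_targets[d] = pd.DataFrame(
            rows, columns=["transcript_id", "gene_id", "sign"])
        dual_genes[d] = chosen_dual

    # cis drivers: relocate target-gene TSS into the driver's cis window
    for d in cis_drivers:
        di = gene_index[d]
        for g in truth_targets[d]["gene_id"].unique():
            gi = gene_index[g]
            gene_chrom[gi] = gene_chrom[di]
            offset = int(rng.integers(-cfg.cis_window // 2, cfg.cis_window // 2))
            gene_tss[gi] = max(1, int(gene_tss[di]) + offset)

    ann_rows = []
    for t, g in zip(transcripts, tr_gene):
        gi = gene_index[g]
        j = int(t.rsplit(".", 1)[1]) - 1
        offset = 0 if j == 0 else int(rng.integers(1, 5_000))
        if gene_strand[gi] == "+":
            tss = int(gene_tss[gi]) + offset
            start, end = tss, tss + int(rng.integers(1_000, 100_000))
        else:
            tss = int(gene_tss[gi]) - offset
            end = tss
            start = max(1, tss - int(rng.integers(1_000, 100_000)))
        ann_rows.append((t, g, gene_chrom[gi], gene_strand[gi], tss, start, end))
    ann = pd.DataFrame(ann_rows, columns=["transcript_id", "gene_id", "chrom",
                                          "strand", "tss", "start", "end"]
                       ).set_index("transcript_id")
    annotation = GeneAnnotation(ann)

    # --- mutations
    maf_rows = []
    mutant_samples: dict[str, list] = {}
    sample_arr = np.array(samples)
    for d in drivers:
        n_mut = int(rng.binomial(cfg.n_samples, cfg.mutation_prevalence))
        n_mut = max(n_mut, 1)
        picked = sorted(rng.choice(cfg.n_samples, size=n_mut, replace=False))
        mutant_samples[d] = [samples[i] for i in picked]
        for s in mutant_samples[d]:
            maf_rows.append((d, "SNP", s))
    lo, hi = cfg.passenger_prevalence
    for g in passengers:
        prev = float(rng.uniform(lo, hi))
        n_mut = max(int(rng.binomial(cfg.n_samples, prev)), 1)
        picked = sorted(rng.choice(cfg.n_samples, size=n_mut, replace=False))
        for i in picked:
            maf_rows.append((g, "SNP", samples[i]))
        # sprinkle occasional non-SNV records (ignored by the scan)
        if rng.random() < 0.2:
            maf_rows.append((g, str(rng.choice(["INS", "DEL"])),
                             str(rng.choice(sample_arr))))
    mutations = MutationTable(pd.DataFrame(
        maf_rows, columns=["gene", "variant_type", "sample"]))

    # --- expression: log-normal baseline x library size, planted effects
    mu = rng.normal(cfg.baseline_log_mean, 1.0, size=n_tr)
    sd = rng.uniform(0.6, 1.4, size=n_tr) * cfg.baseline_log_sd
    X = np.exp(mu[:, None] + sd[:, None] * rng.standard_normal((n_tr, cfg.n_samples)))
    lib = np.exp(rng.normal(0.0, cfg.library_size_sd, size=cfg.n_samples))
    X *= lib[None, :]

    tr_index = {t: i for i, t in enumerate(transcripts)}
    for d in drivers:
        mut_cols = np.array([samples.index(s) for s in mutant_samples[d]])
        for _, r in truth_targets[d].iterrows():
            row = tr_index[r["transcript_id"]]
            X[row, mut_cols] *= 2.0 ** (r["sign"] * cfg.effect_size)

    if cfg.dropout > 0:
        X[rng.random(X.shape) < cfg.dropout] = 0.0

    expr = IsoformExpressionMatrix(
        pd.DataFrame(X, index=pd.Index(transcripts, name="transcript_id"),
                     columns=samples),
        pd.Series(tr_gene, index=pd.Index(transcripts, name="transcript_id"),
                  name="gene_id"))
    truth = SyntheticTruth(drivers=list(drivers),
                           mutant_samples=mutant_samples,
                           targets=truth_targets, dual_genes=dual_genes,
                           cis_drivers=list(cis_drivers))
    return expr, mutations, annotation, truth


def simulate_peak_matrix(expr: IsoformExpressionMatrix,
                         annotation: GeneAnnotation, truth: SyntheticTruth,
                         config: SimulationConfig) -> PeakMatrix:
    """Optional correlated accessibility peaks for a simulated cohort.

    Each annotated gene receives 1-3 peaks inside its span with Gaussian
    log2-normalized baselines; peaks of genes carrying planted targets are
    coupled to a z-scored isoform of their gene with the configured
    coupling, and peaks of driver genes receive a mutant-sample shift.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    samples = list(expr.sample_ids)
    coupled_genes = {g for d in truth.drivers
                     for g in truth.targets[d]["gene_id"]}
    rows, values = [], []
    region_p = np.array([0.3, 0.3, 0.1, 0.2, 0.05, 0.05])
    for gene, grp in annotation.transcripts.groupby("gene_id", sort=True):
        n_pk = int(rng.integers(cfg.peaks_per_gene[0], cfg.peaks_per_gene[1] + 1))
        lo = int(grp["start"].min()) if "start" in grp else int(grp["tss"].min())
        hi = int(grp["end"].max()) if "end" in grp else lo + 1000
        for j in range(n_pk):
            start = int(rng.integers(max(0, lo - 1), max(lo, hi - 500)))
            pid = f"{gene}_pk{j+1}"
            rows.append((pid, grp["chrom"].iloc[0], start, start + 500,
                         str(rng.choice(REGION_CLASSES, p=region_p))))
            v = rng.normal(2.0, 1.0, size=len(samples))
            if gene in coupled_genes:
                iso = expr.gene_ids.index[expr.gene_ids == gene][0]
                e = np.log1p(expr.values.loc[iso].to_numpy(dtype=float))
                if e.std() > 0:
                    v += cfg.accessibility_coupling * (e - e.mean()) / e.std()
            if gene in truth.drivers:
                mut = np.isin(samples, truth.mutant_samples[gene])
                v[mut] += cfg.accessibility_coupling
            values.append(v)
    peaks = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end",
                                        "region_class"]).set_index("peak_id")
    mat = pd.DataFrame(np.vstack(values), index=peaks.index, columns=samples)
    return PeakMatrix(mat, peaks)


def evaluate_recovery(results: pd.DataFrame, truth: SyntheticTruth,
                      targets: dict[str, pd.DataFrame] | None = None,
                      top_k: int = 100) -> dict:
    """Parameter-recovery metrics for one cohort.

    driver sensitivity = called planted drivers / planted drivers;
    empirical FDR = non-planted calls / all calls (NaN when nothing is
    called); target recall@k = planted targets found in the top-k list,
    averaged over recovered drivers (NaN when none recovered).
    """
    called = set(results.index[results["is_isomas"]]) if len(results) else set()
    planted = set(truth.drivers)
    sensitivity = (len(called & planted) / len(planted)) if planted else float("nan")
    fdr = (len(called - planted) / len(called)) if called else float("nan")
    recalls = []
    if targets is not None:
        for d in sorted(called & planted):
            want = set(truth.targets[d]["transcript_id"])
            got = set(targets[d]["transcript_id"].iloc[:top_k])
            recalls.append(len(want & got) / len(want))
    recall = float(np.mean(recalls)) if recalls else float("nan")
    return {"driver_sensitivity": float(sensitivity),
            "empirical_fdr": float(fdr),
            "target_recall_at_k": recall,
            "n_called": len(called)}
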