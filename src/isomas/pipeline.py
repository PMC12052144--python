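"""End-to-end orchestration with deterministic seeding and manifests.

Stages run in order: (optional) simulate -> scan (preprocess + PCA +
association test) -> downstream -> (optional) accessibility.  Every stage
writes TSV outputs with YAML sidecars into the output directory; a
manifest.json with sha256 checksums of all outputs is written at the end,
so a rerun with an identical config and seed can be verified byte for
byte.  Each stochastic stage receives a child seed derived as
seed + stage index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import downstream as ds
from . import io_formats as io
from . import synthetic as syn
from .pca import fit_pca
from .preprocess import preprocess as _preprocess
from .scan import GeneMutationStatus, ScanResult
from .scan import scan as _scan

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_FAILURE = 4

_STAGE_INDEX = {"simulate": 0, "scan": 1, "downstream": 2, "accessibility": 3}


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    out_dir: str = "isomas_out"
    expression: str | None = None
    maf: str | None = None
    annotation: str | None = None
    peak_bed: str | None = None
    peak_matrix: str | None = None
    gene_sets: str | None = None
    K: int = 50
    alpha_pc: float = 0.05
    fdr: float = 0.05
    min_mutant_fraction: float = 0.02
    top_k: int = 100
    rank_mode: str = "abs"
    cis_window: int = 1_000_000
    chrom_test: str = "ks"
    min_samples_per_isoform: int = 3
    min_isoforms_per_sample: int = 200
    mean_cutoff_lo: float = 0.1
    mean_cutoff_hi: float = 8.0
    dispersion_cutoff: float = 1.0
    seed: int = 0
    stages: tuple = ("scan", "downstream")
    simulate: dict | None = None     # SimulationConfig overrides, triggers simulate stage
    barcode_prefix_len: int | None = None
    variant_filter: str | None = None  # file of variant ids restricting mutant status

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def child_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGE_INDEX[stage]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path) -> Path:
    entries = {}
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(out_dir))] = _sha256(p)
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Raises :class:`StageFailure` naming the failing stage on any stage
    error.  Rerunning with an identical config reproduces identical
    manifest checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    state: dict = {}
    stages = list(config.stages)
    if config.simulate is not None and "simulate" not in stages:
        stages = ["simulate"] + stages
    for stage in stages:
        try:
            _run_stage(stage, config, state, out)
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise StageFailure(stage, exc) from exc
    write_manifest(out)
    return out


def _run_stage(stage: str, cfg: RunConfig, state: dict, out: Path) -> None:
    logger.info("running stage %s", stage)
    if stage == "simulate":
        _stage_simulate(cfg, state, out)
    elif stage == "scan":
        _stage_scan(cfg, state, out)
    elif stage == "downstream":
        _stage_downstream(cfg, state, out)
    elif stage == "accessibility":
        _stage_accessibility(cfg, state, out)
    else:
        raise ValueError(f"unknown stage {stage!r}")


def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> None:
    overrides = dict(cfg.simulate or {})
    overrides.setdefault("seed", cfg.child_seed("simulate"))
    sim_cfg = syn.SimulationConfig(**overrides)
    expr, mutations, annotation, truth = syn.simulate_cohort(sim_cfg)
    state.update(expr=expr, mutations=mutations, annotation=annotation,
                 truth=truth, sim_cfg=sim_cfg)
    params = dataclasses.asdict(sim_cfg)
    ex = expr.values.copy()
    ex.insert(0, "gene_id", expr.gene_ids)
    io.write_table(ex, out / "expression.tsv", params, sim_cfg.seed)
    maf = mutations.records.rename(columns={
        "gene": "Hugo_Symbol", "variant_type": "Variant_Type",
        "sample": "Tumor_Sample_Barcode"})
    io.write_table(maf, out / "mutations.maf", params, sim_cfg.seed, index=False)
    io.write_table(annotation.transcripts, out / "annotation.tsv", params,
                   sim_cfg.seed)
    io.write_table(truth.to_frame(), out / "truth.tsv", params, sim_cfg.seed,
                   index=False)
    if sim_cfg.simulate_peaks:
        peak_matrix = syn.simulate_peak_matrix(expr, annotation, truth, sim_cfg)
        state["peak_matrix"] = peak_matrix
        io.write_table(peak_matrix.values, out / "peaks_matrix.tsv",
                       params, sim_cfg.seed)
        bed = peak_matrix.peaks.reset_index()
        bed = bed[["chrom", "start", "end", "peak_id"]].assign(
            score=0, strand=".",
            region_class=peak_matrix.peaks["region_class"].to_numpy())
        bed.to_csv(out / "peaks.bed", sep="\t", header=False, index=False)


def _load_inputs(cfg: RunConfig, state: dict) -> None:
    if "expr" not in state:
        if cfg.expression is None or cfg.maf is None:
            raise FileNotFoundError(
                "scan requires expression and MAF inputs (or a simulate stage)")
        state["expr"] = io.read_expression_matrix(cfg.expression)
        state["mutations"] = io.read_mutation_maf(cfg.maf)
        if cfg.annotation:
            state["annotation"] = io.read_gene_annotation(cfg.annotation)
    if cfg.barcode_prefix_len is not None:
        state["mutations"] = state["mutations"].truncate_barcodes(
            cfg.barcode_prefix_len)


def _stage_scan(cfg: RunConfig, state: dict, out: Path) -> None:
    _load_inputs(cfg, state)
    expr: io.IsoformExpressionMatrix = state["expr"]
    scaled, report = _preprocess(
        expr, state.get("annotation"),
        min_samples_per_isoform=cfg.min_samples_per_isoform,
        min_isoforms_per_sample=cfg.min_isoforms_per_sample,
        mean_cutoff_lo=cfg.mean_cutoff_lo, mean_cutoff_hi=cfg.mean_cutoff_hi,
        dispersion_cutoff=cfg.dispersion_cutoff)
    model = fit_pca(scaled, cfg.K)
    vfilter = None
    if cfg.variant_filter:
        vfilter = [line.strip() for line in open(cfg.variant_filter)
                   if line.strip()]
    result = _scan(model, state["mutations"], cfg.min_mutant_fraction,
                   cfg.alpha_pc, cfg.fdr, cfg.top_k, cfg.rank_mode,
                   variant_filter=vfilter)
    state.update(scaled=scaled, model=model, scan_result=result,
                 preprocess_report=report)
    params = {"K": model.K, "alpha_pc": cfg.alpha_pc, "fdr": cfg.fdr,
              "min_mutant_fraction": cfg.min_mutant_fraction,
              "top_k": cfg.top_k, "rank_mode": cfg.rank_mode}
    io.write_table(report.to_frame(), out / "preprocess_report.tsv",
                   report.parameters, cfg.seed)
    io.write_table(model.loadings, out / "pca_loadings.tsv", params, cfg.seed)
    io.write_table(model.scores, out / "pca_scores.tsv", params, cfg.seed)
    io.write_table(result.genes, out / "isomas_genes.tsv", params, cfg.seed)
    io.write_table(result.targets_table(expr.gene_ids),
                   out / "isomas_targets.tsv", params, cfg.seed, index=False)


def _require_scan_outputs(cfg: RunConfig, state: dict, out: Path) -> None:
    """Rehydrate scan results from cached TSVs for stage-isolated reruns."""
    if "scan_result" in state:
        return
    genes = io.read_table(out / "isomas_genes.tsv")
    targets_long = pd.read_csv(out / "isomas_targets.tsv", sep="\t")
    _load_inputs(cfg, state)
    loadings = io.read_table(out / "pca_loadings.tsv")
    scores = io.read_table(out / "pca_scores.tsv")
    from .pca import PcaModel
    model = PcaModel(loadings, scores,
                     np.zeros(loadings.shape[1]), loadings.shape[1])
    targets = {g: grp.drop(columns=["gene"]).reset_index(drop=True)
               for g, grp in targets_long.groupby("gene", sort=False)}
    samples = list(scores.index)
    statuses = {}
    for g in genes.index[genes["is_isomas"]]:
        statuses[g] = GeneMutationStatus(
            g, state["mutations"].mutant_status(g, samples))
    state.update(model=model,
                 scan_result=ScanResult(genes, targets, model, statuses))


def _stage_downstream(cfg: RunConfig, state: dict, out: Path) -> None:
    _require_scan_outputs(cfg, state, out)
    result: ScanResult = state["scan_result"]
    expr: io.IsoformExpressionMatrix = state["expr"]
    annotation: io.GeneAnnotation | None = state.get("annotation")
    universe = list(result.model.feature_ids)
    params = {"cis_window": cfg.cis_window, "top_k": cfg.top_k,
              "chrom_test": cfg.chrom_test}

    dual_rows, cis_rows, chrom_rows = [], [], []
    for gene in result.isomas_genes:
        status = result.statuses[gene]
        tlist = list(result.targets[gene]["transcript_id"])
        _, agg = ds.detect_dual_direction(expr, status, tlist)
        dual_rows.append((gene, agg["n_dual_genes"], agg["mHMP"],
                          agg["neg_log10_mHMP"]))
        if annotation is not None:
            cres = ds.cis_enrichment_test(gene, tlist, annotation, universe,
                                          cfg.cis_window)
            if cres is not None:
                cis_rows.append((gene, cres.k, cres.m, cres.q, cres.N,
                                 cres.p, cres.trans_consistent))
            try:
                d, p, span = ds.chromosome_preference_test(
                    tlist, annotation, universe, method=cfg.chrom_test,
                    seed=cfg.child_seed("downstream"))
                chrom_rows.append((gene, d, p, span))
            except ValueError:
                pass
    io.write_table(pd.DataFrame(dual_rows, columns=[
        "gene", "n_dual_genes", "mHMP", "neg_log10_mHMP"]),
        out / "dual_direction.tsv", params, cfg.seed, index=False)
    io.write_table(pd.DataFrame(cis_rows, columns=[
        "gene", "k", "m", "q", "N", "p", "trans_consistent"]),
        out / "cis_trans.tsv", params, cfg.seed, index=False)
    io.write_table(pd.DataFrame(chrom_rows, columns=[
        "gene", "D", "p", "chrom_span"]),
        out / "chrom_pref.tsv", params, cfg.seed, index=False)

    if cfg.gene_sets:
        sets = io.read_gmt(cfg.gene_sets)
        background = set(state["mutations"].genes)
        enr = []
        query = set(result.isomas_genes)
        for name, members in sorted(sets.items()):
            res = ds.hypergeometric_enrichment(query, set(members) & background,
                                               background, name)
            enr.append((name, res.N, res.m, res.q, res.k, res.p))
        io.write_table(pd.DataFrame(enr, columns=["set", "N", "m", "q", "k", "p"]),
                       out / "enrichment.tsv", params, cfg.seed, index=False)


def _stage_accessibility(cfg: RunConfig, state: dict, out: Path) -> None:
    _require_scan_outputs(cfg, state, out)
    result: ScanResult = state["scan_result"]
    expr: io.IsoformExpressionMatrix = state["expr"]
    annotation = state.get("annotation")
    if annotation is None:
        raise FileNotFoundError("accessibility stage requires an annotation")
    if "peak_matrix" in state:
        pm = state["peak_matrix"]
    elif cfg.peak_bed and cfg.peak_matrix:
        pm = io.read_peak_matrix(cfg.peak_bed, cfg.peak_matrix)
    else:
        raise FileNotFoundError("accessibility stage requires peak inputs")
    mapping = acc.map_peaks_to_loci(pm, annotation)
    params = {"seed": cfg.child_seed("accessibility")}

    assoc_rows, pair_records, called_pairs = [], [], []
    for gene in result.isomas_genes:
        status = result.statuses[gene]
        gpeaks = acc.peaks_of_gene(mapping, gene)
        if gpeaks:
            _, summary = acc.mutation_accessibility_test(pm, status, gpeaks)
            for key, val in summary.items():
                assoc_rows.append((gene, "mutation_t", key, val))
        tgenes = pd.unique(expr.gene_ids.loc[
            expr.gene_ids.index.intersection(
                pd.Index(result.targets[gene]["transcript_id"]))])
        for tg in tgenes:
            tpeaks = acc.peaks_of_gene(mapping, tg)
            rec = acc.pairwise_peak_hmp(gpeaks, tpeaks, pm, gene, tg)
            pair_records.append(rec)
            called_pairs.append((gene, tg))
    io.write_table(pd.DataFrame(assoc_rows, columns=[
        "gene", "test", "stratum", "hmp"]),
        out / "peak_assoc.tsv", params, cfg.seed, index=False)

    defined = [r for r in pair_records if np.isfinite(r.hmp)]
    rnd_pairs = acc.draw_random_pairs(
        state["mutations"].genes, annotation.genes.index, called_pairs,
        n_pairs=len(defined), seed=cfg.child_seed("accessibility"))
    rnd_records = []
    for g, t in rnd_pairs:
        rec = acc.pairwise_peak_hmp(acc.peaks_of_gene(mapping, g),
                                    acc.peaks_of_gene(mapping, t), pm,
                                    g, t, pool="random_pair")
        if np.isfinite(rec.hmp):
            rnd_records.append(rec)
    all_recs = defined + rnd_records
    io.write_table(pd.DataFrame(
        [(r.isomas_gene, r.target, r.n_peak_pairs, r.hmp, r.pool)
         for r in all_recs],
        columns=["gene", "target", "n_peak_pairs", "hmp", "pool"]),
        out / "pair_hmp.tsv", params, cfg.seed, index=False)
    ks = acc.compare_pair_pools([r.hmp for r in defined],
                                [r.hmp for r in rnd_records])
    ks_df = pd.DataFrame([{"D": ks[0] if ks else np.nan,
                           "p": ks[1] if ks else np.nan,
                           "n_isomas": len(defined),
                           "n_random": len(rnd_records)}])
    io.write_table(ks_df, out / "pool_ks.tsv", params, cfg.seed, index=False)
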