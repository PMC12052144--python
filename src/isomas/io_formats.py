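"""Input/output and core data containers.

Readers for the three core inputs — an isoform-by-sample FPKM matrix (TSV),
somatic mutation calls (MAF), and a transcript annotation (GTF or a minimal
TSV dialect) — plus the optional chromatin-accessibility inputs (BED6+1 peak
annotation and a peak-by-sample TSV), gene sets in GMT format, and a writer
for result tables with a YAML parameter sidecar.

Coordinate conventions: GTF input is 1-based inclusive and the internal TSS
stays a 1-based integer; BED input is 0-based half-open and is kept that way
for interval arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: the 24 nuclear chromosomes, in the order used for binned analyses
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

VARIANT_TYPES = ("SNP", "INS", "DEL", "other")

REGION_CLASSES = ("Promoter", "Intron", "Exon", "Distal", "UTR3", "UTR5")

_REGION_ALIASES = {
    "3'UTR": "UTR3", "3UTR": "UTR3", "UTR3": "UTR3",
    "5'UTR": "UTR5", "5UTR": "UTR5", "UTR5": "UTR5",
    "Promoter": "Promoter", "Intron": "Intron", "Exon": "Exon",
    "Distal": "Distal",
}


def normalize_chrom(label: str) -> str | None:
    """Map a chromosome label onto the 24-chromosome set, or None."""
    c = str(label)
    if c.startswith(("chr", "Chr", "CHR")):
        c = c[3:]
    if c == "23":
        c = "X"
    if c == "24":
        c = "Y"
    return c if c in CHROMOSOMES else None


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IsoformExpressionMatrix:
    """Transcript-by-sample FPKM values with a transcript-to-gene map.

    ``values`` is indexed by transcript id with one column per sample;
    ``gene_ids`` maps each transcript to exactly one gene.  Entries are
    non-negative; transcript and sample ids are unique.
    """

    values: pd.DataFrame
    gene_ids: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate transcript id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not self.gene_ids.index.equals(idx):
            self.gene_ids = self.gene_ids.reindex(idx)
        if self.gene_ids.isna().any():
            bad = self.gene_ids.index[self.gene_ids.isna()][0]
            raise ValueError(f"transcript {bad!r} has no gene_id")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at transcript {idx[i]!r}, "
                f"sample {self.values.columns[j]!r}")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_transcripts(self, transcript_ids) -> "IsoformExpressionMatrix":
        return IsoformExpressionMatrix(self.values.loc[transcript_ids],
                                       self.gene_ids.loc[transcript_ids])

    def subset_samples(self, sample_ids) -> "IsoformExpressionMatrix":
        return IsoformExpressionMatrix(self.values[list(sample_ids)],
                                       self.gene_ids)


@dataclass
class MutationTable:
    """Per-sample somatic variant calls (gene symbol, variant type, sample).

    Duplicate (gene, sample) records collapse to a single mutant call when
    binary status vectors are derived.
    """

    records: pd.DataFrame  # columns: gene, variant_type, sample

    def __post_init__(self) -> None:
        need = {"gene", "variant_type", "sample"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation records missing columns: {sorted(missing)}")
        bad = ~self.records["variant_type"].isin(VARIANT_TYPES)
        if bad.any():
            self.records = self.records.copy()
            self.records.loc[bad, "variant_type"] = "other"

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.records["gene"].unique())

    def snv_records(self, variant_filter=None) -> pd.DataFrame:
        """SNV (variant_type == SNP) records, optionally restricted to a
        user-supplied set of (gene, sample) keys or variant identifiers."""
        rec = self.records[self.records["variant_type"] == "SNP"]
        if variant_filter is not None and "variant_id" in rec.columns:
            rec = rec[rec["variant_id"].isin(set(variant_filter))]
        return rec

    def mutant_status(self, gene: str, sample_ids, snv_only: bool = True,
                      variant_filter=None) -> np.ndarray:
        """Binary mutant indicator over ``sample_ids`` (1 = mutant)."""
        rec = self.snv_records(variant_filter) if snv_only else self.records
        mutant = set(rec.loc[rec["gene"] == gene, "sample"])
        return np.fromiter((s in mutant for s in sample_ids), dtype=bool,
                           count=len(sample_ids))

    def truncate_barcodes(self, prefix_len: int | None) -> "MutationTable":
        """Truncate sample barcodes to a prefix (TCGA-style suffix removal)."""
        if prefix_len is None:
            return self
        rec = self.records.copy()
        rec["sample"] = rec["sample"].str.slice(0, prefix_len)
        return MutationTable(rec)


@dataclass
class GeneAnnotation:
    """Transcript coordinates plus derived gene-level TSS.

    ``transcripts`` is indexed by transcript id with columns gene_id, chrom,
    strand, tss and (optionally populated) start/end spans, all 1-based
    inclusive.  The gene TSS is the 5'-most transcript start per strand
    (min start on '+', max end on '-').  Records on chromosomes outside the
    24-chromosome set are skipped on read and counted in ``n_skipped``.
    """

    transcripts: pd.DataFrame
    genes: pd.DataFrame = field(default=None)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = derive_gene_tss(self.transcripts)
        if (self.transcripts["tss"] < 1).any():
            bad = self.transcripts.index[self.transcripts["tss"] < 1][0]
            raise ValueError(f"transcript {bad!r} has TSS < 1")

    def annotated(self, transcript_ids) -> pd.Index:
        """The subset of ``transcript_ids`` present in the annotation."""
        return pd.Index(transcript_ids).intersection(self.transcripts.index)


@dataclass
class PeakMatrix:
    """Peak-by-sample log2-normalized accessibility with peak coordinates.

    ``peaks`` is indexed by peak id with columns chrom, start, end (0-based
    half-open) and region_class from the six-value set.
    """

    values: pd.DataFrame
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.peaks["start"] >= self.peaks["end"]).any():
            bad = self.peaks.index[self.peaks["start"] >= self.peaks["end"]][0]
            raise ValueError(f"peak {bad!r} has start >= end")
        bad = ~self.peaks["region_class"].isin(REGION_CLASSES)
        if bad.any():
            name = self.peaks.index[bad][0]
            raise ValueError(f"peak {name!r} has unknown region class")

    def average_replicates(self, sample_of_replicate: dict) -> "PeakMatrix":
        """Average technical replicate columns per biological sample."""
        groups = self.values.T.groupby(
            [sample_of_replicate.get(c, c) for c in self.values.columns])
        return PeakMatrix(groups.mean().T, self.peaks)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> IsoformExpressionMatrix:
    """Read a transcript-by-sample FPKM TSV.

    Header: ``transcript_id<TAB>gene_id<TAB><sample1>...``.  Duplicate
    transcript ids, missing gene ids and negative values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["transcript_id", "gene_id"]:
        raise ValueError(
            f"{path}: expected leading columns transcript_id, gene_id, "
            f"got {list(df.columns[:2])}")
    dup = df["transcript_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}:{line}: duplicate transcript id "
                         f"{df['transcript_id'][dup].iloc[0]!r}")
    if df["gene_id"].isna().any() or (df["gene_id"].str.len() == 0).any():
        bad = df["gene_id"].isna() | (df["gene_id"].str.len() == 0)
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}:{line}: missing gene_id for transcript "
                         f"{df['transcript_id'][bad].iloc[0]!r}")
    values = df.set_index("transcript_id").drop(columns=["gene_id"])
    values = values.astype(float)
    gene_ids = df.set_index("transcript_id")["gene_id"]
    return IsoformExpressionMatrix(values, gene_ids)


_MAF_TYPE_MAP = {"SNP": "SNP", "SNV": "SNP", "INS": "INS", "DEL": "DEL",
                 "DNP": "other", "TNP": "other", "ONP": "other"}


def read_mutation_maf(path) -> MutationTable:
    """Read a MAF-like tab-separated mutation file.

    Requires columns Hugo_Symbol, Variant_Type, Tumor_Sample_Barcode;
    comment lines starting with '#' are skipped.  All variant types are
    retained — restriction to SNVs happens at scan time.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     low_memory=False)
    required = ["Hugo_Symbol", "Variant_Type", "Tumor_Sample_Barcode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF lacks required column(s) {missing}")
    rec = pd.DataFrame({
        "gene": df["Hugo_Symbol"],
        "variant_type": df["Variant_Type"].map(
            lambda v: _MAF_TYPE_MAP.get(str(v).upper(), "other")),
        "sample": df["Tumor_Sample_Barcode"],
    })
    for extra in ("HGVSp_Short", "Variant_Classification"):
        if extra in df.columns:
            rec["variant_id" if extra == "HGVSp_Short" else "variant_class"] = df[extra]
    return MutationTable(rec)


def derive_gene_tss(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Gene TSS = 5'-most transcript start per strand.

    '+' genes take the minimum transcript TSS, '-' genes the maximum."""
    rows = []
    for gene, grp in transcripts.groupby("gene_id", sort=True):
        strand = grp["strand"].iloc[0]
        tss = int(grp["tss"].min() if strand == "+" else grp["tss"].max())
        rows.append((gene, grp["chrom"].iloc[0], strand, tss))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"]
                        ).set_index("gene_id")


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_annotation(path) -> GeneAnnotation:
    """Read transcript annotation from GTF or the 5-column TSV dialect.

    GTF (1-based inclusive): transcript spans are taken from 'transcript'
    features, or assembled from exon extents when absent; the TSS is the
    start on '+' and the end on '-'.  TSV dialect: columns transcript_id,
    gene_id, chrom, strand, tss (optional extra columns start, end).
    Records on chromosomes outside the 24-chromosome set are skipped and
    counted.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    if first.count("\t") >= 8:
        return _read_gtf(path)
    return _read_annotation_tsv(path)


def _read_gtf(path) -> GeneAnnotation:
    spans: dict[str, list] = {}
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("transcript", "exon"):
                continue
            chrom_n = normalize_chrom(chrom)
            if chrom_n is None:
                n_skipped += 1
                logger.warning("skipping record on unknown chromosome %r", chrom)
                continue
            a = _parse_gtf_attributes(attrs)
            tid, gid = a.get("transcript_id"), a.get("gene_id")
            if tid is None or gid is None:
                continue
            start, end = int(start), int(end)
            rec = spans.setdefault(tid, [gid, chrom_n, strand, start, end])
            rec[3] = min(rec[3], start)
            rec[4] = max(rec[4], end)
    if not spans:
        raise ValueError(f"{path}: no transcript records parsed")
    df = pd.DataFrame.from_dict(
        spans, orient="index",
        columns=["gene_id", "chrom", "strand", "start", "end"])
    df.index.name = "transcript_id"
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    df = df[["gene_id", "chrom", "strand", "tss", "start", "end"]]
    return GeneAnnotation(df, n_skipped=n_skipped)


def _read_annotation_tsv(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str,
                                            "gene_id": str, "chrom": str})
    required = ["transcript_id", "gene_id", "chrom", "strand", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation TSV lacks column(s) {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    n_skipped = int(df["chrom"].isna().sum())
    if n_skipped:
        logger.warning("skipped %d annotation records on unknown chromosomes",
                       n_skipped)
        df = df[df["chrom"].notna()]
    df = df.set_index("transcript_id")
    df["tss"] = df["tss"].astype(int)
    cols = ["gene_id", "chrom", "strand", "tss"]
    for opt in ("start", "end"):
        if opt in df.columns:
            df[opt] = df[opt].astype(int)
            cols.append(opt)
    return GeneAnnotation(df[cols], n_skipped=n_skipped)


def read_peak_bed(path) -> pd.DataFrame:
    """Read a BED6+1 peak file (7th column = region class), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "peak_id", "score",
                            "strand", "region_class"],
                     dtype={"chrom": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df = df[df["chrom"].notna()]
    df["region_class"] = df["region_class"].map(_REGION_ALIASES)
    if df["region_class"].isna().any():
        bad = df.loc[df["region_class"].isna(), "peak_id"].iloc[0]
        raise ValueError(f"{path}: unknown region class for peak {bad!r}")
    return df.set_index("peak_id")[["chrom", "start", "end", "region_class"]]


def read_peak_matrix(bed_path, tsv_path) -> PeakMatrix:
    """Assemble a PeakMatrix from a BED6+1 file and a peak-by-sample TSV."""
    peaks = read_peak_bed(bed_path)
    values = pd.read_csv(tsv_path, sep="\t", index_col=0)
    common = peaks.index.intersection(values.index)
    if common.empty:
        raise ValueError("no peak ids shared between BED and matrix")
    return PeakMatrix(values.loc[common].astype(float), peaks.loc[common])


def read_gmt(path) -> dict[str, set]:
    """Read gene sets in GMT format: name<TAB>description<TAB>gene..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def intersect_samples(expr_samples, mut_samples) -> list:
    """Stable sample intersection: expression column order wins."""
    mset = set(mut_samples)
    return [s for s in expr_samples if s in mset]


def write_table(df: pd.DataFrame, path, params: dict | None = None,
                seed: int | None = None, index: bool = True) -> Path:
    """Write a result table as TSV (floats at 12 significant digits) plus a
    YAML sidecar recording parameters and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.12g", index=index)
    sidecar = {"table": path.name, "parameters": params or {}}
    if seed is not None:
        sidecar["seed"] = int(seed)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
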