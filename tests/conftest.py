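"""Shared fixtures: tiny hand-built matrices and one planted cohort.

All fixtures are generated programmatically; the planted cohort is
session-scoped because preprocessing + PCA + the scan over ~200 genes is
the expensive part shared by several tests.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from isomas.io_formats import IsoformExpressionMatrix, MutationTable
from isomas.pca import fit_pca
from isomas.preprocess import preprocess
from isomas.scan import scan
from isomas.synthetic import SimulationConfig, simulate_cohort

# sparse-feature synthetic cohorts trip the min-isoforms-per-sample default
# meant for transcriptome-scale data; tests use a sample filter scaled to
# the simulated matrix size
SIM_MIN_ISOFORMS_PER_SAMPLE = 10


def make_expression(values, transcript_ids, gene_ids, sample_ids):
    """Convenience constructor from plain arrays/lists."""
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=pd.Index(transcript_ids, name="transcript_id"),
                      columns=sample_ids)
    return IsoformExpressionMatrix(
        df, pd.Series(gene_ids, index=df.index, name="gene_id"))


def make_mutations(rows):
    """rows: iterable of (gene, variant_type, sample)."""
    return MutationTable(pd.DataFrame(
        rows, columns=["gene", "variant_type", "sample"]))


@pytest.fixture
def small_expr():
    """3 transcripts from 2 genes, 4 samples, strictly positive FPKM."""
    return make_expression(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [5.0, 5.0, 5.0, 5.0]],
        ["tA.1", "tA.2", "tB.1"], ["GA", "GA", "GB"],
        ["s1", "s2", "s3", "s4"])


@pytest.fixture(scope="session")
def planted_cohort():
    """One power-setting cohort with a cis and a trans driver, fully scanned."""
    cfg = SimulationConfig(seed=11, n_cis_drivers=1)
    expr, mutations, annotation, truth = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, report = preprocess(
            expr, annotation,
            min_isoforms_per_sample=SIM_MIN_ISOFORMS_PER_SAMPLE)
        model = fit_pca(scaled, 50)
        result = scan(model, mutations)
    return dict(config=cfg, expr=expr, mutations=mutations,
                annotation=annotation, truth=truth, scaled=scaled,
                model=model, result=result, report=report)


@pytest.fixture(scope="session")
def null_cohort():
    """A driver-free cohort for null-behavior tests."""
    cfg = SimulationConfig(seed=19, n_samples=200, n_drivers=0,
                           effect_size=0.0, n_passenger_genes=100)
    expr, mutations, annotation, truth = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, _ = preprocess(
            expr, annotation,
            min_isoforms_per_sample=SIM_MIN_ISOFORMS_PER_SAMPLE)
        model = fit_pca(scaled, 50)
    return dict(config=cfg, expr=expr, mutations=mutations, model=model)
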