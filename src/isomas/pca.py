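"""Principal component decomposition of the scaled isoform matrix.

The scan rests on the identity E x L = S: the scaled samples-by-features
expression matrix E times the features-by-K loading matrix L yields the
samples-by-K PC score matrix S.  Each PC is a "meta-isoform" — a linear
combination of the input isoforms — and its per-sample values are the PC
scores the association test operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_K = 50


@dataclass
class PcaModel:
    """Loadings L (features x K), scores S (samples x K), variance fractions.

    Invariants (asserted on every fit): columns of L are orthonormal,
    variance fractions are non-increasing, and S reproduces E_scaled x L to
    within 1e-8 relative error.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: np.ndarray
    K: int

    @property
    def feature_ids(self) -> pd.Index:
        return self.loadings.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def check_invariants(self, atol: float = 1e-8) -> None:
        L = self.loadings.to_numpy()
        gram = L.T @ L
        if not np.allclose(gram, np.eye(self.K), atol=atol):
            raise AssertionError("PC loadings are not orthonormal")
        if np.any(np.diff(self.variance_fraction) > atol):
            raise AssertionError("variance fractions are not non-increasing")


def fit_pca(scaled_matrix: pd.DataFrame, K: int = DEFAULT_K,
            randomized: bool = False, seed: int | None = None) -> PcaModel:
    """Fit PCA on a features-by-samples scaled matrix via SVD.

    The matrix must be centered per feature (guaranteed by scale_features).
    ``K`` is clamped to min(n_samples - 1, n_features) and truncated to the
    numerical rank with a warning if it exceeds it.  The full SVD solver is
    the default for determinism; ``randomized=True`` switches to the seeded
    randomized solver for large feature counts.  Signs follow the
    largest-|loading|-positive convention (see :func:`orient_signs`).
    """
    E = scaled_matrix.to_numpy().T  # samples x features
    n, p = E.shape
    if n < 2 or p < 1:
        raise ValueError("need at least 2 samples and 1 feature for PCA")
    K = int(min(K, n - 1, p))
    if randomized:
        from sklearn.utils.extmath import randomized_svd
        U, s, Vt = randomized_svd(E, n_components=K,
                                  random_state=None if seed is None else int(seed))
        total_var = float(np.sum(E ** 2))
    else:
        U, s, Vt = np.linalg.svd(E, full_matrices=False)
        total_var = float(np.sum(s ** 2))
    tol = s.max() * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if K > rank:
        warnings.warn(f"requested K={K} exceeds matrix rank {rank}; truncating")
        K = rank
    if K == 0:
        raise ValueError("scaled matrix has rank 0")
    L = Vt[:K].T                       # p x K
    S = E @ L                          # n x K == U * s on the kept PCs
    var_frac = (s[:K] ** 2) / total_var if total_var > 0 else np.zeros(K)
    model = PcaModel(
        loadings=pd.DataFrame(L, index=scaled_matrix.index,
                              columns=[f"PC_{k+1}" for k in range(K)]),
        scores=pd.DataFrame(S, index=scaled_matrix.columns,
                            columns=[f"PC_{k+1}" for k in range(K)]),
        variance_fraction=var_frac, K=K)
    model = orient_signs(model)
    model.check_invariants()
    return model


def reconstruct_scores(scaled_matrix: pd.DataFrame,
                       loadings: pd.DataFrame) -> pd.DataFrame:
    """Plain matrix product S = E x L (the decomposition oracle).

    No re-normalization is applied: an unnormalized loading column scales
    the scores accordingly.  Features are aligned by id; a mismatch between
    the matrix features and the loading rows is a hard error.
    """
    if not scaled_matrix.index.equals(loadings.index):
        if set(scaled_matrix.index) != set(loadings.index):
            raise ValueError("feature ids of matrix and loadings do not match")
        loadings = loadings.loc[scaled_matrix.index]
    S = scaled_matrix.to_numpy().T @ loadings.to_numpy()
    return pd.DataFrame(S, index=scaled_matrix.columns,
                        columns=loadings.columns)


def orient_signs(model: PcaModel) -> PcaModel:
    """Resolve PCA sign ambiguity deterministically.

    Each PC is flipped, if needed, so that its largest-|loading| entry is
    positive; ties in |loading| are broken by the lower feature index.  The
    scores flip consistently, preserving E x L = S.
    """
    L = model.loadings.to_numpy().copy()
    S = model.scores.to_numpy().copy()
    for k in range(model.K):
        anchor = int(np.argmax(np.abs(L[:, k])))  # argmax: lowest index wins ties
        if L[anchor, k] < 0:
            L[:, k] = -L[:, k]
            S[:, k] = -S[:, k]
    return PcaModel(
        loadings=pd.DataFrame(L, index=model.loadings.index,
                              columns=model.loadings.columns),
        scores=pd.DataFrame(S, index=model.scores.index,
                            columns=model.scores.columns),
        variance_fraction=model.variance_fraction, K=model.K)
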