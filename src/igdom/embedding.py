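"""One-hot encoding of alignments and PCA with group/property overlays.

Each alignment column becomes a 24-wide binary block (feature index =
column_index × 24 + symbol rank in the fixed alphabet order), so a
117-column alignment encodes to 117 × 24 = 2808 features.  PCA uses the
deterministic full SVD on the mean-centred matrix — no unit-variance
scaling, which on one-hot features would inflate rare symbols — with the
sign of each component fixed so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from igdom.alignment import Alignment
from igdom.alphabet import ALPHABET
from igdom.exceptions import InputError, ParameterError


@dataclass
class EncodedAlignment:
    """Binary sequences × (columns × 24) matrix with its symbol order."""

    matrix: np.ndarray
    symbol_order: tuple[str, ...]
    ids: list[str]
    n_columns: int

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PCAResult:
    """Scores, explained-variance ratios and loadings of a fitted PCA."""

    scores: np.ndarray
    variance_ratio: np.ndarray
    component_loadings: np.ndarray
    ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def one_hot_encode(a: Alignment) -> EncodedAlignment:
    """Encode an alignment as a binary matrix with 24-wide per-column blocks."""
    arr = a.to_array()  # ranks in ALPHABET order
    n, L = arr.shape
    K = len(ALPHABET)
    matrix = np.zeros((n, L * K), dtype=np.uint8)
    rows = np.repeat(np.arange(n), L)
    cols = (np.tile(np.arange(L), n).reshape(n, L) * K + arr).ravel()
    matrix[rows, cols] = 1
    return EncodedAlignment(matrix=matrix, symbol_order=ALPHABET, ids=list(a.ids), n_columns=L)


def decode(e: EncodedAlignment) -> list[str]:
    """Invert one_hot_encode; the encoding is a bijection on valid alignments."""
    K = len(e.symbol_order)
    ranks = e.matrix.reshape(len(e.ids), e.n_columns, K).argmax(axis=2)
    symbols = np.array(e.symbol_order)
    return ["".join(symbols[r]) for r in ranks]


def fit_pca(e: EncodedAlignment, k: int) -> PCAResult:
    """PCA of the encoded alignment by deterministic full SVD.

    Features are mean-centred only.  ``variance_ratio`` entries are
    σ_k²/Σσ² so they sum to 1 over the full rank min(n−1, p).  A
    zero-variance matrix yields all-zero ratios with a warning.
    """
    n, p = e.matrix.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 sequences")
    max_k = min(n - 1, p)
    if not 1 <= k <= max_k:
        raise ParameterError(f"k must be in 1..{max_k} for this matrix, got {k}")
    X = e.matrix.astype(float)
    if np.allclose(X.var(axis=0), 0.0):
        warnings.warn("zero-variance matrix: all variance ratios are 0", stacklevel=2)
        return PCAResult(
            scores=np.zeros((n, k)),
            variance_ratio=np.zeros(k),
            component_loadings=np.zeros((k, p)),
            ids=list(e.ids),
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # sign convention: largest-|loading| entry of each component is positive
    flip = np.sign(loadings[np.arange(k), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return PCAResult(
        scores=scores * flip,
        variance_ratio=pca.explained_variance_ratio_.copy(),
        component_loadings=loadings * flip[:, None],
        ids=list(e.ids),
    )


def overlay(
    p: PCAResult,
    values: Mapping[str, float] | pd.Series,
    groups: Optional[Mapping[str, str] | pd.Series] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-sequence values (a property or a label) onto PCA coordinates.

    Returns the join table (seq_id, PC coordinates, value[, group]) and the
    per-group centroid per component (one "all" group when no grouping is
    given). Every sequence id must have a value.
    """
    table = p.to_frame()
    vals = pd.Series(values)
    missing = [i for i in p.ids if i not in vals.index]
    if missing:
        raise InputError(f"overlay value missing for ids: {missing}")
    table["value"] = vals.loc[p.ids].to_numpy()
    if groups is not None:
        grp = pd.Series(groups)
        missing = [i for i in p.ids if i not in grp.index]
        if missing:
            raise InputError(f"group label missing for ids: {missing}")
        table["group"] = grp.loc[p.ids].to_numpy()
        centroids = table.groupby("group")[[f"PC{k+1}" for k in range(p.n_components)] + ["value"]].mean()
    else:
        centroids = table.mean(numeric_only=True).to_frame().T
        centroids.index = pd.Index(["all"], name="group")
    table.index.name = "seq_id"
    return table, centroids
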