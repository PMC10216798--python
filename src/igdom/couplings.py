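"""Evolutionary-coupling tables: ingestion, filtering, and an MI+APC scorer.

External pair tables (EVcouplings-style CSV with columns i, A_i, j, A_j,
score, probability) are ingested and filtered with the probability and
sequence-separation rules used for Ig constant-domain contact maps: pairs
kept when probability is *strictly* greater than the threshold (0.8 for
intradomain maps, 0.6 for interdomain candidates) and when |j − i| meets a
minimum separation (default 5, i.e. more than four residues apart).

For synthetic validation the module also scores an alignment internally
with mutual information plus the average-product correction (APC):

    MI_ij in bits from the (pseudocounted) joint column distribution,
    corrected_ij = MI_ij − MI_i·  MI_·j / MI_mean

where MI_i· is the mean coupling of column i to all other columns.  APC
removes the entropic bias that makes variable columns look coupled to
everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from igdom.alignment import Alignment
from igdom.alphabet import ALPHABET, GAP, SYMBOL_INDEX
from igdom.exceptions import FormatError, InputError

PAIR_COLUMNS = ["i", "j", "res_i", "res_j", "raw_score", "probability"]

_COLUMN_SYNONYMS = {
    "i": "i", "pos1": "i", "i_pos": "i",
    "j": "j", "pos2": "j", "j_pos": "j",
    "a_i": "res_i", "res_i": "res_i", "ai": "res_i",
    "a_j": "res_j", "res_j": "res_j", "aj": "res_j",
    "score": "raw_score", "cn": "raw_score", "raw_score": "raw_score",
    "probability": "probability", "prob": "probability", "score_prob": "probability",
}


@dataclass
class CouplingTable:
    """Scored residue pairs with i < j, unique per (i, j)."""

    pairs: pd.DataFrame
    numbering_space: str = "alignment"

    def __post_init__(self) -> None:
        df = self.pairs
        for col in PAIR_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("raw_score", "probability") else None
        self.pairs = df[PAIR_COLUMNS].reset_index(drop=True)
        if len(self.pairs):
            if not (self.pairs["i"] < self.pairs["j"]).all():
                raise InputError("pairs must satisfy i < j")
            if self.pairs.duplicated(subset=["i", "j"]).any():
                raise InputError("duplicate (i, j) pairs")
            prob = self.pairs["probability"].dropna()
            if ((prob < 0) | (prob > 1)).any():
                raise InputError("probabilities outside [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[int, int]]:
        return {(int(r.i), int(r.j)) for r in self.pairs.itertuples()}

    def top_k(self, k: int) -> "CouplingTable":
        df = self.pairs.sort_values("raw_score", ascending=False, kind="mergesort")
        return CouplingTable(df.head(k).copy(), self.numbering_space)

    def to_csv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, index=False)


def read_coupling_table(
    path: str | Path, numbering_space: str = "alignment"
) -> CouplingTable:
    """Read a scored-pair CSV, tolerating common header synonyms and delimiters.

    Pairs are normalised to i < j (swapping residues along); duplicate
    (i, j) rows collapse to the one with the highest probability (or score
    when no probability column exists).
    """
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        if Path(path).stat().st_size == 0:
            warnings.warn(f"empty coupling table {path}", stacklevel=2)
            return CouplingTable(pd.DataFrame(columns=PAIR_COLUMNS), numbering_space)
        if isinstance(exc, pd.errors.EmptyDataError):
            warnings.warn(f"empty coupling table {path}", stacklevel=2)
            return CouplingTable(pd.DataFrame(columns=PAIR_COLUMNS), numbering_space)
        raise FormatError(f"cannot sniff delimiter of {path}: {exc}") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    df = df.rename(columns={c: _COLUMN_SYNONYMS[c] for c in df.columns if c in _COLUMN_SYNONYMS})
    if "i" not in df.columns or "j" not in df.columns:
        raise FormatError(f"coupling table {path} lacks position columns (i/pos1, j/pos2)")
    if "probability" not in df.columns and "raw_score" not in df.columns:
        raise FormatError(f"coupling table {path} lacks a probability or score column")
    if len(df) == 0:
        warnings.warn(f"coupling table {path} has no rows", stacklevel=2)
        return CouplingTable(pd.DataFrame(columns=PAIR_COLUMNS), numbering_space)
    try:
        df["i"] = df["i"].astype(int)
        df["j"] = df["j"].astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric positions in {path}: {exc}") from None
    for col in ("res_i", "res_j"):
        if col not in df.columns:
            df[col] = None
    for col in ("raw_score", "probability"):
        if col not in df.columns:
            df[col] = np.nan

    swap = df["i"] > df["j"]
    if swap.any():
        df.loc[swap, ["i", "j"]] = df.loc[swap, ["j", "i"]].to_numpy()
        df.loc[swap, ["res_i", "res_j"]] = df.loc[swap, ["res_j", "res_i"]].to_numpy()
    if (df["i"] == df["j"]).any():
        raise FormatError(f"self-pairs (i == j) in {path}")

    sort_key = "probability" if df["probability"].notna().any() else "raw_score"
    df = (
        df.sort_values(sort_key, ascending=False, kind="mergesort")
        .drop_duplicates(subset=["i", "j"], keep="first")
        .sort_values(["i", "j"])
    )
    return CouplingTable(df[PAIR_COLUMNS].reset_index(drop=True), numbering_space)


def filter_couplings(
    t: CouplingTable, min_probability: float = 0.8, min_separation: int = 5
) -> CouplingTable:
    """Keep pairs with probability strictly above the threshold and j − i ≥ min_separation.

    A pair at exactly the probability threshold is dropped. Pass
    ``min_probability=None`` to filter on separation only (for internally
    scored tables that carry no probabilities).
    """
    df = t.pairs
    keep = (df["j"] - df["i"]) >= min_separation
    if min_probability is not None:
        keep &= df["probability"] > min_probability
    return CouplingTable(df[keep].copy(), t.numbering_space)


def mi_matrix(
    a: Alignment,
    pseudocount: float = 0.5,
    gap_mode: Literal["exclude", "state"] = "exclude",
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise mutual information (bits) and per-column entropies.

    ``pseudocount`` is added to every joint cell before normalising.  With
    ``gap_mode="exclude"`` only sequences non-gapped at both columns enter
    a pair's joint counts (gaps never act as a state); with ``"state"`` the
    gap is a 24th categorical state.  Per-column entropies come from the
    single-column counts smoothed consistently with the joints (K·pc per
    symbol), so MI_ij ≤ min(H_i, H_j) holds exactly on gap-free data.
    """
    if a.n_sequences < 2:
        raise InputError("MI needs at least 2 sequences")
    arr = a.to_array()
    n, L = arr.shape
    gap_rank = SYMBOL_INDEX[GAP]
    K = len(ALPHABET) if gap_mode == "state" else len(ALPHABET) - 1

    mi = np.zeros((L, L))
    nongap = arr != gap_rank
    for i in range(L):
        xi = arr[:, i]
        for j in range(i + 1, L):
            xj = arr[:, j]
            if gap_mode == "exclude":
                ok = nongap[:, i] & nongap[:, j]
                joint = np.bincount(xi[ok] * K + xj[ok], minlength=K * K)
            else:
                joint = np.bincount(xi * K + xj, minlength=K * K)
            joint = joint.astype(float) + pseudocount
            joint /= joint.sum()
            J = joint.reshape(K, K)
            pi, pj = J.sum(axis=1), J.sum(axis=0)
            hi = -np.sum(pi[pi > 0] * np.log2(pi[pi > 0]))
            hj = -np.sum(pj[pj > 0] * np.log2(pj[pj > 0]))
            hij = -np.sum(J[J > 0] * np.log2(J[J > 0]))
            mi[i, j] = mi[j, i] = max(hi + hj - hij, 0.0)

    entropies = np.zeros(L)
    for i in range(L):
        if gap_mode == "exclude":
            counts = np.bincount(arr[nongap[:, i], i], minlength=K)[:K]
        else:
            counts = np.bincount(arr[:, i], minlength=K)[:K]
        p = counts.astype(float) + pseudocount * K
        p /= p.sum()
        entropies[i] = -np.sum(p[p > 0] * np.log2(p[p > 0]))
    return mi, entropies


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric coupling matrix.

    corrected_ij = MI_ij − MI_i· MI_·j / MI_mean, with row means and the
    grand mean taken over off-diagonal entries.  A constant MI matrix
    corrects to exactly zero everywhere.
    """
    L = mi.shape[0]
    if L < 2:
        raise InputError("APC needs at least 2 columns")
    off = ~np.eye(L, dtype=bool)
    grand = mi[off].mean()
    if grand == 0:
        warnings.warn("all-zero MI matrix: APC leaves it unchanged", stacklevel=2)
        return mi.copy()
    row_mean = mi.sum(axis=1) / (L - 1)
    corrected = mi - np.outer(row_mean, row_mean) / grand
    np.fill_diagonal(corrected, 0.0)
    return corrected


def mi_apc_scores(
    a: Alignment,
    pseudocount: float = 0.5,
    gap_mode: Literal["exclude", "state"] = "exclude",
) -> CouplingTable:
    """Score all column pairs of an alignment with APC-corrected MI.

    Positions in the returned table are 1-based alignment positions (via
    the column map); probabilities are left empty — this scorer ranks pairs
    but does not calibrate contact probabilities.
    """
    mi = mi_matrix(a, pseudocount=pseudocount, gap_mode=gap_mode)[0]
    if np.allclose(mi, 0.0):
        warnings.warn("constant alignment: all coupling scores are 0", stacklevel=2)
        corrected = mi
    else:
        corrected = apc_correct(mi)
    positions = a.positions()
    L = a.n_columns
    iu, ju = np.triu_indices(L, k=1)
    df = pd.DataFrame(
        {
            "i": [positions[x] for x in iu],
            "j": [positions[x] for x in ju],
            "res_i": None,
            "res_j": None,
            "raw_score": corrected[iu, ju],
            "probability": np.nan,
        }
    )
    return CouplingTable(df, numbering_space="alignment")
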