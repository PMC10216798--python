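"""Per-column conservation scoring by Jensen–Shannon divergence.

Each column's residue distribution (gaps excluded, ambiguity codes
redistributed over their member amino acids) is compared against a
background amino-acid distribution with the generalized Jensen–Shannon
divergence in bits, penalised by the column's gap fraction and optionally
smoothed over a sequence window.  With the default mixing weight 1/2 the
divergence is bounded by 1 bit, so scores live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from igdom.alignment import Alignment
from igdom.alphabet import AA_INDEX, AMBIGUITY_MEMBERS, AMINO_ACIDS, GAP
from igdom.exceptions import InputError, ParameterError

# BLOSUM62 amino-acid background frequencies (the canonical background for
# JSD conservation scoring), re-ordered to this package's alphabetical
# amino-acid order and renormalised to sum exactly to 1.
_BLOSUM62 = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}

BACKGROUNDS: dict[str, np.ndarray] = {
    "blosum62": np.array([_BLOSUM62[a] for a in AMINO_ACIDS]),
    "uniform": np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS)),
}
BACKGROUNDS["blosum62"] /= BACKGROUNDS["blosum62"].sum()


@dataclass
class ConservationProfile:
    """Per-column conservation scores in [0, 1] with their gap fractions."""

    scores: np.ndarray
    gap_fractions: np.ndarray
    params: dict

    def __len__(self) -> int:
        return len(self.scores)


def _check_distribution(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise InputError(f"{name} must be a 1-D probability vector")
    if (v < 0).any():
        raise InputError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-9:
        raise InputError(f"{name} does not sum to 1 (sum={v.sum():.12f})")
    return v


def _kl_bits(p: np.ndarray, r: np.ndarray) -> float:
    # 0·log 0 := 0; r_k = 0 implies p_k = 0 for a mixture component
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / r[mask])))


def jsd_divergence(p: np.ndarray, q: np.ndarray, lambda_mix: float = 0.5) -> float:
    """Generalized Jensen–Shannon divergence in bits.

    JS_λ(p, q) = λ·KL(p‖r) + (1−λ)·KL(q‖r) with r = λp + (1−λ)q,
    logarithms base 2.  Symmetric in (p, q) at λ = 1/2, zero iff p = q,
    and bounded by the binary entropy of λ (hence by 1 bit).
    """
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    if not 0 < lambda_mix < 1:
        raise InputError(f"lambda_mix must be in (0, 1), got {lambda_mix}")
    if p.shape != q.shape:
        raise InputError("p and q have different lengths")
    r = lambda_mix * p + (1 - lambda_mix) * q
    return lambda_mix * _kl_bits(p, r) + (1 - lambda_mix) * _kl_bits(q, r)


def column_aa_distribution(column: str) -> tuple[np.ndarray, float]:
    """Amino-acid distribution of one column, with its gap fraction.

    Gaps are excluded from the distribution (counted separately); each
    ambiguity code contributes equal fractional weight to its member
    amino acids (B → N,D; Z → Q,E; X → all twenty). An all-gap column
    returns a zero vector.
    """
    n = len(column)
    weights = np.zeros(len(AMINO_ACIDS))
    gaps = 0
    for s in column:
        if s == GAP:
            gaps += 1
        elif s in AA_INDEX:
            weights[AA_INDEX[s]] += 1.0
        else:
            members = AMBIGUITY_MEMBERS[s]
            for m in members:
                weights[AA_INDEX[m]] += 1.0 / len(members)
    total = weights.sum()
    if total > 0:
        weights /= total
    return weights, gaps / n


def conservation_profile(
    a: Alignment,
    background: str | np.ndarray = "blosum62",
    window_half_width: int = 3,
    window_weight: float = 0.5,
    lambda_mix: float = 0.5,
) -> ConservationProfile:
    """Score every column of an alignment.

    Per column c the base score is ``jsd(column distribution, background)
    × (1 − gap_fraction_c)``; all-gap columns score 0.  With a positive
    ``window_half_width`` the final score mixes the base score with the
    mean base score of the flanking columns (excluding c itself):
    ``(1 − w)·base_c + w·mean(neighbours)``, w = ``window_weight``.
    """
    if isinstance(background, str):
        try:
            bg = BACKGROUNDS[background]
        except KeyError:
            raise ParameterError(f"unknown background {background!r}") from None
        bg_name = background
    else:
        bg = _check_distribution(np.asarray(background, dtype=float), "background")
        bg_name = "custom"
    if window_half_width < 0:
        raise ParameterError("window_half_width must be >= 0")
    if window_half_width >= a.n_columns:
        raise ParameterError(
            f"window half-width {window_half_width} spans more than the "
            f"{a.n_columns}-column alignment"
        )

    n_col = a.n_columns
    base = np.zeros(n_col)
    gap_fractions = np.zeros(n_col)
    for c in range(n_col):
        dist, gap_frac = column_aa_distribution(a.column(c))
        gap_fractions[c] = gap_frac
        if dist.sum() == 0:  # all-gap column
            base[c] = 0.0
            continue
        base[c] = jsd_divergence(dist, bg, lambda_mix) * (1.0 - gap_frac)

    if window_half_width == 0 or window_weight == 0:
        scores = base
    else:
        scores = np.empty(n_col)
        w = window_weight
        for c in range(n_col):
            lo = max(0, c - window_half_width)
            hi = min(n_col, c + window_half_width + 1)
            neighbours = np.concatenate([base[lo:c], base[c + 1 : hi]])
            smoothed = neighbours.mean() if neighbours.size else base[c]
            scores[c] = (1 - w) * base[c] + w * smoothed

    return ConservationProfile(
        scores=scores,
        gap_fractions=gap_fractions,
        params={
            "background_name": bg_name,
            "lambda_mix": lambda_mix,
            "window_half_width": window_half_width,
            "window_weight": window_weight,
        },
    )
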