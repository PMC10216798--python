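"""Residue biophysical property scales and grouped profiles.

Three scales are shipped:

- **hydrophobicity** — the experimentally derived Wimley–White free
  energies of transfer (kcal/mol).  Both the water→POPC-interface and the
  water→octanol variants are packaged; the interface scale is the default
  and the choice is recorded in output metadata.
- **volume** — the normalized van der Waals volume per residue.
- **charge** — an unsigned presence-of-net-charge indicator: 1 for Asp,
  Glu, Arg and Lys, 0 for every other residue (His counts as uncharged).

Ambiguity codes are averaged over their member residues (B = mean(N, D),
Z = mean(Q, E), X = mean of all twenty); gaps carry no value.  Profiles
aggregate these values per position, per secondary-structure element and
per group (isotype or animal class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from igdom.alignment import Alignment, FrequencyMatrix, LabeledAlignment, column_frequencies
from igdom.alphabet import AMBIGUITY_MEMBERS, AMINO_ACIDS, GAP
from igdom.exceptions import AlphabetError, FormatError, InputError, ParameterError

# Wimley & White water -> POPC-interface transfer free energies, kcal/mol.
WIMLEY_WHITE_INTERFACE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

# Wimley & White water -> n-octanol transfer free energies, kcal/mol.
WIMLEY_WHITE_OCTANOL = {
    "A": 0.50, "R": 1.81, "N": 0.85, "D": 3.64, "C": -0.02,
    "Q": 0.77, "E": 3.63, "G": 1.15, "H": 2.33, "I": -1.12,
    "L": -1.25, "K": 2.80, "M": -0.67, "F": -1.71, "P": 0.14,
    "S": 0.46, "T": 0.25, "W": -2.09, "Y": -0.71, "V": -0.46,
}

# Normalized van der Waals volume.
VDW_VOLUME_NORMALIZED = {
    "A": 1.00, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43,
    "Q": 3.95, "E": 3.78, "G": 0.00, "H": 4.66, "I": 4.00,
    "L": 4.00, "K": 4.77, "M": 4.43, "F": 5.89, "P": 2.72,
    "S": 1.60, "T": 2.60, "W": 8.08, "Y": 6.47, "V": 3.00,
}

CHARGED_RESIDUES = frozenset("DERK")
CHARGE_INDICATOR = {a: (1.0 if a in CHARGED_RESIDUES else 0.0) for a in AMINO_ACIDS}

#: Sequence-logo "chemistry" colour classes; the five classes partition
#: the twenty amino acids.
CHEMISTRY_CLASSES: dict[str, str] = {
    "apolar": "AIFLMPVW",
    "polar": "CGSTY",
    "amide": "QN",
    "acidic": "DE",
    "basic": "RKH",
}


@dataclass(frozen=True)
class PropertyScale:
    """A residue → value mapping with ambiguity-code averaging."""

    name: str
    values: dict

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise InputError(f"scale {self.name!r} lacks residues: {sorted(missing)}")

    def __getitem__(self, symbol: str) -> float:
        return residue_property(symbol, self)


SCALES: dict[str, PropertyScale] = {
    "hydrophobicity": PropertyScale("hydrophobicity", WIMLEY_WHITE_INTERFACE),
    "hydrophobicity_octanol": PropertyScale("hydrophobicity_octanol", WIMLEY_WHITE_OCTANOL),
    "volume": PropertyScale("volume", VDW_VOLUME_NORMALIZED),
    "charge": PropertyScale("charge", CHARGE_INDICATOR),
}


def read_scale(path: str | Path, name: str = "custom") -> PropertyScale:
    """Load a user scale from a two-column (residue, value) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["residue", "value"], comment="#")
    return PropertyScale(name, dict(zip(df["residue"].str.upper(), df["value"].astype(float))))


def residue_property(symbol: str, scale: PropertyScale) -> float:
    """Value of one alignment symbol under a scale.

    B, Z and X average their member residues' values; the gap has no value.
    """
    if symbol == GAP:
        raise InputError("gap has no property value")
    if symbol in scale.values:
        return float(scale.values[symbol])
    if symbol in AMBIGUITY_MEMBERS:
        members = AMBIGUITY_MEMBERS[symbol]
        return float(np.mean([scale.values[m] for m in members]))
    raise AlphabetError(f"unknown symbol {symbol!r}")


def sequence_normalized_property(row: str, scale: PropertyScale) -> float:
    """Mean property over the non-gap positions of one aligned sequence."""
    vals = [residue_property(s, scale) for s in row if s != GAP]
    if not vals:
        raise InputError("all-gap sequence has no normalized property")
    return float(np.mean(vals))


@dataclass
class GroupPropertyMatrix:
    """Per-group, per-column mean property with its support.

    ``values[g, c]`` is the mean property over non-gap residues of group g
    at column c; undefined (support 0) entries are NaN and flagged.
    ``positions`` are the columns' 1-based positions.
    """

    groups: list[str]
    values: np.ndarray
    support: np.ndarray
    positions: list[int]
    scale_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.groups, columns=self.positions)


def group_position_profile(
    a: LabeledAlignment,
    scale: PropertyScale,
    group_by: str = "isotype",
    groups: Optional[list[str]] = None,
) -> GroupPropertyMatrix:
    """Average a property per group at each alignment column."""
    labels = a.groups(group_by)
    if groups is None:
        groups = sorted(labels.unique())
    aln = a.alignment
    n_col = aln.n_columns
    values = np.full((len(groups), n_col), np.nan)
    support = np.zeros((len(groups), n_col), dtype=np.int64)
    row_by_id = dict(zip(aln.ids, aln.rows))
    for g, group in enumerate(groups):
        members = [row_by_id[i] for i in labels.index[labels == group]]
        if not members:
            warnings.warn(f"group {group!r} has no sequences; row flagged", stacklevel=2)
            continue
        for c in range(n_col):
            vals = [residue_property(row[c], scale) for row in members if row[c] != GAP]
            support[g, c] = len(vals)
            if vals:
                values[g, c] = float(np.mean(vals))
    return GroupPropertyMatrix(
        groups=list(groups),
        values=values,
        support=support,
        positions=aln.positions(),
        scale_name=scale.name,
    )


@dataclass(frozen=True)
class SSEElement:
    """One secondary-structure element as a closed 1-based column interval."""

    label: str
    start_col: int
    end_col: int
    orientation: str = "unknown"


ORIENTATION_TAGS = ("interface", "solvent", "intra-sheet", "toward-CH2", "toward-V", "unknown")


@dataclass
class SSEAnnotation:
    """Ordered, non-overlapping secondary-structure intervals."""

    elements: list[SSEElement]

    def __post_init__(self) -> None:
        spans = sorted((e.start_col, e.end_col, e.label) for e in self.elements)
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise InputError(f"overlapping elements {l1!r} and {l2!r}")
        for e in self.elements:
            if e.start_col < 1 or e.end_col < e.start_col:
                raise InputError(f"bad interval for element {e.label!r}")
            if e.orientation not in ORIENTATION_TAGS:
                raise InputError(f"unknown orientation {e.orientation!r}")


def read_sse_annotation(path: str | Path) -> SSEAnnotation:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"SSE TSV needs columns {sorted(required)}")
    elements = [
        SSEElement(
            label=str(r["label"]),
            start_col=int(r["start"]),
            end_col=int(r["end"]),
            orientation=str(r["orientation"]) if "orientation" in df.columns else "unknown",
        )
        for _, r in df.iterrows()
    ]
    return SSEAnnotation(elements)


def group_sse_profile(m: GroupPropertyMatrix, sse: SSEAnnotation) -> pd.DataFrame:
    """Support-weighted mean property per group over each SSE's columns.

    Undefined columns are skipped; an element with zero total support in a
    group is flagged NaN.
    """
    pos_to_idx = {p: i for i, p in enumerate(m.positions)}
    out = pd.DataFrame(np.nan, index=m.groups, columns=[e.label for e in sse.elements])
    for e in sse.elements:
        cols = [pos_to_idx[p] for p in range(e.start_col, e.end_col + 1) if p in pos_to_idx]
        if not cols:
            raise ParameterError(f"element {e.label!r} lies outside the profiled columns")
        vals = m.values[:, cols]
        sup = m.support[:, cols].astype(float)
        sup[np.isnan(vals)] = 0.0
        total = sup.sum(axis=1)
        weighted = np.nansum(vals * sup, axis=1)
        with np.errstate(invalid="ignore"):
            out[e.label] = np.where(total > 0, weighted / np.where(total > 0, total, 1), np.nan)
    return out


def logo_matrix(a: Alignment) -> tuple[FrequencyMatrix, dict[str, str]]:
    """Plot-ready logo table: gap-excluded column frequencies + chemistry classes."""
    return column_frequencies(a, include_gaps=False), dict(CHEMISTRY_CLASSES)


def coupled_pair_composition(
    a: LabeledAlignment,
    i: int,
    j: int,
    min_fraction: float = 0.02,
    group_by: str = "animal_class",
) -> pd.DataFrame:
    """Residue-pair occupancy at two coupled columns, per group.

    ``i`` and ``j`` are 1-based positions.  For each group, the fraction of
    that group's sequences carrying each ordered (res_i, res_j) pair is
    reported; pairs at a fraction <= ``min_fraction`` are dropped (strictly
    "more than" semantics, so a pair at exactly the threshold is excluded).
    Sequences gapped at either column stay in the denominator but
    contribute no pair.
    """
    aln = a.alignment
    if i == j:
        raise InputError("i and j must differ")
    for pos in (i, j):
        if not 1 <= pos <= aln.n_columns:
            raise InputError(f"position {pos} outside 1..{aln.n_columns}")
    labels = a.groups(group_by)
    row_by_id = dict(zip(aln.ids, aln.rows))
    records = []
    for group in sorted(labels.unique()):
        ids = labels.index[labels == group]
        n_total = len(ids)
        if n_total == 0:
            warnings.warn(f"group {group!r} has no sequences", stacklevel=2)
            continue
        counts: dict[tuple[str, str], int] = {}
        for seq_id in ids:
            row = row_by_id[seq_id]
            ri, rj = row[i - 1], row[j - 1]
            if ri == GAP or rj == GAP:
                continue
            counts[(ri, rj)] = counts.get((ri, rj), 0) + 1
        for (ri, rj), n in sorted(counts.items(), key=lambda kv: -kv[1]):
            fraction = n / n_total
            if fraction > min_fraction:
                records.append(
                    {"group": group, "res_i": ri, "res_j": rj, "fraction": fraction}
                )
    return pd.DataFrame(records, columns=["group", "res_i", "res_j", "fraction"])
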