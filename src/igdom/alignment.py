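"""Alignment containers, loading, gap-column trimming and deduplication.

Owns the numbering conventions: columns are indexed 0-based internally but
every reported position is 1-based (the 1..117 convention used for Ig
constant-domain alignments); the optional ``column_map`` carries, per
surviving column, its original 1-based position plus optional reference-PDB
and IMGT labels loaded from a translation table (never computed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from igdom.alphabet import ALPHABET, ALPHABET_SET, GAP, SYMBOL_INDEX
from igdom.exceptions import (
    AlphabetError,
    FormatError,
    InputError,
    MetadataError,
)

DOMAIN_KINDS = ("CH1", "CH2", "CH3", "CH4", "CL", "V")


@dataclass(frozen=True)
class ColumnRecord:
    """Numbering record for one alignment column.

    ``position`` is the 1-based position in the original (untrimmed)
    alignment; ``pdb_number`` / ``imgt_label`` are optional external labels.
    """

    position: int
    pdb_number: Optional[int] = None
    imgt_label: Optional[str] = None


@dataclass
class Alignment:
    """A multiple sequence alignment over the 24-symbol alphabet."""

    ids: list[str]
    rows: list[str]
    column_map: list[ColumnRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        length = lengths.pop()
        if length == 0:
            raise InputError("alignment has zero columns")
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        bad = {s for row in self.rows for s in row} - ALPHABET_SET
        if bad:
            raise AlphabetError(f"symbols outside alphabet: {sorted(bad)}")
        if not self.column_map:
            self.column_map = [ColumnRecord(c + 1) for c in range(length)]
        elif len(self.column_map) != length:
            raise FormatError("column_map length does not match alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def positions(self) -> list[int]:
        """1-based original positions of the current columns."""
        return [c.position for c in self.column_map]

    def to_array(self) -> np.ndarray:
        """Integer-coded (n_sequences, n_columns) matrix over ALPHABET ranks."""
        flat = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int8)
        for s, i in SYMBOL_INDEX.items():
            lut[ord(s)] = i
        return lut[flat].reshape(self.n_sequences, self.n_columns).astype(np.int64)

    def gap_fractions(self) -> np.ndarray:
        arr = self.to_array()
        return (arr == SYMBOL_INDEX[GAP]).mean(axis=0)

    def column(self, c: int) -> str:
        """Column ``c`` (0-based) as a string of length n_sequences."""
        return "".join(row[c] for row in self.rows)


@dataclass
class LabeledAlignment:
    """Alignment plus per-sequence (isotype, animal_class, domain_kind) labels."""

    alignment: Alignment
    labels: pd.DataFrame  # indexed by id: isotype, animal_class, domain_kind

    def __post_init__(self) -> None:
        missing = [i for i in self.alignment.ids if i not in self.labels.index]
        if missing:
            raise MetadataError(f"metadata missing for ids: {missing}")

    def label_of(self, seq_id: str) -> pd.Series:
        return self.labels.loc[seq_id]

    def groups(self, by: str) -> pd.Series:
        """Group label per sequence, in alignment row order."""
        if by not in ("isotype", "animal_class", "domain_kind"):
            raise MetadataError(f"unknown grouping column {by!r}")
        return self.labels.loc[self.alignment.ids, by]


@dataclass
class FrequencyMatrix:
    """Per-column relative symbol frequencies.

    ``values`` is (n_columns, n_symbols) over ``symbols``; ``counts_basis``
    is the number of sequences counted per column.  When gaps are excluded
    the per-column gap fraction is kept in ``gap_fractions`` and columns
    that were entirely gaps are flagged ``undefined`` (their value row is
    NaN, never silently zero).
    """

    values: np.ndarray
    symbols: tuple[str, ...]
    counts_basis: np.ndarray
    gap_fractions: Optional[np.ndarray] = None
    undefined: Optional[np.ndarray] = None

    def to_frame(self, positions: Optional[Iterable[int]] = None) -> pd.DataFrame:
        idx = list(positions) if positions is not None else range(1, len(self.values) + 1)
        return pd.DataFrame(self.values, index=idx, columns=list(self.symbols))


def _clean_sequence(seq_id: str, seq: str) -> str:
    seq = seq.upper().replace(".", GAP)
    if "*" in seq:
        raise AlphabetError(f"sequence {seq_id!r} contains '*'")
    bad = set(seq) - ALPHABET_SET
    if bad:
        raise AlphabetError(f"sequence {seq_id!r} has symbols outside alphabet: {sorted(bad)}")
    return seq


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file. Case-insensitive; ``.`` read as gap, ``*`` rejected."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_clean_sequence(rec.id, str(rec.seq)))
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(ids=ids, rows=rows)


def write_fasta_alignment(a: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(a.ids, a.rows):
            fh.write(f">{seq_id}\n{row}\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "isotype", "animal_class", "domain_kind"}
    missing = required - set(meta.columns)
    if missing:
        raise MetadataError(f"metadata TSV lacks columns: {sorted(missing)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise MetadataError(f"duplicate metadata ids: {dupes}")
    return meta.set_index("id")


def read_numbering_map(path: str | Path) -> list[ColumnRecord]:
    """Load an (alignment_pos, pdb_num, imgt_label) translation TSV."""
    df = pd.read_csv(path, sep="\t")
    if "alignment_pos" not in df.columns:
        raise FormatError("numbering map needs an 'alignment_pos' column")
    records = []
    for _, r in df.iterrows():
        pdb = r.get("pdb_num")
        records.append(
            ColumnRecord(
                position=int(r["alignment_pos"]),
                pdb_number=None if pd.isna(pdb) else int(pdb),
                imgt_label=None if pd.isna(r.get("imgt_label")) else str(r["imgt_label"]),
            )
        )
    return records


def load_dataset(alignment_path: str | Path, metadata_path: str | Path) -> LabeledAlignment:
    """Read an aligned FASTA plus its metadata TSV into a LabeledAlignment."""
    return LabeledAlignment(read_fasta_alignment(alignment_path), read_metadata(metadata_path))


def filter_gap_columns(
    a: Alignment, max_gap_fraction: float = 0.8
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction reaches ``max_gap_fraction``.

    A column is removed iff gap_count / n_sequences >= max_gap_fraction
    (closed bound: at the default 0.8, a column gapped in exactly 80% of
    sequences is removed). Returns the trimmed alignment and the removed
    columns as 1-based positions in the original coordinates carried by
    the column map.
    """
    if not 0 < max_gap_fraction <= 1:
        raise InputError(f"max_gap_fraction must be in (0, 1], got {max_gap_fraction}")
    gap_frac = a.gap_fractions()
    keep = gap_frac < max_gap_fraction
    removed = [a.column_map[c].position for c in np.flatnonzero(~keep)]
    if keep.all():
        return replace(a, ids=list(a.ids), rows=list(a.rows), column_map=list(a.column_map)), []
    if not keep.any():
        raise InputError("every column exceeds the gap threshold; nothing left")
    kept_idx = np.flatnonzero(keep)
    rows = ["".join(row[c] for c in kept_idx) for row in a.rows]
    column_map = [a.column_map[c] for c in kept_idx]
    return Alignment(ids=list(a.ids), rows=rows, column_map=column_map), removed


def deduplicate(a: LabeledAlignment) -> LabeledAlignment:
    """Collapse identical rows within each (domain_kind, isotype, animal_class) subset.

    Row strings are compared verbatim (no gap- or case-normalisation; input
    is already upper-cased). The first-seen id in each subset survives.
    Identical rows in different subsets are untouched.
    """
    seen: set[tuple[str, str, str, str]] = set()
    keep_ids, keep_rows = [], []
    for seq_id, row in zip(a.alignment.ids, a.alignment.rows):
        lab = a.labels.loc[seq_id]
        key = (lab["domain_kind"], lab["isotype"], lab["animal_class"], row)
        if key in seen:
            continue
        seen.add(key)
        keep_ids.append(seq_id)
        keep_rows.append(row)
    aln = Alignment(ids=keep_ids, rows=keep_rows, column_map=list(a.alignment.column_map))
    return LabeledAlignment(aln, a.labels.loc[keep_ids])


def column_frequencies(a: Alignment, include_gaps: bool = True) -> FrequencyMatrix:
    """Relative symbol frequency per column.

    With ``include_gaps=False`` the gap is dropped from the symbol axis,
    frequencies are renormalised over non-gap symbols, and the per-column
    gap fraction is reported separately; all-gap columns are flagged
    undefined rather than returning a silent NaN row.
    """
    arr = a.to_array()
    n_seq, n_col = arr.shape
    n_sym = len(ALPHABET)
    counts = np.zeros((n_col, n_sym), dtype=np.int64)
    for c in range(n_col):
        counts[c] = np.bincount(arr[:, c], minlength=n_sym)
    if include_gaps:
        values = counts / n_seq
        return FrequencyMatrix(
            values=values,
            symbols=ALPHABET,
            counts_basis=np.full(n_col, n_seq, dtype=np.int64),
        )
    gap_idx = SYMBOL_INDEX[GAP]
    gap_fractions = counts[:, gap_idx] / n_seq
    nongap = np.delete(counts, gap_idx, axis=1)
    basis = nongap.sum(axis=1)
    undefined = basis == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} all-gap column(s) have undefined frequencies",
            stacklevel=2,
        )
    values = np.full(nongap.shape, np.nan)
    ok = ~undefined
    values[ok] = nongap[ok] / basis[ok, None]
    return FrequencyMatrix(
        values=values,
        symbols=ALPHABET[:-1],
        counts_basis=basis,
        gap_fractions=gap_fractions,
        undefined=undefined,
    )
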