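"""Reference structures, minimum-atom-distance contacts, and coupled-pair
classification.

Two residues are *in contact* when the minimum distance over their (heavy,
by default) atom pairs is at or below the cutoff, 5.0 Å by default.  A
coupled pair (i, j), read in the monomer chain's author numbering, is
classified with the precedence

    intra_contact > inter_mutual > inter_shared_partner > unexplained:

- **intra_contact** — i and j touch within the monomer chain;
- **inter_mutual** — i on the monomer chain touches j on the partner
  chain, or vice versa (the pair explains itself across the dimer
  interface);
- **inter_shared_partner** — some partner-chain residue k touches both i
  and j (coevolution through a common interface partner);
- **unexplained** — none of the above.

A pair referencing a residue absent from the structure is flagged
``unmapped`` and excluded from the fraction denominator, never silently
dropped.  Interaction types are a deliberately simplified geometric typing
(no angular criteria, hydrogens absent), tagged "simplified-typing" in
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from igdom.couplings import CouplingTable
from igdom.exceptions import FormatError, InputError, SelectionError

CATEGORIES = ("intra_contact", "inter_mutual", "inter_shared_partner", "unexplained")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
ACIDIC = frozenset({"ASP", "GLU"})
BASIC = frozenset({"ARG", "LYS", "HIS"})
AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def coords(self, atom_subset: str = "heavy") -> np.ndarray:
        if atom_subset == "heavy":
            pts = [a.xyz for a in self.atoms if a.element.upper() != "H"]
        else:
            pts = [a.xyz for a in self.atoms]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class Chain:
    label: str
    residues: list[Residue] = field(default_factory=list)

    def get(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class StructureModel:
    chains: dict[str, Chain]

    def chain(self, label: str) -> Chain:
        if label not in self.chains:
            raise SelectionError(
                f"chain {label!r} not in structure (has {sorted(self.chains)})"
            )
        return self.chains[label]

    def residue(self, chain: str, number: int) -> Residue:
        res = self.chain(chain).get(number)
        if res is None:
            raise SelectionError(f"residue {number} not in chain {chain!r}")
        return res


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoff (Å) and atom subset for contact definitions."""

    cutoff_A: float = 5.0
    atom_subset: str = "heavy"

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise InputError("cutoff must be positive")
        if self.atom_subset not in ("heavy", "all"):
            raise InputError("atom_subset must be 'heavy' or 'all'")


def read_structure(path: str | Path, chains: Optional[Sequence[str]] = None) -> StructureModel:
    """Read a PDB-format file into a StructureModel.

    Takes the first model; waters and heteroatoms are excluded; alternate
    locations resolve to the highest-occupancy conformer per atom name
    (ties to the first seen).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    model = st[0]
    available = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise SelectionError(f"chain(s) {missing} not in {path} (has {available})")
    out: dict[str, Chain] = {}
    for ch in model:
        if chains is not None and ch.name not in chains:
            continue
        chain = Chain(ch.name)
        for res in ch:
            if res.is_water():
                continue
            if res.het_flag == "H":
                # keep amino acids even when written as HETATM (e.g. short
                # synthetic chains); drop true ligands
                info = gemmi.find_tabulated_residue(res.name)
                if info is None or not info.is_amino_acid():
                    continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    xyz=np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in best.values()
            ]
            if atoms:
                chain.residues.append(
                    Residue(
                        number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=atoms,
                    )
                )
        if chain.residues:
            out[chain.label] = chain
    if not any(c.residues for c in out.values()):
        raise FormatError(f"no atoms read from {path}")
    return StructureModel(out)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a minimal PDB-format file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "igdom"
    gm = gemmi.Model("1")
    for chain in model.chains.values():
        gc = gemmi.Chain(chain.label)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def residue_min_distance(
    model: StructureModel,
    resA: tuple[str, int],
    resB: tuple[str, int],
    params: ContactParams = ContactParams(),
) -> float:
    """Minimum atom-pair distance (Å) between two residues."""
    a = model.residue(*resA).coords(params.atom_subset)
    b = model.residue(*resB).coords(params.atom_subset)
    if a.size == 0 or b.size == 0:
        raise InputError(f"residue without {params.atom_subset} atoms in pair {resA}/{resB}")
    return float(cdist(a, b).min())


def _min_distance_matrix(
    chain_a: Chain, chain_b: Chain, params: ContactParams
) -> tuple[np.ndarray, dict[int, int], dict[int, int]]:
    """Residue-by-residue min-distance matrix plus number→row index maps."""
    coords_a = [r.coords(params.atom_subset) for r in chain_a.residues]
    coords_b = [r.coords(params.atom_subset) for r in chain_b.residues]
    pts_a = np.concatenate([c for c in coords_a if len(c)]) if coords_a else np.empty((0, 3))
    pts_b = np.concatenate([c for c in coords_b if len(c)]) if coords_b else np.empty((0, 3))
    owner_a = np.repeat(np.arange(len(coords_a)), [len(c) for c in coords_a])
    owner_b = np.repeat(np.arange(len(coords_b)), [len(c) for c in coords_b])
    dmat = np.full((len(coords_a), len(coords_b)), np.inf)
    if len(pts_a) and len(pts_b):
        d = cdist(pts_a, pts_b)
        np.minimum.at(dmat, (owner_a[:, None], owner_b[None, :]), d)
    idx_a = {r.number: k for k, r in enumerate(chain_a.residues)}
    idx_b = {r.number: k for k, r in enumerate(chain_b.residues)}
    return dmat, idx_a, idx_b


@dataclass
class PairClassification:
    """Per-pair categories with supporting distances, plus the intra fraction."""

    table: pd.DataFrame  # i, j, category, min_dist_intra, min_dist_inter, partner_residue
    fraction_intra: float
    n_mapped: int
    n_unmapped: int

    def counts(self) -> dict[str, int]:
        mapped = self.table[self.table["category"] != "unmapped"]
        return {c: int((mapped["category"] == c).sum()) for c in CATEGORIES}


def classify_coupled_pairs(
    t: CouplingTable,
    model: StructureModel,
    monomer_chain: str,
    partner_chain: Optional[str] = None,
    params: ContactParams = ContactParams(),
    position_map: Optional[dict[int, int]] = None,
) -> PairClassification:
    """Classify every coupled pair against the reference structure.

    ``position_map`` translates table positions into the structure's author
    numbering (identity if omitted) — built from the alignment column map
    when the table lives in alignment coordinates.  Without a partner
    chain the two interdomain categories are disabled and non-intra pairs
    fall through to unexplained.
    """
    chain_a = model.chain(monomer_chain)
    chain_b = model.chain(partner_chain) if partner_chain is not None else None
    d_aa, idx_a, _ = _min_distance_matrix(chain_a, chain_a, params)
    if chain_b is not None:
        d_ab, _, idx_b = _min_distance_matrix(chain_a, chain_b, params)
    rows = []
    n_intra = 0
    n_unmapped = 0
    for rec in t.pairs.itertuples():
        i, j = int(rec.i), int(rec.j)
        si = position_map.get(i, None) if position_map is not None else i
        sj = position_map.get(j, None) if position_map is not None else j
        if si is None or sj is None or si not in idx_a or sj not in idx_a:
            n_unmapped += 1
            rows.append(
                {"i": i, "j": j, "category": "unmapped", "min_dist_intra": np.nan,
                 "min_dist_inter": np.nan, "partner_residue": None}
            )
            continue
        ka, kb = idx_a[si], idx_a[sj]
        d_intra = d_aa[ka, kb]
        category = None
        d_inter = np.nan
        partner = None
        if d_intra <= params.cutoff_A:
            category = "intra_contact"
            n_intra += 1
        elif chain_b is not None:
            d_ij = d_ab[ka, idx_b[sj]] if sj in idx_b else np.inf
            d_ji = d_ab[kb, idx_b[si]] if si in idx_b else np.inf
            if min(d_ij, d_ji) <= params.cutoff_A:
                category = "inter_mutual"
                d_inter = float(min(d_ij, d_ji))
            else:
                both = np.maximum(d_ab[ka], d_ab[kb])
                k_best = int(both.argmin())
                if both[k_best] <= params.cutoff_A:
                    category = "inter_shared_partner"
                    d_inter = float(both[k_best])
                    partner = chain_b.residues[k_best].number
        if category is None:
            category = "unexplained"
        rows.append(
            {"i": i, "j": j, "category": category,
             "min_dist_intra": float(d_intra) if np.isfinite(d_intra) else np.nan,
             "min_dist_inter": d_inter, "partner_residue": partner}
        )
    n_mapped = len(rows) - n_unmapped
    fraction_intra = n_intra / n_mapped if n_mapped else float("nan")
    return PairClassification(
        table=pd.DataFrame(
            rows, columns=["i", "j", "category", "min_dist_intra", "min_dist_inter",
                           "partner_residue"]
        ),
        fraction_intra=fraction_intra,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
    )


def _side_chain_atoms(res: Residue) -> list[Atom]:
    return [a for a in res.atoms if a.name not in BACKBONE_ATOMS and a.element.upper() != "H"]


def _ring_centroid(res: Residue) -> Optional[np.ndarray]:
    names = AROMATIC_RING_ATOMS.get(res.name)
    if not names:
        return None
    pts = [a.xyz for a in res.atoms if a.name in names]
    return np.mean(pts, axis=0) if pts else None


def assign_contact_type(
    model: StructureModel, resA: tuple[str, int], resB: tuple[str, int]
) -> str:
    """Simplified geometric interaction typing; first matching rule wins.

    salt_bridge: side-chain O/N of Asp/Glu within 4.0 Å of a side-chain N
    of Arg/Lys/His; hydrogen_bond: any N/O within 3.5 Å of an O/N (no
    angle term — hydrogens are absent from crystal structures);
    pi_stacking: aromatic ring centroids (Phe/Tyr/Trp/His) within 7.0 Å;
    vdw: minimum heavy-atom distance ≤ 5.0 Å; otherwise none.
    """
    ra = model.residue(*resA)
    rb = model.residue(*resB)

    def _min_pair(atoms1: list[Atom], atoms2: list[Atom]) -> float:
        if not atoms1 or not atoms2:
            return np.inf
        return float(cdist(np.array([a.xyz for a in atoms1]),
                           np.array([a.xyz for a in atoms2])).min())

    for acid, base in ((ra, rb), (rb, ra)):
        if acid.name in ACIDIC and base.name in BASIC:
            acid_on = [a for a in _side_chain_atoms(acid) if a.element.upper() in ("O", "N")]
            base_n = [a for a in _side_chain_atoms(base) if a.element.upper() == "N"]
            if _min_pair(acid_on, base_n) <= 4.0:
                return "salt_bridge"

    no_a = [a for a in ra.atoms if a.element.upper() in ("N", "O")]
    no_b = [a for a in rb.atoms if a.element.upper() in ("N", "O")]
    if _min_pair(no_a, no_b) <= 3.5:
        return "hydrogen_bond"

    ca, cb = _ring_centroid(ra), _ring_centroid(rb)
    if ca is not None and cb is not None and float(np.linalg.norm(ca - cb)) <= 7.0:
        return "pi_stacking"

    heavy_a = [a for a in ra.atoms if a.element.upper() != "H"]
    heavy_b = [a for a in rb.atoms if a.element.upper() != "H"]
    if _min_pair(heavy_a, heavy_b) <= 5.0:
        return "vdw"
    return "none"
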