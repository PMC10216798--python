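import numpy as np
import pandas as pd
import pytest

from igdom.couplings import CouplingTable
from igdom.exceptions import InputError, SelectionError
from igdom.structure import (
    Atom,
    Chain,
    ContactParams,
    Residue,
    StructureModel,
    assign_contact_type,
    classify_coupled_pairs,
    read_structure,
    residue_min_distance,
    write_pdb,
)


def pdb_atom(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ", element="C"):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


def toy_model(chain_atoms):
    """Build a StructureModel from {chain: {resnum: (resname, [(name, el, xyz)])}}."""
    chains = {}
    for label, residues in chain_atoms.items():
        chain = Chain(label)
        for num, (resname, atoms) in sorted(residues.items()):
            chain.residues.append(
                Residue(num, "", resname,
                        [Atom(n, e, np.array(xyz, dtype=float)) for n, e, xyz in atoms])
            )
        chains[label] = chain
    return StructureModel(chains)


class TestReadStructure:
    def test_two_chain_toy_file(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(
            pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0)
            + pdb_atom(2, "CA", "ALA", "A", 2, 3.8, 0, 0)
            + pdb_atom(3, "CA", "GLY", "B", 1, 0, 12, 0)
            + "END\n"
        )
        model = read_structure(path)
        assert set(model.chains) == {"A", "B"}
        assert len(model.chain("A").residues) == 2

    def test_missing_chain_named_in_error(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0) + "END\n")
        with pytest.raises(SelectionError, match="Z"):
            read_structure(path, chains=["A", "Z"])

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            pdb_atom(1, "CA", "SER", "A", 1, 0, 0, 0, occ=0.6, altloc="A")
            + pdb_atom(2, "CA", "SER", "A", 1, 5, 0, 0, occ=0.4, altloc="B")
            + "END\n"
        )
        model = read_structure(path)
        res = model.residue("A", 1)
        assert len(res.atoms) == 1
        np.testing.assert_allclose(res.atoms[0].xyz, [0, 0, 0])

    def test_waters_excluded(self, tmp_path):
        path = tmp_path / "wat.pdb"
        path.write_text(
            pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0)
            + "HETATM    2  O   HOH A 100       1.000   1.000   1.000  1.00  0.00           O\n"
            + "END\n"
        )
        model = read_structure(path)
        assert len(model.chain("A").residues) == 1

    def test_write_read_roundtrip(self, tmp_path):
        model = toy_model(
            {"A": {1: ("ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])},
             "B": {1: ("GLY", [("CA", "C", (0, 12, 0))])}}
        )
        path = tmp_path / "rt.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        assert set(back.chains) == {"A", "B"}
        np.testing.assert_allclose(back.residue("A", 1).atoms[1].xyz, [1.5, 0, 0])


class TestResidueMinDistance:
    def test_single_atom_residues(self):
        model = toy_model(
            {"A": {1: ("ALA", [("CA", "C", (0, 0, 0))]),
                   2: ("ALA", [("CA", "C", (3, 0, 0))])}}
        )
        assert residue_min_distance(model, ("A", 1), ("A", 2)) == pytest.approx(3.0)

    def test_residue_vs_itself_is_zero(self):
        model = toy_model({"A": {1: ("ALA", [("CA", "C", (1, 2, 3))])}})
        assert residue_min_distance(model, ("A", 1), ("A", 1)) == 0.0

    def test_matches_exhaustive_pair_scan(self, rng):
        atoms1 = [("A%d" % k, "C", rng.normal(size=3)) for k in range(6)]
        atoms2 = [("B%d" % k, "C", rng.normal(size=3) + 5) for k in range(4)]
        model = toy_model({"A": {1: ("ALA", atoms1), 2: ("ALA", atoms2)}})
        brute = min(
            np.linalg.norm(np.array(a[2]) - np.array(b[2]))
            for a in atoms1 for b in atoms2
        )
        assert residue_min_distance(model, ("A", 1), ("A", 2)) == pytest.approx(brute)

    def test_hydrogens_excluded_under_heavy_subset(self):
        model = toy_model(
            {"A": {1: ("ALA", [("CA", "C", (0, 0, 0)), ("H", "H", (9.0, 0, 0))]),
                   2: ("ALA", [("CA", "C", (10, 0, 0))])}}
        )
        heavy = residue_min_distance(model, ("A", 1), ("A", 2))
        everything = residue_min_distance(
            model, ("A", 1), ("A", 2), ContactParams(5.0, "all")
        )
        assert heavy == pytest.approx(10.0)
        assert everything == pytest.approx(1.0)

    def test_symmetry(self, rng):
        atoms1 = [("X", "C", rng.normal(size=3))]
        atoms2 = [("Y", "C", rng.normal(size=3))]
        model = toy_model({"A": {1: ("ALA", atoms1), 2: ("ALA", atoms2)}})
        assert residue_min_distance(model, ("A", 1), ("A", 2)) == pytest.approx(
            residue_min_distance(model, ("A", 2), ("A", 1))
        )


def coupling_table(pairs):
    return CouplingTable(
        pd.DataFrame(
            [{"i": min(i, j), "j": max(i, j), "raw_score": 1.0, "probability": np.nan}
             for i, j in pairs]
        )
    )


class TestClassifyCoupledPairs:
    def _planted_model(self):
        """Chain A: 8 residues in a line; pair (1,5) intra; pair (2,6)
        inter_mutual via chain B; pair (3,7) shares chain-B partner 4."""
        A = {r: ("ALA", [("CA", "C", (7.0 * r, 0, 0))]) for r in range(1, 9)}
        B = {r: ("ALA", [("CA", "C", (7.0 * r, 20, 0))]) for r in range(1, 9)}
        # intra (1,5): side atoms meet at z=30
        A[1][1].append(("S1", "C", (0, 0, 30)))
        A[5][1].append(("S1", "C", (3, 0, 30)))
        # inter_mutual (2,6): A:2 meets B:6 at z=50
        A[2][1].append(("S2", "C", (0, 10, 50)))
        B[6][1].append(("S2", "C", (3, 10, 50)))
        # shared partner (3,7) via B:4 at z=70
        A[3][1].append(("S3", "C", (0, 10, 70)))
        B[4][1].append(("S3", "C", (4, 10, 70)))
        A[7][1].append(("S3", "C", (8, 10, 70)))
        return toy_model({"A": A, "B": B})

    def test_categories_and_fraction(self):
        model = self._planted_model()
        t = coupling_table([(1, 5), (2, 6), (3, 7), (1, 8)])
        res = classify_coupled_pairs(t, model, "A", "B")
        cats = dict(zip(zip(res.table.i, res.table.j), res.table.category))
        assert cats[(1, 5)] == "intra_contact"
        assert cats[(2, 6)] == "inter_mutual"
        assert cats[(3, 7)] == "inter_shared_partner"
        assert cats[(1, 8)] == "unexplained"
        assert res.fraction_intra == pytest.approx(0.25)
        assert res.table.loc[
            (res.table.i == 3) & (res.table.j == 7), "partner_residue"
        ].iloc[0] == 4

    def test_all_planted_intra_gives_fraction_one(self):
        A = {r: ("ALA", [("CA", "C", (7.0 * r, 0, 0))]) for r in range(1, 22)}
        pairs = [(k, k + 10) for k in range(1, 11)]
        for p, (i, j) in enumerate(pairs):
            A[i][1].append((f"S{p}", "C", (10.0 * p, 0, 30)))
            A[j][1].append((f"S{p}", "C", (10.0 * p + 3, 0, 30)))
        model = toy_model({"A": A})
        res = classify_coupled_pairs(coupling_table(pairs), model, "A")
        assert res.fraction_intra == 1.0

    def test_unmapped_pairs_flagged_and_excluded_from_denominator(self):
        model = self._planted_model()
        t = coupling_table([(1, 5), (1, 99)])
        res = classify_coupled_pairs(t, model, "A", "B")
        assert res.n_unmapped == 1
        assert res.fraction_intra == 1.0
        assert (res.table.category == "unmapped").sum() == 1

    def test_category_counts_partition_mapped_pairs(self):
        model = self._planted_model()
        t = coupling_table([(1, 5), (2, 6), (3, 7), (1, 8), (2, 8)])
        res = classify_coupled_pairs(t, model, "A", "B")
        assert sum(res.counts().values()) == res.n_mapped == 5

    def test_invariant_to_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        model = self._planted_model()
        R = Rotation.random(random_state=3).as_matrix()
        shift = rng.normal(scale=50, size=3)
        moved = toy_model({})
        moved.chains = {}
        for label, chain in model.chains.items():
            new = Chain(label)
            for res in chain.residues:
                new.residues.append(
                    Residue(res.number, "", res.name,
                            [Atom(a.name, a.element, R @ a.xyz + shift) for a in res.atoms])
                )
            moved.chains[label] = new
        t = coupling_table([(1, 5), (2, 6), (3, 7), (1, 8)])
        res1 = classify_coupled_pairs(t, model, "A", "B")
        res2 = classify_coupled_pairs(t, moved, "A", "B")
        assert res1.table.category.tolist() == res2.table.category.tolist()

    def test_position_map_translates_numbering(self):
        model = self._planted_model()
        t = coupling_table([(101, 105)])
        res = classify_coupled_pairs(
            t, model, "A", "B", position_map={101: 1, 105: 5}
        )
        assert res.table.category.iloc[0] == "intra_contact"


class TestAssignContactType:
    def test_salt_bridge(self):
        model = toy_model(
            {"A": {1: ("ASP", [("CB", "C", (0, 0, 0)), ("OD1", "O", (1, 0, 0))]),
                   2: ("LYS", [("CB", "C", (6, 0, 0)), ("NZ", "N", (4.2, 0, 0))])}}
        )
        assert assign_contact_type(model, ("A", 1), ("A", 2)) == "salt_bridge"

    def test_hydrogen_bond(self):
        model = toy_model(
            {"A": {1: ("SER", [("OG", "O", (0, 0, 0))]),
                   2: ("THR", [("OG1", "O", (3.3, 0, 0))])}}
        )
        assert assign_contact_type(model, ("A", 1), ("A", 2)) == "hydrogen_bond"

    def test_pi_stacking(self):
        ring = [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"), ("CE2", "C"), ("CZ", "C")]
        hexagon = [
            (1.4 * np.cos(np.pi * k / 3), 1.4 * np.sin(np.pi * k / 3), 0.0)
            for k in range(6)
        ]
        model = toy_model(
            {"A": {1: ("PHE", [(n, e, p) for (n, e), p in zip(ring, hexagon)]),
                   2: ("PHE", [(n, e, (p[0], p[1], p[2] + 5.5))
                               for (n, e), p in zip(ring, hexagon)])}}
        )
        assert assign_contact_type(model, ("A", 1), ("A", 2)) == "pi_stacking"

    def test_vdw_fallback(self):
        model = toy_model(
            {"A": {1: ("ALA", [("CB", "C", (0, 0, 0))]),
                   2: ("LEU", [("CD1", "C", (4.5, 0, 0))])}}
        )
        assert assign_contact_type(model, ("A", 1), ("A", 2)) == "vdw"

    def test_none_beyond_cutoffs(self):
        model = toy_model(
            {"A": {1: ("ALA", [("CB", "C", (0, 0, 0))]),
                   2: ("ALA", [("CB", "C", (8, 0, 0))])}}
        )
        assert assign_contact_type(model, ("A", 1), ("A", 2)) == "none"

    def test_salt_bridge_outranks_hydrogen_bond(self):
        model = toy_model(
            {"A": {1: ("GLU", [("OE1", "O", (0, 0, 0))]),
                   2: ("ARG", [("NH1", "N", (3.0, 0, 0))])}}
        )
        assert assign_contact_type(model, ("A", 1), ("A", 2)) == "salt_bridge"
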