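"""Synthetic grouped alignments and toy dimer structures with ground truth.

The generator emulates the statistical structure the downstream analyses
assume in real Ig constant-domain data, with every planted feature
recorded as truth:

- sequences i.i.d. within groups over a background categorical (uniform
  over the 20 amino acids unless overridden);
- *property-shifted* columns where a chosen group draws a charged residue
  (D/E/R/K, uniformly) with probability ``p_charged``;
- *coupled* column pairs (i, j): with probability ``coupling_strength`` a
  joint residue-pair state is drawn uniformly from the pair's codebook,
  otherwise both columns draw independently from the background;
- gaps, then ambiguity codes (B/X/Z), injected cell-wise at stated rates —
  gap injection happens after coupling sampling, so planted mutual
  information is attenuated by gaps exactly as in real alignments.

``build_toy_dimer`` emits a two-chain pseudo-atom model realizing a
prescribed contact plan: each chain is a line of backbone pseudo-atoms
(6.5 Å spacing, chains 12 Å apart) and each planned contact is realized by
placing extra side-chain pseudo-atoms at a private meeting point well away
from everything else.  The model is verified against the classifier's own
distance criterion before being returned; an unsatisfiable plan raises
instead of producing a silently wrong structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from igdom.alignment import Alignment, LabeledAlignment
from igdom.alphabet import AMINO_ACIDS, GAP
from igdom.couplings import CouplingTable
from igdom.exceptions import ConstructionError, InputError, SyntheticSpecError
from igdom.structure import (
    Atom,
    Chain,
    ContactParams,
    Residue,
    StructureModel,
    classify_coupled_pairs,
)

CHARGED = ("D", "E", "R", "K")
AMBIGUITY_CODES = ("B", "Z", "X")


@dataclass(frozen=True)
class CoupledPair:
    """A planted covarying column pair (1-based positions)."""

    i: int
    j: int
    strength: float = 0.9
    codebook: tuple[tuple[str, str], ...] = (("K", "D"), ("R", "E"), ("L", "F"), ("S", "T"))


@dataclass(frozen=True)
class GroupSpec:
    """One sequence group: size, labels, and its property-shift plan."""

    label: str
    n: int
    shifted_columns: tuple[int, ...] = ()
    p_charged: float = 0.0
    isotype: Optional[str] = None
    animal_class: Optional[str] = None
    domain_kind: str = "CH3"


@dataclass
class SyntheticSpec:
    """Full description of a synthetic grouped alignment."""

    L: int
    groups: tuple[GroupSpec, ...]
    coupled_pairs: tuple[CoupledPair, ...] = ()
    gap_rate: float = 0.0
    ambiguity_rate: float = 0.0
    seed: int = 0
    background: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise SyntheticSpecError("L must be positive")
        if not self.groups:
            raise SyntheticSpecError("at least one group required")
        if not 0 <= self.gap_rate < 1:
            raise SyntheticSpecError("gap_rate must be in [0, 1)")
        if not 0 <= self.ambiguity_rate < 1:
            raise SyntheticSpecError("ambiguity_rate must be in [0, 1)")
        used: set[int] = set()
        for cp in self.coupled_pairs:
            if not (1 <= cp.i <= self.L and 1 <= cp.j <= self.L) or cp.i == cp.j:
                raise SyntheticSpecError(f"bad coupled pair ({cp.i}, {cp.j})")
            if not 0 <= cp.strength <= 1:
                raise SyntheticSpecError("coupling strength must be in [0, 1]")
            if {cp.i, cp.j} & used:
                raise SyntheticSpecError("coupled-pair columns must be disjoint")
            used |= {cp.i, cp.j}
        for g in self.groups:
            for c in g.shifted_columns:
                if not 1 <= c <= self.L:
                    raise SyntheticSpecError(f"shifted column {c} outside 1..{self.L}")
                if c in used:
                    raise SyntheticSpecError(
                        f"shifted column {c} overlaps a coupled-pair column"
                    )
            if not 0 <= g.p_charged <= 1:
                raise SyntheticSpecError("p_charged must be in [0, 1]")
            if g.n < 1:
                raise SyntheticSpecError(f"group {g.label!r} has no sequences")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset."""

    planted_pairs: list[tuple[int, int]]
    group_property_means: dict[str, float]
    contact_plan: list[dict]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_pairs": [list(p) for p in self.planted_pairs],
                    "group_property_means": self.group_property_means,
                    "contact_plan": self.contact_plan,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = tuple(
        GroupSpec(
            label=g["label"],
            n=int(g["n"]),
            shifted_columns=tuple(g.get("shifted_columns", ())),
            p_charged=float(g.get("p_charged", 0.0)),
            isotype=g.get("isotype"),
            animal_class=g.get("animal_class"),
            domain_kind=g.get("domain_kind", "CH3"),
        )
        for g in raw["groups"]
    )
    pairs = tuple(
        CoupledPair(
            i=int(p["i"]),
            j=int(p["j"]),
            strength=float(p.get("strength", 0.9)),
            codebook=tuple(tuple(s) for s in p.get("codebook", CoupledPair(1, 2).codebook)),
        )
        for p in raw.get("coupled_pairs", ())
    )
    return SyntheticSpec(
        L=int(raw["L"]),
        groups=groups,
        coupled_pairs=pairs,
        gap_rate=float(raw.get("gap_rate", 0.0)),
        ambiguity_rate=float(raw.get("ambiguity_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
    )


def simulate_alignment(spec: SyntheticSpec) -> tuple[LabeledAlignment, SyntheticTruth]:
    """Draw a grouped alignment realizing the spec; identical seeds give
    identical outputs."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    if spec.background is None:
        bg = np.full(len(aa), 1.0 / len(aa))
    else:
        bg = np.asarray(spec.background, dtype=float)
        if bg.shape != (len(aa),) or abs(bg.sum() - 1) > 1e-9 or (bg < 0).any():
            raise SyntheticSpecError("background must be a 20-aa distribution")

    ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    for g in spec.groups:
        shifted = np.array(g.shifted_columns, dtype=int) - 1
        for s in range(g.n):
            row = rng.choice(aa, size=spec.L, p=bg)
            if len(shifted):
                mask = rng.random(len(shifted)) < g.p_charged
                row[shifted[mask]] = rng.choice(np.array(CHARGED), size=int(mask.sum()))
            for cp in spec.coupled_pairs:
                if rng.random() < cp.strength:
                    ri, rj = cp.codebook[rng.integers(len(cp.codebook))]
                    row[cp.i - 1], row[cp.j - 1] = ri, rj
                # else: both columns keep their independent background draws
            if spec.gap_rate > 0:
                row[rng.random(spec.L) < spec.gap_rate] = GAP
            if spec.ambiguity_rate > 0:
                amb = (rng.random(spec.L) < spec.ambiguity_rate) & (row != GAP)
                row[amb] = rng.choice(np.array(AMBIGUITY_CODES), size=int(amb.sum()))
            seq_id = f"{g.label}_{s:04d}"
            ids.append(seq_id)
            rows.append(row)
            meta.append(
                {
                    "id": seq_id,
                    "isotype": g.isotype or g.label,
                    "animal_class": g.animal_class or g.label,
                    "domain_kind": g.domain_kind,
                }
            )

    aln = Alignment(ids=ids, rows=["".join(r) for r in rows])
    labels = pd.DataFrame(meta).set_index("id")
    # expected normalized charge per group at its shifted columns:
    # p_charged ·1 + (1 − p_charged) · background charged mass
    bg_charged = float(bg[[list(AMINO_ACIDS).index(c) for c in CHARGED]].sum())
    means = {
        g.label: g.p_charged + (1 - g.p_charged) * bg_charged if g.shifted_columns else bg_charged
        for g in spec.groups
    }
    truth = SyntheticTruth(
        planted_pairs=[(cp.i, cp.j) for cp in spec.coupled_pairs],
        group_property_means=means,
        contact_plan=[],
        seed=spec.seed,
    )
    return LabeledAlignment(aln, labels), truth


# ---------------------------------------------------------------------------
# toy dimer construction

PLAN_CATEGORIES = ("intra", "inter_mutual", "shared_partner", "none")

_BACKBONE_SPACING = 6.5  # Å between consecutive backbone pseudo-atoms
_CHAIN_SEPARATION = 12.0  # Å between the two parallel chains
_CONTACT_DISTANCE = 3.0  # Å between meeting-point atoms of a planned contact
_SHARED_ARM = 4.0  # Å from each shared-partner residue to the partner atom


@dataclass(frozen=True)
class PlannedContact:
    """One plan entry: pair (i, j) in chain-A numbering plus its category.

    ``partner`` optionally names the chain-B residue realizing a
    shared_partner entry; it must differ from i and j (otherwise the pair
    would classify as inter_mutual), and defaults to an unused residue.
    """

    i: int
    j: int
    category: str
    partner: Optional[int] = None


def build_toy_dimer(
    plan: Sequence[PlannedContact],
    L: int,
    params: ContactParams = ContactParams(),
) -> StructureModel:
    """Build a two-chain pseudo-atom model realizing a contact plan.

    Every planned pair satisfies exactly its intended category under the
    given ContactParams; all unplanned residue pairs stay beyond the
    cutoff with a guard margin.  The model is re-checked against
    ``classify_coupled_pairs`` before being returned.
    """
    for p in plan:
        if p.category not in PLAN_CATEGORIES:
            raise InputError(f"unknown plan category {p.category!r}")
        if not (1 <= p.i <= L and 1 <= p.j <= L) or p.i == p.j:
            raise InputError(f"bad plan pair ({p.i}, {p.j})")
        if abs(p.i - p.j) < 2:
            raise ConstructionError(
                f"pair ({p.i}, {p.j}): adjacent backbone residues sit at "
                f"{_BACKBONE_SPACING} Å and cannot avoid ambiguity"
            )
    used: set[int] = set()
    for p in plan:
        if {p.i, p.j} & used:
            raise ConstructionError("plan entries must use disjoint residues")
        used |= {p.i, p.j}

    chains = {label: Chain(label) for label in ("A", "B")}
    y = {"A": 0.0, "B": _CHAIN_SEPARATION}
    for label in ("A", "B"):
        for r in range(1, L + 1):
            chains[label].residues.append(
                Residue(
                    number=r,
                    insertion_code="",
                    name="ALA",
                    atoms=[Atom("CA", "C", np.array([r * _BACKBONE_SPACING, y[label], 0.0]))],
                )
            )

    def _res(label: str, num: int) -> Residue:
        return chains[label].residues[num - 1]

    partners_used: set[int] = set()
    for p_idx, p in enumerate(plan):
        if p.category == "none":
            continue
        # private meeting point, far from both backbones and other entries
        m = np.array([3.0 * p_idx, _CHAIN_SEPARATION / 2, 20.0 + 10.0 * p_idx])
        tag = f"X{p_idx}"
        if p.category == "intra":
            _res("A", p.i).atoms.append(Atom(tag, "C", m))
            _res("A", p.j).atoms.append(Atom(tag, "C", m + [_CONTACT_DISTANCE, 0, 0]))
        elif p.category == "inter_mutual":
            _res("A", p.i).atoms.append(Atom(tag, "C", m))
            _res("B", p.j).atoms.append(Atom(tag, "C", m + [_CONTACT_DISTANCE, 0, 0]))
        elif p.category == "shared_partner":
            if p.partner is not None:
                partner = p.partner
            else:
                # an unused chain-B residue: a partner equal to i or j would
                # put the pair itself within the cutoff across the interface
                candidates = (
                    r for r in range(1, L + 1) if r not in used and r not in partners_used
                )
                partner = next(candidates, None)
                if partner is None:
                    raise ConstructionError("no free chain-B residue for shared partner")
            if not 1 <= partner <= L:
                raise ConstructionError(f"shared partner {partner} outside chain B")
            if partner in (p.i, p.j):
                raise ConstructionError(
                    f"shared partner {partner} coincides with the pair ({p.i}, {p.j})"
                )
            if partner in partners_used:
                raise ConstructionError(f"chain-B partner {partner} reused across entries")
            partners_used.add(partner)
            _res("A", p.i).atoms.append(Atom(tag, "C", m))
            _res("B", partner).atoms.append(Atom(tag, "C", m + [_SHARED_ARM, 0, 0]))
            _res("A", p.j).atoms.append(Atom(tag, "C", m + [2 * _SHARED_ARM, 0, 0]))

    model = StructureModel(chains)
    _verify_plan(model, plan, params)
    return model


_PLAN_TO_CATEGORY = {
    "intra": "intra_contact",
    "inter_mutual": "inter_mutual",
    "shared_partner": "inter_shared_partner",
    "none": "unexplained",
}


def _verify_plan(
    model: StructureModel, plan: Sequence[PlannedContact], params: ContactParams
) -> None:
    """Self-check: every planned pair must classify exactly as intended."""
    if not plan:
        return
    df = pd.DataFrame(
        {
            "i": [min(p.i, p.j) for p in plan],
            "j": [max(p.i, p.j) for p in plan],
            "raw_score": 1.0,
            "probability": np.nan,
        }
    )
    result = classify_coupled_pairs(
        CouplingTable(df), model, monomer_chain="A", partner_chain="B", params=params
    )
    got = dict(zip(zip(result.table["i"], result.table["j"]), result.table["category"]))
    for p in plan:
        key = (min(p.i, p.j), max(p.i, p.j))
        want = _PLAN_TO_CATEGORY[p.category]
        if got[key] != want:
            raise ConstructionError(
                f"pair ({p.i}, {p.j}) planned {p.category!r} classified {got[key]!r}"
            )


def random_contact_plan(
    rng: np.random.Generator,
    L: int,
    n_per_category: dict[str, int],
    min_separation: int = 5,
) -> list[PlannedContact]:
    """Draw a random plan with disjoint residues and long-range pairs."""
    needed = 2 * sum(n_per_category.values())
    if needed > L // 2:
        raise ConstructionError(f"plan needs {needed} residues; L={L} too small")
    available = list(range(1, L + 1))
    plan: list[PlannedContact] = []
    for category, count in n_per_category.items():
        for _ in range(count):
            for _attempt in range(1000):
                i, j = rng.choice(len(available), size=2, replace=False)
                ri, rj = available[i], available[j]
                if abs(ri - rj) >= max(min_separation, 2):
                    break
            else:
                raise ConstructionError("could not place plan pair")
            for r in sorted((ri, rj), reverse=True):
                available.remove(r)
            plan.append(PlannedContact(min(ri, rj), max(ri, rj), category))
    return plan


def recovery_report(
    truth: SyntheticTruth, inferred: CouplingTable, k: int
) -> dict[str, float]:
    """Precision and recall of the top-k inferred pairs against the planted set.

    Pairs are compared as unordered position pairs; ``k`` larger than the
    table is clamped with a warning.
    """
    import warnings

    if k < 1:
        raise InputError("k must be >= 1")
    if k > len(inferred):
        warnings.warn(f"k={k} exceeds table size {len(inferred)}; clamped", stacklevel=2)
        k = len(inferred)
    planted = {frozenset(p) for p in truth.planted_pairs}
    top = {frozenset(p) for p in inferred.top_k(k).pair_set()}
    hits = len(top & planted)
    return {
        "precision_at_k": hits / k if k else float("nan"),
        "recall_at_k": hits / len(planted) if planted else float("nan"),
        "k": k,
        "n_planted": len(planted),
    }
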