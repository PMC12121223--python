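"""Structure-side mutation design: ligand proximity, in-silico point
mutation with an idealized side-chain builder, steric-clash screening, and
the combined candidate-ranking pipeline.

The design rules are geometric. A substitution site must (1) have basic
support in the paralog alignment, (2) accept the new side chain without
steric clashes, and (3) sit near the bound glycosaminoglycan ligand so the
added positive charge can actually reach it. Side chains are modelled as
idealized straight chains extended along the CA->CB direction (1.53 A per
heavy atom, collinear) — a deliberately conservative single-conformation
surrogate for rotamer search: it can flag relievable contacts but cannot
miss a genuinely unavoidable one along that direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .alignment import Alignment, find_candidate_columns
from .numbering import ResidueNumbering
from .variants import MutationSpec

logger = logging.getLogger(__name__)

#: HETATM residue names flagged as ligand by default: heparin/heparan
#: sulfate saccharide codes plus the generic names used by the toy builder.
DEFAULT_LIGAND_NAMES = frozenset(
    {"SGN", "IDS", "IDU", "UAP", "GCU", "BDP", "GCS", "ASG", "HEP", "LIG"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Side-chain heavy atoms beyond CB, in chain order, for the idealized
#: collinear builder. Branched side chains are flattened into a chain —
#: adequate for a reach/clash screen, not for chemistry.
SIDE_CHAIN_TEMPLATES: dict[str, tuple[str, ...]] = {
    "G": (), "A": (), "S": ("OG",), "C": ("SG",), "T": ("OG1", "CG2"),
    "V": ("CG1", "CG2"), "P": ("CG", "CD"), "L": ("CG", "CD1", "CD2"),
    "I": ("CG1", "CG2", "CD1"), "M": ("CG", "SD", "CE"),
    "N": ("CG", "OD1", "ND2"), "D": ("CG", "OD1", "OD2"),
    "Q": ("CG", "CD", "OE1", "NE2"), "E": ("CG", "CD", "OE1", "OE2"),
    "K": ("CG", "CD", "CE", "NZ"), "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "R": ("CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "W": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

BOND_LENGTH = 1.53  # A per added heavy atom


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    name: str
    element: str
    x: float
    y: float
    z: float
    is_ligand: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass(frozen=True)
class Structure:
    """A flat, immutable atom list with ligand flags."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        coords = np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        keys = [(a.chain, a.res_seq, a.icode, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom name) records")

    @property
    def ligand_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.is_ligand)

    @property
    def protein_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_ligand)

    def residue_atoms(self, res_seq: int, chain: str | None = None
                      ) -> tuple[Atom, ...]:
        found = tuple(a for a in self.atoms
                      if a.res_seq == res_seq and not a.is_ligand
                      and (chain is None or a.chain == chain))
        if not found:
            raise KeyError(f"no residue {res_seq} (chain {chain or 'any'})")
        chains = {a.chain for a in found}
        if len(chains) > 1:
            raise KeyError(f"residue {res_seq} ambiguous across chains {chains}")
        return found

    def residue_name(self, res_seq: int, chain: str | None = None) -> str:
        return self.residue_atoms(res_seq, chain)[0].res_name

    def residue_numbers(self, chain: str | None = None) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.protein_atoms:
            if chain is None or a.chain == chain:
                seen.setdefault(a.res_seq, None)
        return list(seen)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Structure":
        """Rigid-body transform of every atom (for invariance checks)."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        new = []
        for a in self.atoms:
            x, y, z = rot @ a.pos + tr
            new.append(replace(a, x=float(x), y=float(y), z=float(z)))
        return Structure(tuple(new))


def _coords(atoms: Sequence[Atom]) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float).reshape(-1, 3)


def read_structure(pdb_text: str,
                   ligand_names: Iterable[str] = DEFAULT_LIGAND_NAMES
                   ) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    HETATM residues whose name is in ``ligand_names`` are flagged as
    ligand; waters are dropped. Malformed coordinate fields raise with the
    offending line number.
    """
    ligand_names = frozenset(ligand_names)
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"malformed coordinate field on line {lineno}: {line!r}"
                    ) from None
    st = gemmi.read_pdb_string(pdb_text)
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name in _WATER_NAMES:
                    continue
                het = res.het_flag == "H"
                is_ligand = het and res.name in ligand_names
                for atom in res:
                    atoms.append(Atom(
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip(),
                        res_name=res.name,
                        name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        is_ligand=is_ligand,
                    ))
        break  # first model only
    if not any(not a.is_ligand for a in atoms):
        raise ValueError("no protein atoms in PDB input")
    return Structure(tuple(atoms))


def read_structure_file(path: "str | Path",
                        ligand_names: Iterable[str] = DEFAULT_LIGAND_NAMES
                        ) -> Structure:
    return read_structure(Path(path).read_text(), ligand_names)


def to_pdb(structure: Structure) -> str:
    """Serialize to PDB text (via gemmi; ligand residues become HETATM)."""
    st = gemmi.Structure()
    st.name = "fgfhs"
    model = gemmi.Model("1")
    # group atoms by (chain, residue) preserving order; gemmi copies on
    # add_*, so each container must be complete before it is added
    grouped: dict[str, dict[tuple, list[Atom]]] = {}
    for a in structure.atoms:
        grouped.setdefault(a.chain, {}).setdefault(
            (a.res_seq, a.icode, a.res_name), []).append(a)
    for chain_name, residues in grouped.items():
        chain = gemmi.Chain(chain_name)
        for (res_seq, icode, res_name), res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(res_seq, icode or " ")
            res.het_flag = "H" if res_atoms[0].is_ligand else "A"
            for a in res_atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def write_structure(structure: Structure, path: "str | Path") -> None:
    Path(path).write_text(to_pdb(structure))


def min_distance_to_ligand(structure: Structure, position: int,
                           chain: str | None = None) -> float:
    """Minimum heavy-atom distance (A) from a residue to the ligand."""
    res_atoms = [a for a in structure.residue_atoms(position, chain) if a.is_heavy]
    lig_atoms = [a for a in structure.ligand_atoms if a.is_heavy]
    if not lig_atoms:
        raise ValueError("structure has no ligand atoms")
    d = _coords(res_atoms)[:, None, :] - _coords(lig_atoms)[None, :, :]
    return float(np.sqrt((d ** 2).sum(axis=2)).min())


def _synthesize_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # idealized tetrahedral CB direction: opposite the N/C bisector
    v = (n - ca) + (c - ca)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate backbone geometry; cannot place CB")
    return ca - BOND_LENGTH * v / norm


def mutate_residue(structure: Structure, spec: "MutationSpec | tuple[int, str]",
                   chain: str | None = None) -> Structure:
    """Replace a residue's side chain with an idealized model of another.

    Backbone atoms are untouched. The new side chain is a straight chain of
    the target residue's heavy atoms extended from CB along the CA->CB
    direction at 1.53 A per atom; shrinking substitutions simply truncate.
    Mutating from glycine synthesizes CB at the idealized tetrahedral
    position. ``spec`` is a :class:`MutationSpec` (its position is used as
    the structure's residue number) or a bare ``(position, new_residue)``.
    """
    if isinstance(spec, MutationSpec):
        position, new_res = spec.position, spec.new_residue
    else:
        position, new_res = spec
    if new_res not in SIDE_CHAIN_TEMPLATES:
        raise KeyError(f"unknown target residue {new_res!r}")
    res_atoms = structure.residue_atoms(position, chain)
    the_chain = res_atoms[0].chain
    by_name = {a.name: a for a in res_atoms}
    for anchor in ("N", "CA"):
        if anchor not in by_name:
            raise ValueError(f"residue {position} lacks anchor atom {anchor}")
    if "CB" in by_name:
        cb = by_name["CB"].pos
    elif "C" in by_name:
        cb = _synthesize_cb(by_name["N"].pos, by_name["CA"].pos, by_name["C"].pos)
    else:
        raise ValueError(f"residue {position} lacks CB and C anchors")
    ca = by_name["CA"].pos
    u = cb - ca
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError(f"residue {position}: CA and CB coincide")
    u = u / norm

    new_name3 = ONE_TO_THREE[new_res]
    kept = [replace(a, res_name=new_name3) for a in res_atoms
            if a.name in BACKBONE_ATOMS]
    if new_res != "G":
        kept.append(Atom(the_chain, position, res_atoms[0].icode, new_name3,
                         "CB", "C", float(cb[0]), float(cb[1]), float(cb[2])))
        for k, atom_name in enumerate(SIDE_CHAIN_TEMPLATES[new_res], start=1):
            p = cb + k * BOND_LENGTH * u
            kept.append(Atom(the_chain, position, res_atoms[0].icode, new_name3,
                             atom_name, atom_name[0],
                             float(p[0]), float(p[1]), float(p[2])))

    others = [a for a in structure.atoms
              if not (not a.is_ligand and a.chain == the_chain
                      and a.res_seq == position)]
    return Structure(tuple(others + kept))


@dataclass(frozen=True)
class ClashReport:
    clash: bool
    pairs: tuple[tuple[Atom, Atom, float], ...] = ()

    def __bool__(self) -> bool:
        return self.clash


def detect_clashes(structure: Structure, position: int,
                   clash_cutoff: float = 2.4,
                   chain: str | None = None) -> ClashReport:
    """Steric-clash screen for one residue's side chain.

    A clash is any heavy side-chain atom of the residue closer than
    ``clash_cutoff`` (A, center-to-center) to a heavy atom of the ligand or
    of another residue; the backbone of the two sequence neighbours (i+-1,
    same chain) is excluded, their side chains are not. Returns the
    offending atom pairs with their distances.
    """
    res_atoms = structure.residue_atoms(position, chain)
    the_chain = res_atoms[0].chain
    side = [a for a in res_atoms if a.name not in BACKBONE_ATOMS and a.is_heavy]
    if not side:
        return ClashReport(False)

    def excluded(a: Atom) -> bool:
        if a.is_ligand:
            return False
        if a.chain == the_chain and a.res_seq == position:
            return True
        if (a.chain == the_chain and abs(a.res_seq - position) == 1
                and a.name in BACKBONE_ATOMS):
            return True
        return False

    env = [a for a in structure.atoms if a.is_heavy and not excluded(a)]
    if not env:
        return ClashReport(False)
    dmat = np.sqrt(((_coords(side)[:, None, :] - _coords(env)[None, :, :]) ** 2
                    ).sum(axis=2))
    hits = np.argwhere(dmat < clash_cutoff)
    pairs = tuple(sorted(
        ((side[i], env[j], float(dmat[i, j])) for i, j in hits),
        key=lambda p: p[2]))
    return ClashReport(bool(pairs), pairs)


@dataclass(frozen=True)
class CandidateSite:
    """A retained basic-residue substitution proposal."""

    position: int
    wt_residue: str
    proposed_residue: str
    basic_support: int
    min_ligand_distance: float
    clash: bool = False
    rank: int = 0

    @property
    def label(self) -> str:
        return f"{self.wt_residue}{self.position}{self.proposed_residue}"


def identity_numbering(length: int) -> ResidueNumbering:
    """1-based identity frame for structures numbered like the sequence."""
    return ResidueNumbering("identity", start=0, stop=length)


def design_candidates(alignment: Alignment, target_id: str,
                      structure: Structure,
                      mapping: ResidueNumbering | None = None,
                      vicinity_cutoff: float = 8.0,
                      clash_cutoff: float = 2.4,
                      min_support: int = 3,
                      chain: str | None = None,
                      proposed_order: str = "RK") -> list[CandidateSite]:
    """The full alignment + structure design pipeline.

    Candidate columns from the basic-support rule are mapped onto structure
    residue numbers (through the ungapped target sequence index and
    ``mapping``, identity by default), filtered by ligand vicinity, then
    each surviving site is mutated in silico to arginine and lysine and
    screened for clashes. Arginine is preferred when both pass. Sites are
    ranked by (ligand distance ascending, basic support descending).
    Unmappable columns are skipped with a log entry, not an error.
    """
    target_seq = alignment.ungapped(target_id)
    if mapping is None:
        mapping = identity_numbering(len(target_seq))
    for a in structure.protein_atoms:
        if a.icode:
            raise ValueError(
                f"insertion code {a.icode!r} at residue {a.res_seq}; "
                "renumber the structure before design")

    sites: list[CandidateSite] = []
    for cc in find_candidate_columns(alignment, target_id, min_support):
        idx = alignment.column_to_ungapped_index(target_id, cc.column)
        try:
            position = mapping.from_parent_index(idx)
        except KeyError:
            logger.info("column %d: target index %d unmapped; skipped",
                        cc.column, idx)
            continue
        try:
            dist = min_distance_to_ligand(structure, position, chain)
        except KeyError:
            logger.info("column %d: residue %d absent from structure; skipped",
                        cc.column, position)
            continue
        if dist > vicinity_cutoff:
            continue
        chosen: str | None = None
        for proposed in proposed_order:
            mutated = mutate_residue(structure, (position, proposed), chain)
            if not detect_clashes(mutated, position, clash_cutoff, chain):
                chosen = proposed
                break
        if chosen is None:
            continue
        sites.append(CandidateSite(
            position=position,
            wt_residue=target_seq[idx],
            proposed_residue=chosen,
            basic_support=cc.basic_support,
            min_ligand_distance=dist,
        ))
    sites.sort(key=lambda s: (s.min_ligand_distance, -s.basic_support, s.position))
    return [replace(s, rank=i) for i, s in enumerate(sites, start=1)]


def write_candidates_csv(sites: Sequence[CandidateSite], path: "str | Path",
                         scheme: str = "identity") -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "scheme", "wt", "proposed", "support",
                    "min_dist_A", "clash", "rank"])
        for s in sites:
            w.writerow([s.position, scheme, s.wt_residue, s.proposed_residue,
                        s.basic_support, f"{s.min_ligand_distance:.3f}",
                        s.clash, s.rank])
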