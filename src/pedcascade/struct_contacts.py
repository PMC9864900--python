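"""Side-chain contact detection and substitution impact on a structure.

The structural argument for the arginine-to-histidine change is geometric:
in the actin-bound RPEL2 fold the arginine's guanidinium group donates
hydrogen bonds and forms charged interactions with two nearby acidic
residues, stabilizing the end of the repeat; histidine's shorter imidazole
cannot reach them. This module detects such contacts with conventional
distance cutoffs (3.5 Å hydrogen bond, 4.0 Å salt bridge; no angle terms,
since crystal structures at this resolution typically lack hydrogens) and
reports which contacts survive a substitution by atom-name intersection —
no rotamer rebuilding or repacking is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning


class ParseError(ValueError):
    pass


class ResidueLookupError(KeyError):
    pass


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def id(self) -> str:
        return f"{self.chain}/{self.res_name}{self.res_number}/{self.atom_name}"

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Structure:
    atoms: list[Atom]

    def residue_atoms(self, chain: str, res_number: int) -> list[Atom]:
        atoms = [a for a in self.atoms
                 if a.chain == chain and a.res_number == res_number]
        if not atoms:
            raise ResidueLookupError(f"no residue {chain}/{res_number}")
        return atoms

    def residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.res_number), a.res_name)
        return [(c, n, r) for (c, n), r in seen.items()]


@dataclass(frozen=True)
class Contact:
    donor_atom: str     # atom id on the positively-charged/donor side
    acceptor_atom: str
    distance: float
    kind: str           # HBOND or SALT_BRIDGE


# Backbone atoms excluded under the default side-chain-only analysis.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Side-chain hydrogen-bond donors (N/O with attached hydrogens).
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"},
}
# Side-chain hydrogen-bond acceptors (N/O lone pairs).
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"},
}
# Charged-group atoms for salt bridges.
POSITIVE_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
}
CARBOXYLATE_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

# Canonical heavy side-chain atom names per residue type.
SIDECHAIN_ATOMS = {
    "GLY": set(), "ALA": {"CB"}, "SER": {"CB", "OG"}, "CYS": {"CB", "SG"},
    "THR": {"CB", "OG1", "CG2"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"}, "PRO": {"CB", "CG", "CD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
    "TRP": {"CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "ASP": {"CB", "CG", "OD1", "OD2"}, "GLU": {"CB", "CG", "CD", "OE1", "OE2"},
    "ASN": {"CB", "CG", "OD1", "ND2"}, "GLN": {"CB", "CG", "CD", "OE1", "NE2"},
    "HIS": {"CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "LYS": {"CB", "CG", "CD", "CE", "NZ"},
    "ARG": {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_structure(path: str | Path, skip_waters: bool = True) -> Structure:
    """Read ATOM/HETATM records from a PDB file.

    Alternate location A (or blank) is preferred; waters are skipped by
    default; hydrogens are retained but play no role in the distance-only
    contact criteria.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    model = next(bio_structure.get_models())
    for chain in model:
        for residue in chain:
            if skip_waters and residue.get_resname().strip() in WATER_NAMES:
                continue
            for atom in residue:
                if atom.is_disordered():
                    children = {a.get_altloc(): a
                                for a in atom.disordered_get_list()}
                    atom = children.get("A") or children.get(" ") \
                        or next(iter(children.values()))
                x, y, z = (float(c) for c in atom.coord)
                if not all(math.isfinite(c) for c in (x, y, z)):
                    raise ParseError(f"{path}: non-finite coordinate on "
                                     f"{atom.get_fullname().strip()}")
                atoms.append(Atom(
                    chain=chain.id,
                    res_number=residue.id[1],
                    res_name=residue.get_resname().strip(),
                    atom_name=atom.get_name().strip(),
                    element=(atom.element or "").strip(),
                    x=x, y=y, z=z))
    return Structure(atoms=atoms)


def _distance(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.xyz - b.xyz))


def _directed_contacts(atoms_a: list[Atom], atoms_b: list[Atom],
                       hbond_cutoff: float, salt_cutoff: float,
                       ) -> list[Contact]:
    contacts = []
    for a in atoms_a:
        donors = SIDECHAIN_DONORS.get(a.res_name, set())
        positives = POSITIVE_ATOMS.get(a.res_name, set())
        for b in atoms_b:
            acceptors = SIDECHAIN_ACCEPTORS.get(b.res_name, set())
            carboxylates = CARBOXYLATE_ATOMS.get(b.res_name, set())
            d = None
            if a.atom_name in donors and b.atom_name in acceptors:
                d = _distance(a, b)
                if 0 < d <= hbond_cutoff:
                    contacts.append(Contact(a.id, b.id, round(d, 3), "HBOND"))
            if a.atom_name in positives and b.atom_name in carboxylates:
                d = _distance(a, b) if d is None else d
                if 0 < d <= salt_cutoff:
                    contacts.append(Contact(a.id, b.id, round(d, 3), "SALT_BRIDGE"))
    return contacts


def find_contacts(structure: Structure,
                  residue_a: tuple[str, int], residue_b: tuple[str, int],
                  hbond_cutoff: float = 3.5, salt_cutoff: float = 4.0,
                  sidechain_only: bool = True) -> list[Contact]:
    """Hydrogen bonds and salt bridges between two residues.

    Distance-only criteria over donor/acceptor and charged-group atom-name
    sets; symmetric in its residue arguments (the donor side is always
    reported first in each contact).
    """
    atoms_a = structure.residue_atoms(*residue_a)
    atoms_b = structure.residue_atoms(*residue_b)
    if sidechain_only:
        atoms_a = [a for a in atoms_a if a.atom_name not in BACKBONE_ATOMS]
        atoms_b = [a for a in atoms_b if a.atom_name not in BACKBONE_ATOMS]
    contacts = (_directed_contacts(atoms_a, atoms_b, hbond_cutoff, salt_cutoff)
                + _directed_contacts(atoms_b, atoms_a, hbond_cutoff, salt_cutoff))
    # de-duplicate symmetric pairs (e.g. His-His donor/acceptor both ways)
    seen: dict[tuple, Contact] = {}
    for c in contacts:
        seen.setdefault((frozenset((c.donor_atom, c.acceptor_atom)), c.kind), c)
    return sorted(seen.values(), key=lambda c: (c.kind, c.donor_atom, c.acceptor_atom))


def residue_contacts(structure: Structure, chain: str, res_number: int,
                     hbond_cutoff: float = 3.5, salt_cutoff: float = 4.0,
                     ) -> list[Contact]:
    """All side-chain contacts between one residue and every other residue."""
    contacts: list[Contact] = []
    for other_chain, other_num, _ in structure.residues():
        if (other_chain, other_num) == (chain, res_number):
            continue
        contacts.extend(find_contacts(structure, (chain, res_number),
                                      (other_chain, other_num),
                                      hbond_cutoff, salt_cutoff))
    return contacts


@dataclass
class SubstitutionImpact:
    chain: str
    res_number: int
    original_residue: str
    substituted_residue: str
    contacts_before: list[Contact]
    contacts_retained: list[Contact]
    contacts_lost: list[Contact]

    def to_dict(self) -> dict:
        def ser(cs: list[Contact]) -> list[dict]:
            return [{"donor": c.donor_atom, "acceptor": c.acceptor_atom,
                     "distance_A": c.distance, "kind": c.kind} for c in cs]
        return {"chain": self.chain, "residue": self.res_number,
                "original": self.original_residue,
                "substituted": self.substituted_residue,
                "contacts_before": ser(self.contacts_before),
                "contacts_retained": ser(self.contacts_retained),
                "contacts_lost": ser(self.contacts_lost)}


def substitution_impact(structure: Structure, chain: str, res_number: int,
                        alt_residue: str, hbond_cutoff: float = 3.5,
                        salt_cutoff: float = 4.0) -> SubstitutionImpact:
    """Contacts lost when a residue is replaced, by atom-name intersection.

    The substituted side chain keeps only the atoms whose names exist in
    the replacement residue's canonical atom set (with the new residue
    type's donor/charge roles); contacts the shared atoms can no longer
    make are reported lost. No rotamer is modelled — for an
    arginine-to-histidine change this removes the guanidinium atoms (NE,
    CZ, NH1, NH2) and with them every contact they mediated.
    """
    alt = alt_residue.upper()
    if alt not in SIDECHAIN_ATOMS:
        raise ValueError(f"unknown residue name {alt_residue!r}")
    target_atoms = structure.residue_atoms(chain, res_number)
    original = target_atoms[0].res_name

    before = residue_contacts(structure, chain, res_number,
                              hbond_cutoff, salt_cutoff)

    shared = SIDECHAIN_ATOMS[alt] | BACKBONE_ATOMS
    mutated_atoms: list[Atom] = []
    for a in structure.atoms:
        if a.chain == chain and a.res_number == res_number:
            if a.atom_name not in shared:
                continue
            a = Atom(a.chain, a.res_number, alt, a.atom_name, a.element,
                     a.x, a.y, a.z)
        mutated_atoms.append(a)
    mutated = Structure(atoms=mutated_atoms)
    if any(a.chain == chain and a.res_number == res_number
           for a in mutated.atoms):
        after = residue_contacts(mutated, chain, res_number,
                                 hbond_cutoff, salt_cutoff)
    else:  # no shared atoms: the substituted side chain keeps nothing
        after = []

    def pair_key(c: Contact) -> tuple:
        def strip_res(atom_id: str) -> str:
            chain_part, res_part, name = atom_id.split("/")
            num = "".join(ch for ch in res_part if ch.isdigit() or ch == "-")
            return f"{chain_part}/{num}/{name}"
        return (frozenset((strip_res(c.donor_atom), strip_res(c.acceptor_atom))),
                c.kind)

    after_keys = {pair_key(c) for c in after}
    retained = [c for c in before if pair_key(c) in after_keys]
    lost = [c for c in before if pair_key(c) not in after_keys]
    return SubstitutionImpact(chain=chain, res_number=res_number,
                              original_residue=original,
                              substituted_residue=alt,
                              contacts_before=before,
                              contacts_retained=retained,
                              contacts_lost=lost)
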