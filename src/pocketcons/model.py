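"""In-memory atomic model shared by the structural modules.

The model is deliberately minimal: heavy-atom coordinates, author residue
numbering, and a separation of polymer residues from ligand poses and
monatomic ion sites.  Cryo-EM depositions of TRP channels carry no
hydrogens, so every distance-based operation downstream works on heavy
atoms only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Elements accepted as monatomic ion sites.
MONATOMIC_IONS = {
    "NA", "K", "CA", "MG", "ZN", "CL", "MN", "FE", "CU", "CO", "NI", "CD",
    "BR", "I", "CS", "RB", "BA", "SR", "LI",
}

STANDARD_AMINO_ACIDS = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in STANDARD_AMINO_ACIDS.items()}


@dataclass(frozen=True)
class Atom:
    """A single heavy atom with coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name!r}"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Residue:
    """A polymer residue identified by author numbering."""

    chain_id: str
    seq_num: int
    comp_name: str
    atoms: list[Atom]
    icode: str = ""
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.comp_name} {self.chain_id}{self.seq_num} has no atoms"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def one_letter(self) -> str:
        return STANDARD_AMINO_ACIDS.get(self.comp_name, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.comp_name} {self.seq_num}")

    @property
    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class LigandPose:
    """One bound instance of a small-molecule ligand."""

    comp_name: str
    pose_label: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"ligand pose {self.pose_label!r} has no atoms")

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]


@dataclass(frozen=True)
class IonSite:
    """A monatomic ion position (e.g. the Ca2+ site at the pocket mouth)."""

    element: str
    coords: tuple[float, float, float]
    site_label: str = ""

    def __post_init__(self) -> None:
        if self.element.upper() not in MONATOMIC_IONS:
            raise ValueError(f"{self.element!r} is not a recognised monatomic ion")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for ion {self.site_label!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of one residue within a named structure."""

    structure_id: str
    chain_id: str
    seq_num: int
    icode: str = ""
    comp_name: str = ""

    def __str__(self) -> str:  # e.g. "7wre:A:782:GLU"
        ic = self.icode or ""
        return f"{self.structure_id}:{self.chain_id}:{self.seq_num}{ic}:{self.comp_name}"


class ResidueSet:
    """Ordered, duplicate-free collection of :class:`ResidueRef`.

    Ordering is by (chain_id, seq_num, icode); duplicates (same structure,
    chain, number, insertion code) are collapsed.
    """

    def __init__(self, refs: "list[ResidueRef] | tuple[ResidueRef, ...]" = ()) -> None:
        seen: dict[tuple, ResidueRef] = {}
        for r in refs:
            seen.setdefault((r.structure_id, r.chain_id, r.seq_num, r.icode), r)
        self._refs = sorted(
            seen.values(), key=lambda r: (r.structure_id, r.chain_id, r.seq_num, r.icode)
        )

    def __iter__(self) -> Iterator[ResidueRef]:
        return iter(self._refs)

    def __len__(self) -> int:
        return len(self._refs)

    def __contains__(self, ref: ResidueRef) -> bool:
        return any(
            (r.structure_id, r.chain_id, r.seq_num, r.icode)
            == (ref.structure_id, ref.chain_id, ref.seq_num, ref.icode)
            for r in self._refs
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueSet):
            return NotImplemented
        return self.keys() == other.keys()

    def __repr__(self) -> str:
        return f"ResidueSet({[str(r) for r in self._refs]})"

    def keys(self) -> set[tuple]:
        return {(r.structure_id, r.chain_id, r.seq_num, r.icode) for r in self._refs}

    def seq_nums(self) -> list[int]:
        return [r.seq_num for r in self._refs]

    def union(self, other: "ResidueSet") -> "ResidueSet":
        return ResidueSet(list(self._refs) + list(other._refs))

    def issubset(self, other: "ResidueSet") -> bool:
        return self.keys() <= other.keys()


@dataclass
class Structure:
    """A parsed atomic model: polymer chains + ligand poses + ion sites."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[LigandPose] = field(default_factory=list)
    ions: list[IonSite] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [r.key for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue keys in chain {cid!r}")
            ordered = sorted(keys, key=lambda k: (k[1], k[2]))
            if keys != ordered:
                self.chains[cid] = sorted(residues, key=lambda r: (r.seq_num, r.icode))

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def residues(self) -> Iterator[Residue]:
        for cid in sorted(self.chains):
            yield from self.chains[cid]

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"structure {self.id!r} has no chain {chain_id!r}; "
                f"available: {sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id):
            if r.seq_num == seq_num and r.icode == icode:
                return r
        raise KeyError(f"no residue {seq_num}{icode} in chain {chain_id} of {self.id}")

    def ref(self, residue: Residue) -> ResidueRef:
        return ResidueRef(
            structure_id=self.id,
            chain_id=residue.chain_id,
            seq_num=residue.seq_num,
            icode=residue.icode,
            comp_name=residue.comp_name,
        )
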