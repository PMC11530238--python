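"""Reading and writing atomic models (mmCIF / PDB) via gemmi.

Author (``auth_``) numbering is authoritative throughout: the literature on
these channels cites residues by author numbers (G805, A867), so the parsed
model preserves them verbatim.  Only model 1 of multi-model files is used,
and for alternate locations the highest-occupancy conformer is kept
(ties broken by lexicographically smallest altloc).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import gemmi

from .model import (
    MONATOMIC_IONS,
    Atom,
    IonSite,
    LigandPose,
    Residue,
    ResidueRef,
    ResidueSet,
    Structure,
)

__all__ = [
    "load_structure",
    "select_residues",
    "extract_ligand_poses",
    "write_pdb",
    "polymer_sequence",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed into a usable model."""


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, then smallest altloc."""
    best: dict[str, Atom] = {}
    for a in atoms:
        prev = best.get(a.name)
        if prev is None or (a.occupancy, _neg(a.altloc)) > (prev.occupancy, _neg(prev.altloc)):
            best[a.name] = a
    # preserve original atom order
    seen: set[str] = set()
    out = []
    for a in atoms:
        if a.name in best and a.name not in seen:
            out.append(best[a.name])
            seen.add(a.name)
    return out


def _is_amino_acid(comp_name: str) -> bool:
    info = gemmi.find_tabulated_residue(comp_name)
    return bool(info and info.is_amino_acid())


def _neg(altloc: str) -> tuple:
    # sort helper: smaller altloc should win ties -> invert ordering
    return tuple(-ord(c) for c in altloc)


def load_structure(path: str | Path, format_hint: str = "auto") -> Structure:
    """Parse an mmCIF or PDB file into a :class:`~pocketcons.model.Structure`.

    Polymer residues, multi-atom non-polymer components (ligand poses) and
    monatomic components (ion sites) are separated.  Waters are dropped.

    Parameters
    ----------
    path:
        Coordinate file.
    format_hint:
        ``"mmcif"``, ``"pdb"`` or ``"auto"`` (by extension/content).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format_hint == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif format_hint == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif format_hint == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format_hint {format_hint!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError on bad input
        if isinstance(exc, ValueError) and "format_hint" in str(exc):
            raise
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]  # model 1 only

    out = Structure(id=(st.name or path.stem).lower())
    out.meta["source_path"] = str(path)
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            atoms = []
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name.upper(),
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
            if not atoms:
                continue
            atoms = _dedupe_altlocs(atoms)
            name = res.name.upper()
            if name == "HOH":
                continue
            is_ion = len(atoms) == 1 and (
                name in MONATOMIC_IONS or atoms[0].element in MONATOMIC_IONS
            )
            if is_ion and het:
                out.ions.append(
                    IonSite(
                        element=atoms[0].element,
                        coords=atoms[0].coords,
                        site_label=f"{name}:{chain.name}:{res.seqid.num}",
                    )
                )
            elif het and not _is_amino_acid(name):
                out.ligands.append(
                    LigandPose(
                        comp_name=name,
                        pose_label=f"{out.id}:{chain.name}:{res.seqid.num}",
                        atoms=atoms,
                    )
                )
            else:
                out.chains.setdefault(chain.name, []).append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        comp_name=name,
                        atoms=atoms,
                        is_polymer=True,
                    )
                )
    if not out.chains and not out.ligands and not out.ions:
        raise StructureParseError(f"{path} parsed to an empty model")
    # enforce residue ordering within chains
    out.__post_init__()
    return out


def select_residues(
    s: Structure, chain_id: str, seq_range: tuple[int, int]
) -> ResidueSet:
    """Residues of ``chain_id`` with author seq_num in the inclusive range.

    Residues missing from the model are silently absent; the count of
    missing positions is reported via a warning when the selection is empty.
    """
    lo, hi = seq_range
    if lo > hi:
        raise ValueError(f"empty range {seq_range}")
    residues = s.chain(chain_id)
    picked = [s.ref(r) for r in residues if lo <= r.seq_num <= hi]
    if not picked:
        warnings.warn(
            f"selection {chain_id}[{lo},{hi}] of {s.id} is empty", stacklevel=2
        )
    return ResidueSet(picked)


def extract_ligand_poses(s: Structure, selector: str) -> list[LigandPose]:
    """All ligand poses whose component name matches ``selector`` (case-insensitive)."""
    if not selector:
        raise ValueError("empty ligand selector")
    return [p for p in s.ligands if p.comp_name.upper() == selector.upper()]


def extract_ligand_poses_by_formula(
    s: Structure, formula: dict[str, int]
) -> list[LigandPose]:
    """Ligand poses whose heavy-atom composition matches ``formula``
    (e.g. ``{"C": 16, "N": 3, "O": 4}``).  Useful when the chemical
    component ID of a deposited ligand is not known a priori."""
    want = {k.upper(): int(v) for k, v in formula.items()}
    out = []
    for p in s.ligands:
        comp: dict[str, int] = {}
        for a in p.heavy_atoms:
            comp[a.element.upper()] = comp.get(a.element.upper(), 0) + 1
        if comp == want:
            out.append(p)
    return out


def polymer_sequence(s: Structure, chain_id: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the parallel author numbering."""
    residues = s.chain(chain_id)
    return "".join(r.one_letter for r in residues), [r.seq_num for r in residues]


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the model as PDB text (fixture/interchange use).

    Coordinates are written at the format's native 0.001 Å precision.
    """
    lines = []
    serial = 1
    for cid in sorted(s.chains):
        for r in s.chains[cid]:
            for a in r.atoms:
                lines.append(_pdb_line("ATOM", serial, a, r.comp_name, cid, r.seq_num, r.icode))
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    for i, lig in enumerate(s.ligands, start=1):
        chain = lig.pose_label.split(":")[1] if ":" in lig.pose_label else "X"
        for a in lig.atoms:
            lines.append(_pdb_line("HETATM", serial, a, lig.comp_name, chain, i, ""))
            serial += 1
    for i, ion in enumerate(s.ions, start=1):
        at = Atom(name=ion.element, element=ion.element, coords=ion.coords)
        lines.append(_pdb_line("HETATM", serial, at, ion.element, "Z", i, ""))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_line(
    rec: str, serial: int, a: Atom, comp: str, chain: str, seq: int, icode: str
) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    x, y, z = a.coords
    return (
        f"{rec:<6s}{serial:5d} {name:<4s}{'':1s}{comp:<3s} {chain:1s}"
        f"{seq:4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )
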