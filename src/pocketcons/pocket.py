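"""Binding-pocket definition from ligand proximity and ion coordination.

The pocket on a reference channel structure is the union, over all accepted
ligand poses, of residues with any heavy atom within ``ligand_cutoff``
(inclusive) of any ligand heavy atom, optionally extended by residues whose
O/N atoms coordinate a bound ion (the Ca2+ cofactor site at the cytoplasmic
mouth of the pocket).  A geometric interaction fingerprint classifies each
pocket residue's contacts with the ligand (hydrophobic, H-bond donor /
acceptor, ionic, aromatic) from conventional distance/angle criteria.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import IonSite, LigandPose, ResidueRef, ResidueSet, Structure

__all__ = [
    "PocketParams",
    "PocketDefinition",
    "Fingerprint",
    "contact_residues",
    "ion_coordinators",
    "define_pocket",
    "interaction_fingerprint",
]


@dataclass
class PocketParams:
    """Cutoffs and policies for pocket definition (distances in Å, inclusive)."""

    ligand_cutoff: float = 4.0
    ion_cutoff: float = 4.0
    per_protomer_policy: str = "union"  # or "single_chain"
    include_ion_coordinators: bool = True

    def __post_init__(self) -> None:
        if self.ligand_cutoff <= 0 or self.ion_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.per_protomer_policy not in ("union", "single_chain"):
            raise ValueError(f"unknown policy {self.per_protomer_policy!r}")


@dataclass
class PocketDefinition:
    """Ordered pocket residues on the reference, with per-residue provenance."""

    reference_id: str
    residues: ResidueSet
    provenance: dict[tuple, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.residues:
            key = (r.chain_id, r.seq_num, r.icode)
            if not self.provenance.get(key):
                raise ValueError(f"pocket residue {r} lacks provenance tags")

    def tags(self, ref: ResidueRef) -> set[str]:
        return self.provenance[(ref.chain_id, ref.seq_num, ref.icode)]

    @property
    def seq_nums(self) -> list[int]:
        return sorted({r.seq_num for r in self.residues})


# --- small built-in residue chemistry table ------------------------------
# Heavy-atom roles per standard residue; backbone N is a donor, O an acceptor.
_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"},
}
_CHARGED = {  # formal charge of the side-chain group
    "ASP": (-1, {"OD1", "OD2", "CG"}),
    "GLU": (-1, {"OE1", "OE2", "CD"}),
    "LYS": (+1, {"NZ"}),
    "ARG": (+1, {"NE", "NH1", "NH2", "CZ"}),
    "HIS": (+1, {"ND1", "NE2", "CE1", "CD2", "CG"}),
}
_AROMATIC_RINGS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}
_KNOWN_CHEMISTRY = (
    set(_DONORS) | set(_ACCEPTORS) | set(_CHARGED) | set(_AROMATIC_RINGS)
    | {"ALA", "GLY", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "SER", "THR", "CYS"}
)


@dataclass
class Fingerprint:
    """Per-residue interaction labels plus the geometry of each contact."""

    labels: dict[tuple, set[str]] = field(default_factory=dict)
    geometry: list[dict] = field(default_factory=list)

    def labels_for(self, ref: ResidueRef) -> set[str]:
        return self.labels.get((ref.chain_id, ref.seq_num, ref.icode), set())


def _heavy_coords(pose: LigandPose) -> np.ndarray:
    coords = pose.coords_array()[
        [i for i, a in enumerate(pose.atoms) if a.element.upper() != "H"]
    ]
    if coords.size == 0:
        raise ValueError(f"pose {pose.pose_label!r} has no heavy atoms")
    return coords


def contact_residues(s: Structure, pose: LigandPose, cutoff: float = 4.0) -> ResidueSet:
    """Polymer residues with ≥1 heavy atom within ``cutoff`` (≤) of the ligand."""
    lig = _heavy_coords(pose)
    tree = cKDTree(lig)
    hits: list[ResidueRef] = []
    for res in s.residues():
        coords = res.coords_array()
        d, _ = tree.query(coords, k=1)
        if float(np.min(d)) <= cutoff:
            hits.append(s.ref(res))
    return ResidueSet(hits)


def ion_coordinators(s: Structure, ion: IonSite, cutoff: float = 4.0) -> ResidueSet:
    """Residues with an O or N heavy atom within ``cutoff`` of the ion position.

    Coordination chemistry of Ca2+ (and related hard cations) is through
    electronegative O/N, so carbon contacts are ignored.
    """
    hits: list[ResidueRef] = []
    for res in s.residues():
        for a in res.atoms:
            if a.element not in ("O", "N"):
                continue
            if np.linalg.norm(a.xyz - ion.xyz) <= cutoff:
                hits.append(s.ref(res))
                break
    if not hits:
        warnings.warn(
            f"no residues coordinate ion {ion.site_label!r} within {cutoff} Å",
            stacklevel=2,
        )
    return ResidueSet(hits)


def define_pocket(
    poses: list[tuple[Structure, LigandPose]],
    ions: list[tuple[Structure, IonSite]] | None = None,
    params: PocketParams | None = None,
    numbering_map: dict[str, dict[tuple, tuple]] | None = None,
    reference_id: str | None = None,
) -> PocketDefinition:
    """Union pocket over ligand poses and (optionally) ion coordinators.

    Parameters
    ----------
    poses:
        ``(structure, pose)`` pairs; contacts from every pose are unioned.
    ions:
        ``(structure, ion)`` pairs whose coordinating residues are added
        when ``params.include_ion_coordinators``.
    numbering_map:
        For poses from structures other than the reference:
        ``{structure_id: {(chain, seq, icode): (ref_chain, ref_seq, ref_icode)}}``
        mapping their residues onto reference numbering.
    reference_id:
        Accession whose numbering anchors the pocket; defaults to the first
        pose's structure.
    """
    if not poses:
        raise ValueError("at least one ligand pose is required")
    params = params or PocketParams()
    ions = ions or []
    ref_id = reference_id or poses[0][0].id
    numbering_map = numbering_map or {}

    # Under the "union" policy, contacts from all protomer chains collapse
    # onto residue identity (seq_num, icode): the channel is C4-symmetric and
    # the pocket is reported once per channel, not per protomer.
    refs: dict[tuple, ResidueRef] = {}
    tags: dict[tuple, set[str]] = {}

    def _to_reference(s: Structure, r: ResidueRef, tag: str) -> None:
        key = (r.chain_id, r.seq_num, r.icode)
        if s.id != ref_id:
            mapping = numbering_map.get(s.id)
            if mapping is None:
                raise ValueError(
                    f"numbering_map required for pose structure {s.id!r} != "
                    f"reference {ref_id!r}"
                )
            if key not in mapping:
                return  # residue has no reference equivalent
            key = mapping[key]
        r = ResidueRef(ref_id, key[0], key[1], key[2], r.comp_name)
        collapse = (
            (key[1], key[2]) if params.per_protomer_policy == "union" else key
        )
        refs.setdefault(collapse, r)
        tags.setdefault(collapse, set()).add(tag)

    for s, pose in poses:
        tag = f"contact:{pose.pose_label}"
        for r in contact_residues(s, pose, params.ligand_cutoff):
            _to_reference(s, r, tag)
    if params.include_ion_coordinators:
        for s, ion in ions:
            for r in ion_coordinators(s, ion, params.ion_cutoff):
                _to_reference(s, r, "ion_coordinator")

    provenance = {
        (refs[k].chain_id, refs[k].seq_num, refs[k].icode): tags[k] for k in refs
    }
    return PocketDefinition(
        reference_id=ref_id,
        residues=ResidueSet(list(refs.values())),
        provenance=provenance,
    )


def _apolar_carbons(res) -> list[np.ndarray]:
    polarised = set()
    comp = res.comp_name
    if comp in _CHARGED:
        polarised |= _CHARGED[comp][1]
    return [
        a.xyz
        for a in res.atoms
        if a.element == "C" and a.name not in ("C",) and a.name not in polarised
    ]


def interaction_fingerprint(
    s: Structure,
    pose: LigandPose,
    pocket: ResidueSet,
    ligand_charged_atoms: dict[str, int] | None = None,
    ligand_donors: set[str] | None = None,
    ligand_acceptors: set[str] | None = None,
    ligand_ring_atoms: list[list[str]] | None = None,
    hbond_cutoff: float = 3.5,
    hbond_angle_min: float = 120.0,
    ionic_cutoff: float = 4.5,
    hydrophobic_cutoff: float = 4.0,
    aromatic_cutoff: float = 5.5,
) -> Fingerprint:
    """Classify pocket-residue/ligand contacts by geometric criteria.

    H-bonds: donor–acceptor heavy-atom distance ≤ ``hbond_cutoff`` with the
    donor-antecedent angle (a proxy for D–H…A in H-free models) ≥
    ``hbond_angle_min``.  Ionic: opposite formal charges with charged-group
    heavy atoms ≤ ``ionic_cutoff``.  Hydrophobic: apolar C–C ≤
    ``hydrophobic_cutoff``.  Aromatic: ring-centroid distance ≤
    ``aromatic_cutoff``.  Ligand chemistry (charges, donors/acceptors,
    rings) comes from configuration, never from hard-coded component IDs.
    """
    ligand_charged_atoms = ligand_charged_atoms or {}
    ligand_donors = ligand_donors or set()
    ligand_acceptors = ligand_acceptors or set()
    ligand_ring_atoms = ligand_ring_atoms or []

    lig_by_name = {a.name: a for a in pose.heavy_atoms}
    lig_coords = {n: a.xyz for n, a in lig_by_name.items()}
    # default ligand acceptor/donor inference: O and N heavy atoms accept;
    # N donates (no hydrogens in the model to say otherwise).
    inferred_acceptors = {n for n, a in lig_by_name.items() if a.element in ("O", "N")}
    inferred_donors = {n for n, a in lig_by_name.items() if a.element == "N"}
    lig_acc = ligand_acceptors or inferred_acceptors
    lig_don = ligand_donors or inferred_donors

    ring_centroids = [
        np.mean([lig_coords[n] for n in ring if n in lig_coords], axis=0)
        for ring in ligand_ring_atoms
        if any(n in lig_coords for n in ring)
    ]
    lig_apolar = [a.xyz for a in pose.heavy_atoms if a.element == "C"]

    fp = Fingerprint()
    residues = {(r.chain_id, r.seq_num, r.icode): r for r in pocket}
    for res in s.residues():
        key = (res.chain_id, res.seq_num, res.icode)
        if key not in residues:
            continue
        ref = s.ref(res)
        labels: set[str] = set()
        comp = res.comp_name
        if comp not in _KNOWN_CHEMISTRY:
            warnings.warn(f"unknown chemistry for {comp}; labelled unclassified", stacklevel=2)
            labels.add("unclassified")

        def record(label: str, dist: float, angle: float | None = None) -> None:
            labels.add(label)
            rec = {"residue": str(ref), "label": label, "distance": round(float(dist), 3)}
            if angle is not None:
                rec["angle"] = round(float(angle), 1)
            fp.geometry.append(rec)

        # hydrogen bonds, residue as donor
        donors = _DONORS.get(comp, set()) | {"N"}
        for dn in donors:
            try:
                d_at = res.atom(dn)
            except KeyError:
                continue
            ante = _antecedent(res, dn)
            for an in lig_acc:
                dist = float(np.linalg.norm(d_at.xyz - lig_coords[an]))
                if dist <= hbond_cutoff:
                    ang = _angle(ante, d_at.xyz, lig_coords[an]) if ante is not None else 180.0
                    if ang >= hbond_angle_min:
                        record("hbond_donor", dist, ang)
        # hydrogen bonds, residue as acceptor
        acceptors = _ACCEPTORS.get(comp, set()) | {"O"}
        for an in acceptors:
            try:
                a_at = res.atom(an)
            except KeyError:
                continue
            for dn in lig_don:
                dist = float(np.linalg.norm(a_at.xyz - lig_coords[dn]))
                if dist <= hbond_cutoff:
                    record("hbond_acceptor", dist)
        # ionic
        if comp in _CHARGED and ligand_charged_atoms:
            charge, group = _CHARGED[comp]
            for gname in group:
                try:
                    g_at = res.atom(gname)
                except KeyError:
                    continue
                for ln, lcharge in ligand_charged_atoms.items():
                    if ln not in lig_coords or lcharge * charge >= 0:
                        continue
                    dist = float(np.linalg.norm(g_at.xyz - lig_coords[ln]))
                    if dist <= ionic_cutoff:
                        record("ionic", dist)
        # hydrophobic
        done_hydro = False
        for rc in _apolar_carbons(res):
            for lc in lig_apolar:
                dist = float(np.linalg.norm(rc - lc))
                if dist <= hydrophobic_cutoff:
                    record("hydrophobic", dist)
                    done_hydro = True
                    break
            if done_hydro:
                break
        # aromatic
        if comp in _AROMATIC_RINGS and ring_centroids:
            names = _AROMATIC_RINGS[comp]
            pts = [res.atom(n).xyz for n in names if _has_atom(res, n)]
            if len(pts) >= 3:
                cen = np.mean(pts, axis=0)
                for rc in ring_centroids:
                    dist = float(np.linalg.norm(cen - rc))
                    if dist <= aromatic_cutoff:
                        record("aromatic", dist)
        if labels:
            fp.labels[key] = labels
    return fp


def _has_atom(res, name: str) -> bool:
    return any(a.name == name for a in res.atoms)


_ANTECEDENT = {
    "N": "CA", "NE": "CD", "NH1": "CZ", "NH2": "CZ", "ND2": "CG", "NE2": "CD",
    "ND1": "CG", "NZ": "CE", "OG": "CB", "OG1": "CB", "NE1": "CD1", "OH": "CZ",
    "SG": "CB",
}


def _antecedent(res, donor_name: str) -> np.ndarray | None:
    ante = _ANTECEDENT.get(donor_name)
    if ante is None or not _has_atom(res, ante):
        return None
    return res.atom(ante).xyz


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
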