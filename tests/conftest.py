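import numpy as np
import pytest

from pocketcons import (
    Atom,
    BundleSpec,
    GatingParams,
    LigandPose,
    Protocol,
    Residue,
    Structure,
    make_helix_bundle,
)


@pytest.fixture(scope="session")
def bundle18():
    """Four-helix bundle with an 18-residue planted pocket (seed 1)."""
    return make_helix_bundle(BundleSpec(pocket_size=18, seed=1))


@pytest.fixture(scope="session")
def noiseless_protocol():
    return Protocol()


@pytest.fixture()
def quiet_gating():
    return GatingParams(noise_sd=0.0, leak_g=0.0, seed=0)


def make_residue(chain, seq, comp, atom_specs):
    """atom_specs: list of (name, element, xyz)."""
    return Residue(
        chain_id=chain,
        seq_num=seq,
        comp_name=comp,
        atoms=[Atom(name=n, element=e, coords=tuple(map(float, c))) for n, e, c in atom_specs],
    )


def make_ligand(atom_specs, comp="LIG", label="toy:A:1"):
    return LigandPose(
        comp_name=comp,
        pose_label=label,
        atoms=[Atom(name=n, element=e, coords=tuple(map(float, c))) for n, e, c in atom_specs],
    )


def toy_structure(residues, ligands=(), ions=(), sid="toy"):
    chains = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    return Structure(id=sid, chains=chains, ligands=list(ligands), ions=list(ions))


@pytest.fixture()
def helpers():
    class H:
        residue = staticmethod(make_residue)
        ligand = staticmethod(make_ligand)
        structure = staticmethod(toy_structure)
    return H


def brute_force_contacts(s, pose, cutoff):
    """All-pairs distance scan; the independent oracle for contact detection."""
    lig = np.array([a.coords for a in pose.atoms if a.element.upper() != "H"])
    hits = []
    for res in s.residues():
        pts = res.coords_array()
        d = np.sqrt(((pts[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2))
        if d.min() <= cutoff:
            hits.append(s.ref(res))
    return hits
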