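"""Synthetic fixtures with known ground truth for both pipeline branches.

Structural side: idealised α-helical bundles (rise 1.5 Å per residue,
100° per residue) arranged like a peripheral four-helix domain, with a
planted multi-atom ligand positioned so that an exactly controlled set of
residues lies within the 4 Å contact cutoff, plus controlled residue
substitutions, coordinate noise and deletions for alignment/identity
recovery tests.  Residues are poly-Ala-like backbones carrying a
single-atom side-chain marker: pocket and identity logic needs residue
identity and geometry, not rotamer realism.

Electrophysiology side: a phenomenological gating simulator (Boltzmann
voltage dependence, single-exponential relaxation, instantaneous
component, linear leak, Gaussian noise) generating voltage-step current
families and wash-out timecourses whose every downstream feature is
analytically known.

All generators are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ephys import Condition, CurrentFamily, Protocol, Sweep, WashTimecourse
from .model import Atom, LigandPose, Residue, ResidueRef, ResidueSet, Structure

__all__ = [
    "BundleSpec",
    "BundleTruth",
    "GatingParams",
    "make_helix_bundle",
    "mutate_pocket",
    "perturb_structure",
    "delete_residues",
    "simulate_family",
    "simulate_wash",
    "default_gating",
]

_AA20 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class BundleSpec:
    """Recipe for a toy helical-bundle structure with a planted pocket."""

    n_helices: int = 4
    helix_len: int = 15
    bundle_radius: float = 8.5  # Å, helix axes from the bundle axis
    helix_radius: float = 2.3  # Å, Cα from the helix axis
    rise_per_res: float = 1.5  # Å
    twist_per_res: float = 100.0  # degrees
    pocket_size: int = 18
    ligand_atoms: int = 6  # core atoms, besides one arm atom per pocket residue
    substitutions: list[tuple[int, str]] = field(default_factory=list)
    noise_sd: float = 0.0  # Å, Gaussian jitter on every atom
    seed: int = 0
    structure_id: str = "bundle"

    def __post_init__(self) -> None:
        total = self.n_helices * self.helix_len
        if not (0 < self.pocket_size <= total):
            raise ValueError(f"pocket_size must be in (0, {total}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BundleTruth:
    """Planted ground truth accompanying a generated bundle."""

    pocket: ResidueSet
    sequence: dict[int, str]  # seq_num -> comp_name
    correspondence: dict[int, int]  # seq_num -> seq_num (identity for the source)


def _helix_coords(spec: BundleSpec, helix_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Cα and marker coordinates of one helix (antiparallel arrangement)."""
    phi0 = 2.0 * np.pi * helix_idx / spec.n_helices
    axis_xy = spec.bundle_radius * np.array([np.cos(phi0), np.sin(phi0)])
    n = spec.helix_len
    k = np.arange(n)
    theta = np.deg2rad(spec.twist_per_res) * k + phi0 + np.pi  # start facing inward
    z = spec.rise_per_res * (k - (n - 1) / 2.0)
    if helix_idx % 2 == 1:
        z = -z  # antiparallel
    ca = np.column_stack(
        [
            axis_xy[0] + spec.helix_radius * np.cos(theta),
            axis_xy[1] + spec.helix_radius * np.sin(theta),
            z,
        ]
    )
    # marker 1.5 Å further out along the helix-radial direction
    marker = ca.copy()
    marker[:, 0] += 1.5 * np.cos(theta)
    marker[:, 1] += 1.5 * np.sin(theta)
    return ca, marker


def make_helix_bundle(spec: BundleSpec) -> tuple[Structure, BundleTruth]:
    """Build the bundle and plant a ligand touching exactly ``pocket_size`` residues.

    The ligand has a small core at the bundle centroid plus one "arm" atom
    per pocket residue, placed on the segment from the residue's nearest
    atom toward the centroid so the contact distance is under the 4 Å
    cutoff.  Construction is validated by a brute-force distance scan and
    raises if the requested pocket is geometrically infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    cas, markers = [], []
    for h in range(spec.n_helices):
        ca, mk = _helix_coords(spec, h)
        cas.append(ca)
        markers.append(mk)
    ca_all = np.concatenate(cas)
    mk_all = np.concatenate(markers)
    n_total = len(ca_all)

    # residue identities: deterministic draw, then requested substitutions
    seq = {i + 1: _AA20[int(rng.integers(len(_AA20)))] for i in range(n_total)}
    for pos, aa in spec.substitutions:
        if pos not in seq:
            raise ValueError(f"substitution position {pos} outside 1..{n_total}")
        seq[pos] = aa

    if spec.noise_sd > 0:
        ca_all = ca_all + rng.normal(0.0, spec.noise_sd, ca_all.shape)
        mk_all = mk_all + rng.normal(0.0, spec.noise_sd, mk_all.shape)

    centroid = np.zeros(3)
    # the pocket_size residues whose atoms come closest to the bundle axis
    min_d = np.minimum(
        np.linalg.norm(ca_all - centroid, axis=1), np.linalg.norm(mk_all - centroid, axis=1)
    )
    order = np.argsort(min_d, kind="stable")
    chosen = np.sort(order[: spec.pocket_size])
    chosen_set = set(int(i) for i in chosen)

    core = [
        Atom(name=f"C{i+1}", element="C", coords=tuple(centroid + 0.5 * _unit(i)))
        for i in range(spec.ligand_atoms)
    ]
    lig_atoms = None
    for arm_dist in (3.7, 3.4, 3.0, 2.6, 2.2):
        arms = []
        for k, i in enumerate(chosen):
            anchor = (
                mk_all[i]
                if np.linalg.norm(mk_all[i]) <= np.linalg.norm(ca_all[i])
                else ca_all[i]
            )
            direction = centroid - anchor
            direction = direction / np.linalg.norm(direction)
            arms.append(
                Atom(
                    name=f"A{k+1}",
                    element="C",
                    coords=tuple(anchor + arm_dist * direction),
                )
            )
        candidate = core + arms
        lig_xyz = np.array([a.coords for a in candidate])
        within = set()
        for i in range(n_total):
            pts = np.vstack([ca_all[i], mk_all[i]])
            d = np.min(np.linalg.norm(pts[:, None, :] - lig_xyz[None, :, :], axis=2))
            if d <= 4.0:
                within.add(i)
        if within == chosen_set:
            lig_atoms = candidate
            break
    if lig_atoms is None:
        raise ValueError(
            f"pocket_size {spec.pocket_size} infeasible for this bundle geometry"
        )

    residues = []
    for i in range(n_total):
        seq_num = i + 1
        residues.append(
            Residue(
                chain_id="A",
                seq_num=seq_num,
                comp_name=seq[seq_num],
                atoms=[
                    Atom(name="CA", element="C", coords=tuple(ca_all[i])),
                    Atom(name="CB", element="C", coords=tuple(mk_all[i])),
                ],
            )
        )
    s = Structure(
        id=spec.structure_id,
        chains={"A": residues},
        ligands=[LigandPose(comp_name="LIG", pose_label=f"{spec.structure_id}:A:1", atoms=lig_atoms)],
    )
    pocket_refs = [
        ResidueRef(spec.structure_id, "A", int(i) + 1, "", seq[int(i) + 1]) for i in chosen
    ]
    truth = BundleTruth(
        pocket=ResidueSet(pocket_refs),
        sequence=dict(seq),
        correspondence={i + 1: i + 1 for i in range(n_total)},
    )
    return s, truth


def _unit(i: int) -> np.ndarray:
    angles = np.deg2rad(60.0 * i)
    return np.array([np.cos(angles), np.sin(angles), 0.25 * ((-1) ** i)])


def mutate_pocket(
    structure: Structure, truth: BundleTruth, k: int, seed: int = 0
) -> tuple[Structure, BundleTruth, int]:
    """Relabel ``k`` pocket residues to different amino acids.

    Returns the mutated structure, its updated truth, and the expected
    identity percent ``round(100 · (m − k) / m)`` against the source.
    """
    m = len(truth.pocket)
    if k > m:
        raise ValueError(f"k={k} exceeds pocket size {m}")
    rng = np.random.default_rng(seed)
    pocket_nums = [r.seq_num for r in truth.pocket]
    to_mutate = sorted(rng.choice(pocket_nums, size=k, replace=False).tolist())
    new_seq = dict(truth.sequence)
    for pos in to_mutate:
        choices = [a for a in _AA20 if a != new_seq[pos]]
        new_seq[pos] = choices[int(rng.integers(len(choices)))]
    new_chain = []
    for r in structure.chain("A"):
        new_chain.append(
            Residue(
                chain_id=r.chain_id,
                seq_num=r.seq_num,
                comp_name=new_seq[r.seq_num],
                atoms=list(r.atoms),
                icode=r.icode,
            )
        )
    mutated = Structure(
        id=structure.id + f"_mut{k}",
        chains={"A": new_chain},
        ligands=list(structure.ligands),
        ions=list(structure.ions),
    )
    new_truth = BundleTruth(
        pocket=ResidueSet(
            [ResidueRef(mutated.id, "A", r.seq_num, "", new_seq[r.seq_num]) for r in truth.pocket]
        ),
        sequence=new_seq,
        correspondence=dict(truth.correspondence),
    )
    from .conservation import round_half_away

    expected_percent = round_half_away(100.0 * (m - k) / m)
    return mutated, new_truth, expected_percent


def perturb_structure(
    structure: Structure,
    noise_sd: float = 0.0,
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    new_id: str | None = None,
) -> Structure:
    """Apply Gaussian coordinate noise then a rigid motion to every atom."""
    rng = np.random.default_rng(seed)
    ax, ay, az = np.deg2rad(rotation_deg)
    Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    Rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    t = np.asarray(translation, dtype=float)

    def move(xyz: tuple) -> tuple:
        p = np.asarray(xyz) + (rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else 0.0)
        return tuple(R @ p + t)

    chains = {}
    for cid, residues in structure.chains.items():
        chains[cid] = [
            Residue(
                chain_id=r.chain_id,
                seq_num=r.seq_num,
                comp_name=r.comp_name,
                icode=r.icode,
                atoms=[
                    Atom(a.name, a.element, move(a.coords), a.occupancy, a.altloc)
                    for a in r.atoms
                ],
            )
            for r in residues
        ]
    ligands = [
        LigandPose(
            comp_name=p.comp_name,
            pose_label=p.pose_label,
            atoms=[Atom(a.name, a.element, move(a.coords), a.occupancy, a.altloc) for a in p.atoms],
        )
        for p in structure.ligands
    ]
    from .model import IonSite

    ions = [IonSite(i.element, move(i.coords), i.site_label) for i in structure.ions]
    return Structure(
        id=new_id or structure.id + "_pert",
        chains=chains,
        ligands=ligands,
        ions=ions,
    )


def delete_residues(
    structure: Structure, chain_id: str, seq_nums: list[int], new_id: str | None = None
) -> Structure:
    """Remove residues (planted internal deletion for gap-recovery tests)."""
    drop = set(seq_nums)
    chains = dict(structure.chains)
    chains[chain_id] = [r for r in structure.chain(chain_id) if r.seq_num not in drop]
    return Structure(
        id=new_id or structure.id + "_del",
        chains=chains,
        ligands=list(structure.ligands),
        ions=list(structure.ions),
    )


# ------------------------- gating simulator ------------------------------

@dataclass
class GatingParams:
    """Phenomenological gating model for one recording condition.

    Open probability relaxes mono-exponentially toward a Boltzmann
    equilibrium: Po_inf(V) = 1 / (1 + exp((V_half − V) / slope)).  On a
    step, the instantaneous component jumps to
    ``inst_share · Po_inf(V) + (1 − inst_share) · Po_hold`` and the
    remainder relaxes with ``tau_ms``.
    """

    g_max: float = 2.0  # nS
    V_rev: float = 0.0  # mV
    V_half: float = 80.0  # mV
    slope: float = 30.0  # mV
    tau_ms: float = 40.0
    inst_share: float = 0.3
    leak_g: float = 0.05  # nS
    noise_sd: float = 2.0  # pA
    unbind_tau_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_max <= 0 or self.tau_ms <= 0:
            raise ValueError("g_max and tau_ms must be positive")
        if not (0.0 <= self.inst_share <= 1.0):
            raise ValueError("inst_share must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def po_inf(self, V: float) -> float:
        return 1.0 / (1.0 + np.exp((self.V_half - V) / self.slope))


def default_gating(condition: Condition, seed: int = 0) -> GatingParams:
    """Study-condition stand-ins for Ca2+/icilin-dependent gating.

    Emulates the qualitative behaviour of a Ca2+-activated, outwardly
    rectifying channel modulated by a cooling agent: rising intracellular
    Ca2+ increases maximal conductance (half-activating near 500 µM) and
    the instantaneous share; the cooling agent left-shifts voltage
    activation and raises the instantaneous share, dramatically so on the
    sensitised (Ala→Gly) background and not at all on the binding-deficient
    (Arg→His) background.  Functional form and numbers are this module's
    own phenomenology, chosen to give the analysis code ground truth.
    """
    ca, ic = condition.ca_uM, condition.icilin_uM
    ca_act = ca / (ca + 500.0) if ca > 0 else 0.0  # Hill-1, EC50 500 µM
    icilin_on = ic > 0 and condition.construct != "R901H"
    boost = 2.0 if condition.construct == "A867G" else 1.0
    v_half = 80.0 - (60.0 * boost if icilin_on else 0.0)
    inst = 0.2 + 0.4 * ca_act + (0.35 * boost if icilin_on else 0.0)
    return GatingParams(
        g_max=2.0 * ca_act if ca > 0 else 0.0,
        V_half=v_half,
        slope=30.0,
        tau_ms=40.0,
        inst_share=float(min(inst, 1.0)),
        leak_g=0.05,
        noise_sd=2.0,
        unbind_tau_s=12.0 if (ic > 0 and condition.construct == "A867G") else
        (7.0 if icilin_on else 3.0),
        seed=seed,
    )


def simulate_family(
    params: GatingParams, protocol: Protocol
) -> tuple[CurrentFamily, dict]:
    """Voltage-step current family from the gating model (plus truth record).

    I(V, t) = leak_g·(V − V_rev) + g_max·Po(V, t)·(V − V_rev), with Po
    relaxing exponentially from the instantaneous level toward Po_inf(V);
    the tail segment relaxes back toward the holding-level equilibrium.
    """
    rng = np.random.default_rng(params.seed)
    time = protocol.time_base()
    po_hold = params.po_inf(protocol.holding_V)
    sweeps = {}
    truth = {
        "po_inf": {},
        "po_start": {},
        "I_inst_true": {},
        "I_SS_true": {},
        "I_tail0_true": {},
        "params": params,
    }
    step_mask = time < protocol.step_duration
    t_tail = time[~step_mask] - protocol.step_duration
    for V in protocol.step_Vs:
        po_inf = params.po_inf(V)
        po0 = params.inst_share * po_inf + (1.0 - params.inst_share) * po_hold
        po_step = po_inf + (po0 - po_inf) * np.exp(-time[step_mask] / params.tau_ms)
        po_end = po_inf + (po0 - po_inf) * np.exp(-protocol.step_duration / params.tau_ms)
        po_inf_tail = params.po_inf(protocol.tail_V)
        po_tail = po_inf_tail + (po_end - po_inf_tail) * np.exp(-t_tail / params.tau_ms)
        drive_step = V - params.V_rev
        drive_tail = protocol.tail_V - params.V_rev
        current = np.concatenate(
            [
                (params.leak_g + params.g_max * po_step) * drive_step,
                (params.leak_g + params.g_max * po_tail) * drive_tail,
            ]
        )
        if params.noise_sd > 0:
            current = current + rng.normal(0.0, params.noise_sd, current.shape)
        sweeps[V] = Sweep(step_V=V, time=time, current=current)
        truth["po_inf"][V] = po_inf
        truth["po_start"][V] = po0
        truth["I_inst_true"][V] = (params.leak_g + params.g_max * po0) * drive_step
        truth["I_SS_true"][V] = (params.leak_g + params.g_max * po_inf) * drive_step
        truth["I_tail0_true"][V] = (params.leak_g + params.g_max * po_end) * drive_tail
    return CurrentFamily(protocol=protocol, sweeps=sweeps), truth


def simulate_wash(
    params: GatingParams,
    removal_time: float = 5.0,
    duration: float = 25.0,
    probe_V: float = 160.0,
    dt: float = 0.1,
) -> tuple[WashTimecourse, dict]:
    """Timecourse at a fixed probe voltage with agonist removal.

    Before removal the current sits at its equilibrium level; afterwards
    the agonist-dependent component decays with ``unbind_tau_s`` toward
    the leak baseline.
    """
    if duration < removal_time + 14.0:
        raise ValueError("duration must span removal_time + 14 s")
    rng = np.random.default_rng(params.seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    drive = probe_V - params.V_rev
    leak = params.leak_g * drive
    active = params.g_max * params.po_inf(probe_V) * drive
    current = np.where(
        times <= removal_time,
        leak + active,
        leak + active * np.exp(-(times - removal_time) / params.unbind_tau_s)
        if np.isfinite(params.unbind_tau_s)
        else leak + active,
    )
    if params.noise_sd > 0:
        current = current + rng.normal(0.0, params.noise_sd, current.shape)
    tc = WashTimecourse(
        times=times,
        currents=current,
        removal_time=removal_time,
        probe_V=probe_V,
        baseline=leak,
    )
    truth = {
        "pre_removal": leak + active,
        "baseline": leak,
        "expected_fraction_14s": float(np.exp(-14.0 / params.unbind_tau_s))
        if np.isfinite(params.unbind_tau_s)
        else 1.0,
    }
    return tc, truth
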