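"""TM-score-driven pairwise structural alignment and reference-anchored MSA.

The aligner follows the classic fragment-seeded iterative scheme used for
fold-level comparison of protein structures: candidate superpositions are
generated from gapless threadings and from best-superposing contiguous
fragments, then each candidate is refined by alternating (i) Kabsch
superposition on the currently aligned residue pairs with (ii) dynamic
programming over the Cα–Cα distance matrix scored by 1/(1 + (d/d0)^2)
with affine gap penalties, until the pairing stops changing.  The returned
alignment is the candidate with the highest TM-score.

Only Cα atoms participate: residue correspondence in conserved helices is
what downstream conservation mapping consumes, and Cα-level alignment is
the standard, sufficient resolution for that task.  Bit-compatibility with
any particular published aligner binary is not promised.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ResidueRef, Structure

__all__ = [
    "RigidTransform",
    "AlignmentParams",
    "StructuralAlignment",
    "StructureMSA",
    "CaChain",
    "kabsch_superpose",
    "tm_score",
    "tm_d0",
    "align_pair",
    "family_alignment",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class AlignmentParams:
    """Knobs of the iterative aligner.

    ``d0`` follows the standard length-dependent form
    ``max(1.24 * cbrt(L_norm - 15) - 1.8, 0.5)`` Å; ``L_norm`` is the
    reference length by default (the analysis is reference-anchored).
    """

    l_norm_policy: str = "reference_length"  # or "shorter_chain"
    gap_open: float = -0.6
    gap_extend: float = 0.0
    fragment_len: int = 8
    max_iter: int = 30
    converge_tol: float = 1e-6
    column_cutoff: float = 5.0
    n_refine_seeds: int = 8  # seeds refined to convergence (rest get one DP pass)

    def __post_init__(self) -> None:
        if self.fragment_len < 3:
            raise ValueError("fragment_len must be >= 3")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.column_cutoff <= 0:
            raise ValueError("column_cutoff must be > 0")


def tm_d0(l_norm: int) -> float:
    """Length-dependent distance scale of the TM-score."""
    return max(1.24 * float(np.cbrt(l_norm - 15.0)) - 1.8, 0.5)


@dataclass
class StructuralAlignment:
    """Result of one pairwise alignment (pairs are index pairs, monotone)."""

    pairs: list[tuple[int, int]]
    transform: RigidTransform
    tm: float
    rmsd_aligned: float
    n_aligned: int
    seed_label: str = ""

    def __post_init__(self) -> None:
        ri = [p[0] for p in self.pairs]
        ti = [p[1] for p in self.pairs]
        if sorted(ri) != ri or sorted(ti) != ti or len(set(ri)) != len(ri) or len(
            set(ti)
        ) != len(ti):
            raise ValueError("alignment pairs must be strictly increasing / one-to-one")
        if not (0.0 < self.tm <= 1.0 + 1e-12):
            raise ValueError(f"tm score {self.tm} outside (0, 1]")


@dataclass
class CaChain:
    """A region to align: parallel lists of residue refs and Cα coordinates."""

    structure_id: str
    refs: list[ResidueRef]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.refs), 3):
            raise ValueError("coords must be (n_refs, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite Cα coordinates")

    def __len__(self) -> int:
        return len(self.refs)

    @staticmethod
    def from_structure(
        s: Structure, chain_id: str, seq_range: tuple[int, int] | None = None
    ) -> "CaChain":
        refs, coords = [], []
        for r in s.chain(chain_id):
            if seq_range is not None and not (seq_range[0] <= r.seq_num <= seq_range[1]):
                continue
            ca = r.ca
            if ca is None:
                continue
            refs.append(s.ref(r))
            coords.append(ca.coords)
        return CaChain(s.id, refs, np.array(coords, dtype=float).reshape(len(refs), 3))


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid transform of ``Q`` onto ``P`` and its RMSD.

    Reflections are corrected so the rotation is always proper.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    tr = RigidTransform(R, t)
    diff = tr.apply(Q) - P
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return tr, rmsd


def tm_score(
    ref_coords: np.ndarray,
    tgt_coords: np.ndarray,
    pairs: list[tuple[int, int]],
    transform: RigidTransform,
    l_norm: int,
    d0: float | None = None,
) -> float:
    """TM-score of an alignment: (1/L_norm) Σ 1 / (1 + (d_i/d0)^2)."""
    if not pairs:
        raise ValueError("empty alignment")
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    d0 = tm_d0(l_norm) if d0 is None else d0
    ri = np.array([p[0] for p in pairs])
    ti = np.array([p[1] for p in pairs])
    moved = transform.apply(np.asarray(tgt_coords)[ti])
    d = np.linalg.norm(np.asarray(ref_coords)[ri] - moved, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


# ------------------------- dynamic programming ---------------------------

def _dp_align(S: np.ndarray, gap_open: float, gap_extend: float) -> list[tuple[int, int]]:
    """Highest-scoring monotone alignment for similarity matrix ``S``.

    Affine gaps, free end gaps (standard for structure alignment).  The
    common ``gap_extend == 0`` case uses a vectorised Gotoh recursion; the
    general case falls back to the plain cubic-free scalar version.
    """
    if gap_extend != 0.0:
        return _dp_align_scalar(S, gap_open, gap_extend)
    n, m = S.shape
    NEG = -1e18
    H = np.full((n + 1, m + 1), 0.0)
    F = np.full((n + 1, m + 1), NEG)  # vertical: gap in target (skip ref row)
    E = np.full((n + 1, m + 1), NEG)  # horizontal: gap in reference
    for i in range(1, n + 1):
        F[i] = np.maximum(F[i - 1], H[i - 1] + gap_open)
        diag = H[i - 1, :-1] + S[i - 1]
        M = np.maximum(diag, F[i, 1:])
        # with gap_extend == 0 the horizontal state is gap_open + running max
        run = np.maximum.accumulate(np.concatenate(([H[i, 0]], M))[:-1])
        E[i, 1:] = run + gap_open
        H[i, 1:] = np.maximum(M, E[i, 1:])
    return _traceback(S, H, E, F, gap_open, 0.0)


def _traceback(
    S: np.ndarray,
    H: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[int, int]]:
    n, m = S.shape
    # free end gaps: best cell on the last row or column
    last_col = H[:, m]
    last_row = H[n, :]
    if float(last_col.max()) >= float(last_row.max()):
        i, j = int(last_col.argmax()), m
    else:
        i, j = n, int(last_row.argmax())
    pairs: list[tuple[int, int]] = []
    eps = 1e-9
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= eps:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif abs(h - F[i, j]) <= eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            if abs(F[i, j] - (H[i - 1, j] + gap_open)) <= eps:
                state = "H"
            # else: extension, stay in F
            i -= 1
        else:  # E
            if abs(E[i, j] - (H[i, j - 1] + gap_open)) <= eps:
                state = "H"
            j -= 1
    pairs.reverse()
    return pairs


def _dp_align_scalar(
    S: np.ndarray, gap_open: float, gap_extend: float
) -> list[tuple[int, int]]:
    """Reference scalar Gotoh (general affine gaps, free end gaps)."""
    n, m = S.shape
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            H[i][j] = max(H[i - 1][j - 1] + S[i - 1][j - 1], E[i][j], F[i][j])
    return _traceback(S, np.array(H), np.array(E), np.array(F), gap_open, gap_extend)


# ----------------------------- align_pair --------------------------------

def _similarity(ref: np.ndarray, tgt_moved: np.ndarray, d0: float) -> np.ndarray:
    diff = ref[:, None, :] - tgt_moved[None, :, :]
    d2 = np.sum(diff * diff, axis=2)
    return 1.0 / (1.0 + d2 / (d0 * d0))


def _seed_transforms(
    P: np.ndarray, Q: np.ndarray, frag_len: int
) -> list[tuple[str, RigidTransform]]:
    n, m = len(P), len(Q)
    seeds: list[tuple[str, RigidTransform]] = []
    # gapless threading at all offsets with sufficient overlap
    min_ov = max(frag_len, min(n, m) // 2)
    offsets = range(-(m - min_ov), n - min_ov + 1)
    for o in offsets:
        lo_r, hi_r = max(0, o), min(n, m + o)
        idx_r = np.arange(lo_r, hi_r)
        idx_t = idx_r - o
        if len(idx_r) < min_ov:
            continue
        tr, _ = kabsch_superpose(P[idx_r], Q[idx_t])
        seeds.append((f"thread:{o}", tr))
    # contiguous fragment superpositions on a coarse grid
    step = max(1, min(n, m) // 10)
    for i in range(0, n - frag_len + 1, step):
        for j in range(0, m - frag_len + 1, step):
            tr, _ = kabsch_superpose(P[i : i + frag_len], Q[j : j + frag_len])
            seeds.append((f"frag:{i}:{j}", tr))
    return seeds


def align_pair(
    ref: CaChain, tgt: CaChain, params: AlignmentParams | None = None
) -> StructuralAlignment:
    """Iterative fragment-seeded structural alignment of ``tgt`` onto ``ref``.

    Deterministic for fixed inputs and parameters; ties between
    equal-scoring seeds are broken by the earliest seed.
    """
    params = params or AlignmentParams()
    P, Q = ref.coords, tgt.coords
    n, m = len(P), len(Q)
    if n < 20 or m < 20:
        raise ValueError("both regions must have at least 20 Cα positions")
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("degenerate reference coordinates")
    l_norm = n if params.l_norm_policy == "reference_length" else min(n, m)
    d0 = tm_d0(l_norm)

    def one_pass(tr: RigidTransform) -> tuple[list[tuple[int, int]], RigidTransform, float]:
        pairs = _dp_align(_similarity(P, tr.apply(Q), d0), params.gap_open, params.gap_extend)
        if len(pairs) < 3:
            return pairs, tr, -1.0
        return pairs, tr, tm_score(P, Q, pairs, tr, l_norm, d0)

    seeds = _seed_transforms(P, Q, params.fragment_len)
    scored: list[tuple[float, int, str, list[tuple[int, int]], RigidTransform]] = []
    for k, (label, tr) in enumerate(seeds):
        pairs, tr, score = one_pass(tr)
        if score > 0:
            scored.append((score, k, label, pairs, tr))
    if not scored:
        raise ValueError("no alignment found: no seed produced a scoring alignment")
    # refine the most promising seeds to convergence
    scored.sort(key=lambda x: (-x[0], x[1]))
    best: tuple[float, int, str, list[tuple[int, int]], RigidTransform] | None = None
    for score, k, label, pairs, tr in scored[: params.n_refine_seeds]:
        prev_pairs = pairs
        prev_score = score
        for _ in range(params.max_iter):
            idx_r = np.array([p[0] for p in prev_pairs])
            idx_t = np.array([p[1] for p in prev_pairs])
            tr, _ = kabsch_superpose(P[idx_r], Q[idx_t])
            pairs, tr, score = one_pass(tr)
            if pairs == prev_pairs or abs(score - prev_score) < params.converge_tol:
                prev_pairs, prev_score = pairs, score
                break
            prev_pairs, prev_score = pairs, score
        cand = (prev_score, k, label, prev_pairs, tr)
        if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
            best = cand
    score, _, label, pairs, tr = best
    idx_r = np.array([p[0] for p in pairs])
    idx_t = np.array([p[1] for p in pairs])
    diff = tr.apply(Q[idx_t]) - P[idx_r]
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return StructuralAlignment(
        pairs=pairs,
        transform=tr,
        tm=min(score, 1.0),
        rmsd_aligned=rmsd,
        n_aligned=len(pairs),
        seed_label=label,
    )


# --------------------------- family alignment ----------------------------

@dataclass
class StructureMSA:
    """Reference-anchored multi-structure alignment.

    ``columns[i]`` maps structure_id -> index into that target's region (or
    None for a gap) for reference position ``i``.  Insertions relative to
    the reference are kept for reporting only.
    """

    reference: CaChain
    targets: dict[str, CaChain] = field(default_factory=dict)
    columns: list[dict[str, int | None]] = field(default_factory=list)
    stats: dict[str, StructuralAlignment] = field(default_factory=dict)
    insertions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    failed: list[str] = field(default_factory=list)

    def target_ref(self, structure_id: str, column: int) -> ResidueRef | None:
        idx = self.columns[column].get(structure_id)
        if idx is None:
            return None
        return self.targets[structure_id].refs[idx]

    def column_of_seq_num(self, seq_num: int, icode: str = "") -> int:
        for i, r in enumerate(self.reference.refs):
            if r.seq_num == seq_num and r.icode == icode:
                return i
        raise KeyError(f"reference position {seq_num}{icode} not in alignment region")


def family_alignment(
    reference: CaChain,
    targets: list[CaChain],
    params: AlignmentParams | None = None,
) -> StructureMSA:
    """Align every target pairwise to the reference and anchor the columns.

    A target residue enters a reference column only if its post-superposition
    Cα distance to the reference residue is ≤ ``params.column_cutoff``;
    otherwise the column is gapped for that target.  A target whose pairwise
    alignment fails is recorded in ``failed`` and the rest proceed.
    """
    params = params or AlignmentParams()
    msa = StructureMSA(reference=reference)
    msa.columns = [{} for _ in range(len(reference))]
    for tgt in targets:
        try:
            aln = align_pair(reference, tgt, params)
        except ValueError:
            msa.failed.append(tgt.structure_id)
            continue
        msa.targets[tgt.structure_id] = tgt
        msa.stats[tgt.structure_id] = aln
        placed: dict[int, int] = {}
        moved = aln.transform.apply(tgt.coords)
        for ri, ti in aln.pairs:
            d = float(np.linalg.norm(reference.coords[ri] - moved[ti]))
            if d <= params.column_cutoff:
                placed[ri] = ti
        paired_t = set(placed.values())
        msa.insertions[tgt.structure_id] = [
            (ri, ti) for ri, ti in aln.pairs if ti not in paired_t
        ]
        for i in range(len(reference)):
            msa.columns[i][tgt.structure_id] = placed.get(i)
    return msa
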