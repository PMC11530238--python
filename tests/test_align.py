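import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketcons import (
    AlignmentParams,
    BundleSpec,
    CaChain,
    RigidTransform,
    align_pair,
    family_alignment,
    kabsch_superpose,
    make_helix_bundle,
    tm_d0,
    tm_score,
)
from pocketcons.align import _dp_align
from pocketcons.synthetic import delete_residues, perturb_structure


def _chain(structure):
    return CaChain.from_structure(structure, "A")


def _alignment_score(pairs, S, gap_open):
    """Score of a monotone pairing under the aligner's gap model:
    matched similarities plus one gap_open per internal gap run
    (end gaps free, zero extension cost)."""
    total = sum(S[i, j] for i, j in pairs)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 > i1 + 1:
            total += gap_open
        if j2 > j1 + 1:
            total += gap_open
    return total


def _enumerate_best(S, gap_open):
    """Exhaustive maximum over all monotone one-to-one pairings."""
    n, m = S.shape
    best = -np.inf
    rows = list(range(n))
    cols = list(range(m))
    for k in range(1, min(n, m) + 1):
        for ri in itertools.combinations(rows, k):
            for ci in itertools.combinations(cols, k):
                best = max(best, _alignment_score(list(zip(ri, ci)), S, gap_open))
    return best


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        tr, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-10)

    def test_recovers_rigid_motion(self):
        P = np.random.default_rng(1).normal(size=(8, 3)) * 5
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = (P - np.array([1.0, 2.0, 3.0])) @ R.T
        tr, rmsd = kabsch_superpose(P, Q)
        assert rmsd <= 1e-9
        assert np.allclose(tr.apply(Q), P, atol=1e-9)

    def test_errors(self):
        P = np.zeros((4, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(P, np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            P = rng.normal(size=(10, 3)) * 4
            Q = rng.normal(size=(10, 3)) * 4
            tr, rmsd = kabsch_superpose(P, Q)
            rot, _ = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
            ref = np.sqrt(
                np.mean(np.sum((rot.apply(Q - Q.mean(0)) - (P - P.mean(0))) ** 2, axis=1))
            )
            assert rmsd == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_so3_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(5, 3)) * 3
        Q = rng.normal(size=(5, 3)) * 3
        _, rmsd = kabsch_superpose(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        step = 15
        best = np.inf
        for a in range(0, 360, step):
            for b in range(0, 180 + step, step):
                for c in range(0, 360, step):
                    R = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                    d = Qc @ R.T - Pc
                    best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
        assert rmsd <= best + 1e-9  # closed form is optimal
        assert best - rmsd <= 0.6  # and the coarse grid comes close


class TestTmScore:
    def test_self_alignment_scores_one(self, bundle18):
        ch = _chain(bundle18[0])
        pairs = [(i, i) for i in range(len(ch))]
        assert tm_score(
            ch.coords, ch.coords, pairs, RigidTransform.identity(), len(ch)
        ) == pytest.approx(1.0)

    def test_single_pair_at_d0_scores_half(self):
        d0 = tm_d0(1)
        P = np.array([[0.0, 0.0, 0.0]])
        Q = np.array([[d0, 0.0, 0.0]])
        assert tm_score(P, Q, [(0, 0)], RigidTransform.identity(), 1) == pytest.approx(0.5)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(100, 3)) * 10
        Q = P + np.array([2.0, 0.0, 0.0])  # uniform 2 Å displacement
        pairs = [(i, i) for i in range(100)]
        got = tm_score(P, Q, pairs, RigidTransform.identity(), 100)
        d0 = tm_d0(100)
        expected = np.mean(1.0 / (1.0 + (2.0 / d0) ** 2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_d0_floor_for_short_chains(self):
        assert tm_d0(10) == pytest.approx(0.5)
        assert tm_d0(15) == pytest.approx(0.5)

    def test_invariant_under_joint_rigid_motion(self, bundle18):
        s, _ = bundle18
        ch = _chain(s)
        moved = perturb_structure(s, rotation_deg=(45, 10, -30), translation=(3, 4, 5))
        chm = _chain(moved)
        pairs = [(i, i) for i in range(len(ch))]
        t1 = tm_score(ch.coords, ch.coords, pairs, RigidTransform.identity(), len(ch))
        t2 = tm_score(chm.coords, chm.coords, pairs, RigidTransform.identity(), len(ch))
        assert t1 == pytest.approx(t2, abs=1e-9)


class TestDP:
    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 6, 7
        S = rng.uniform(0.05, 1.0, size=(n, m))
        gap_open = -0.6
        pairs = _dp_align(S, gap_open, 0.0)
        got = _alignment_score(pairs, S, gap_open)
        assert got == pytest.approx(_enumerate_best(S, gap_open), abs=1e-9)

    def test_vectorised_agrees_with_scalar_gotoh(self):
        from pocketcons.align import _dp_align_scalar

        rng = np.random.default_rng(11)
        for _ in range(5):
            S = rng.uniform(0.0, 1.0, size=(12, 9))
            fast = _dp_align(S, -0.6, 0.0)
            slow = _dp_align_scalar(S, -0.6, 0.0)
            assert _alignment_score(fast, S, -0.6) == pytest.approx(
                _alignment_score(slow, S, -0.6), abs=1e-9
            )


class TestAlignPair:
    def test_self_alignment_is_identity(self, bundle18):
        ch = _chain(bundle18[0])
        aln = align_pair(ch, ch)
        assert aln.pairs == [(i, i) for i in range(len(ch))]
        assert aln.tm == pytest.approx(1.0, abs=1e-9)
        assert aln.rmsd_aligned == pytest.approx(0.0, abs=1e-9)

    def test_noisy_copy_keeps_identity_pairing(self, bundle18):
        s, _ = bundle18
        noisy = perturb_structure(
            s, noise_sd=0.5, rotation_deg=(30, 60, 15), translation=(8, -2, 5), seed=4
        )
        aln = align_pair(_chain(s), _chain(noisy))
        assert aln.tm >= 0.9
        assert aln.pairs == [(i, i) for i in range(len(_chain(s)))]

    def test_planted_deletion_recovered(self, bundle18):
        s, _ = bundle18
        # remove 5 residues from the middle of helix 2
        gap_nums = [22, 23, 24, 25, 26]
        target = delete_residues(s, "A", gap_nums, new_id="gapped")
        aln = align_pair(_chain(s), _chain(target))
        paired_ref = {p[0] for p in aln.pairs}
        gap_idx = {n - 1 for n in gap_nums}  # seq_num n sits at index n-1
        assert gap_idx.isdisjoint(paired_ref)
        # every other reference residue pairs with its planted partner
        tgt_nums = [r.seq_num for r in _chain(target).refs]
        for ri, ti in aln.pairs:
            assert tgt_nums[ti] == ri + 1

    def test_tm_degrades_monotonically_with_noise(self, bundle18):
        s, _ = bundle18
        ref = _chain(s)
        tms = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            noisy = perturb_structure(s, noise_sd=sigma, seed=9)
            tms.append(align_pair(ref, _chain(noisy)).tm)
        assert all(a >= b - 1e-9 for a, b in zip(tms, tms[1:]))

    def test_short_region_rejected(self, bundle18):
        s, _ = bundle18
        ch = _chain(s)
        short = CaChain(ch.structure_id, ch.refs[:10], ch.coords[:10])
        with pytest.raises(ValueError):
            align_pair(ch, short)


class TestFamilyAlignment:
    def test_exact_copies_fill_every_column(self, bundle18):
        s, _ = bundle18
        ref = _chain(s)
        t1 = _chain(perturb_structure(s, rotation_deg=(10, 0, 0), new_id="c1"))
        t2 = _chain(perturb_structure(s, translation=(5, 5, 5), new_id="c2"))
        msa = family_alignment(ref, [t1, t2])
        assert msa.failed == []
        for col in msa.columns:
            assert col["c1"] is not None and col["c2"] is not None

    def test_diverged_bundles_recover_planted_pairs(self):
        s, _ = make_helix_bundle(BundleSpec(pocket_size=12, seed=5))
        ref = _chain(s)
        recovered = []
        for i, sigma in enumerate((0.5, 1.0)):
            t = perturb_structure(
                s, noise_sd=sigma, rotation_deg=(40, 20, 5), translation=(6, 1, -4),
                seed=20 + i, new_id=f"d{i}",
            )
            msa = family_alignment(ref, [_chain(t)])
            ok = sum(
                1 for ci, col in enumerate(msa.columns) if col[f"d{i}"] == ci
            )
            recovered.append(ok / len(ref))
        assert min(recovered) >= 0.95
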