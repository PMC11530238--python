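# Methods

## Scope and model

`pocketcons` implements two computational procedures around the S1–S4
cooling-agent binding pocket of TRPM-family channels: (i) definition of the
pocket on a reference structure and quantification of its conservation
across other channel structures via structure-based alignment, and (ii)
quantification of voltage-step patch-clamp families measuring how a
cooling agent modulates Ca²⁺-dependent gating. Wet-lab procedures, cryo-EM
map interpretation, ligand pose fitting and figure rendering are out of
scope.

## Structure model and parsing

Structures are parsed with gemmi from mmCIF or PDB into a minimal model:
polymer residues (author numbering preserved — the functional literature
cites author numbers such as G805 or A867), multi-atom heteros as ligand
poses, monatomic heteros as ion sites; waters are dropped. Deposited
cryo-EM models carry no hydrogens, so all distance criteria use heavy
atoms. Only model 1 of multi-model files is read, and for alternate
locations the highest-occupancy conformer is kept (ties: lexicographically
smallest altloc). Ligands are selected by chemical component name from
configuration or by heavy-atom formula (e.g. C16 N3 O4 for icilin), never
by a hard-coded component ID.

## Pocket definition

A residue lines the pocket if any of its heavy atoms is within the ligand
cutoff (default 4.0 Å, **inclusive** — "within 4 Å" is read as ≤ 4.0) of
any ligand heavy atom, in **any** accepted pose; the union over poses is
the most inclusive definition. Pose structures other than the reference are
mapped onto reference numbering through a sequence-alignment-derived
numbering map. Because the channel is a C4 tetramer, contacts are computed
per protomer and collapsed onto residue identity (seq_num) before the
union. Ca²⁺-coordinating residues (any O/N heavy atom within the ion
cutoff, default 4.0 Å, of the ion position) are added because the ion is an
obligate cofactor of cooling-agent activation; coordination is restricted
to O/N because a hard cation is not coordinated by carbon. Every pocket
residue carries provenance tags (which pose(s) contacted it, whether it
coordinates the ion).

The interaction fingerprint classifies pocket-residue/ligand contacts with
conventional geometric criteria: H-bond if donor–acceptor heavy atoms are
≤ 3.5 Å apart and the donor-antecedent angle (a proxy for the D–H…A angle
in hydrogen-free models) is ≥ 120°; ionic if oppositely charged groups have
heavy atoms ≤ 4.5 Å apart (residue formal charges from a built-in table:
Asp/Glu −, Lys/Arg/His +; ligand charges from configuration); hydrophobic
if apolar carbons are ≤ 4.0 Å apart; aromatic if ring centroids are
≤ 5.5 Å apart. All thresholds are configurable; they are conventional
defaults, not fitted values.

## Structural alignment

Pairwise alignment is Cα-only, rigid, and reference-anchored — the
standard resolution for fold-level residue correspondence in conserved
helices. Candidate superpositions are seeded from (a) gapless threadings
at all offsets with at least half-chain overlap and (b) contiguous
fragments (default length 8) on a coarse start-position grid. Each seed
gets one pass of dynamic programming over the similarity matrix
s(i,j) = 1/(1 + (dᵢⱼ/d₀)²); the most promising seeds (default 8) are then
refined by alternating Kabsch superposition on the current pairs with a
fresh DP pass until the pairing is unchanged or `max_iter` is reached. The
DP uses affine gaps (open −0.6, extend 0.0 on the normalized score) with
free end gaps; the common zero-extension case runs a vectorised Gotoh
recursion (the horizontal gap state reduces to a running maximum), with a
scalar reference implementation for the general case and for the
enumeration oracle in the tests. The returned alignment maximises the
TM-score with d₀ = max(1.24·∛(L_norm−15) − 1.8, 0.5) and L_norm the
reference length (the analysis is anchored on the reference channel);
seed ties break by earliest seed index so results are deterministic.
Bit-compatibility with any published aligner binary is not promised — the
downstream identity percentages depend only on residue pairing within
conserved helices, which is robust to implementation detail.

The multi-structure alignment aligns each target to the reference
pairwise; a target residue occupies a reference column only if its
post-superposition Cα distance is ≤ `column_cutoff` (default 5.0 Å),
otherwise the column is gapped. Insertions relative to the reference are
retained for reporting only. A failing target is recorded and the others
proceed.

## Identity and quality

Pocket (or arbitrary-region) identity counts identical amino-acid types
among the mapped pairs over the full pocket size; gaps count as mismatches
in the headline number (the aligned-only denominator is reported
alongside). Percentages are rounded half away from zero to integers.
Deposited structures may come from a different species than the numbering
convention of the functional literature; a global BLOSUM62 pairwise
alignment (open −11, extend −1) between the structure's polymer sequence
and a user-supplied ortholog sequence converts author numbers to ortholog
numbers (e.g. a human-channel deposition reported in mouse numbering).

Column quality uses BLOSUM62: each residue pair in a column scores
(B(a,b) − B_min)/(max(B(a,a), B(b,b)) − B_min), clipped to [0,1] and equal
to 1 for identities; the column score is the mean over pairs scaled by the
column's occupancy (non-gap fraction, exponent configurable). All-identical
fully occupied columns score exactly 1, all-gap columns 0.

## Ephys quantification

Currents are in pA, voltages in mV, time in ms. The default protocol holds
at −60 mV with 200 ms steps from −100 to +160 mV (Δ20 mV) and a tail at
−60 mV, sampled at 10 kHz. Leak subtraction is pointwise against the
0-Ca²⁺ family of the same cell. Measurement windows are this package's
declared defaults: 2 ms capacitive settle; I_inst over
[2, 5) ms after step onset; I_SS over the last 10 ms of the step; tails
over [2, 5) ms after repolarisation. Windows are half-open so a window
ending at the step edge never captures the first post-step sample. The
instantaneous fraction I_inst/I_SS is flagged undefined (NaN) when |I_SS|
is below a noise floor of 5 baseline SDs rather than reported as 0.

Conductance comes either from tail amplitudes divided by the constant tail
driving force (tail_V − V_rev), or from I_SS/(V − V_rev) with the
V = V_rev point excluded; V_rev defaults to 0 mV for near-symmetric
monovalent solutions. Every cell's curves are divided by that cell's
steady-state response at +160 mV in 500 µM Ca²⁺, so the reference point is
exactly 1.0 and normalization is idempotent; population curves are the
mean ± SEM of per-cell normalized values. Exclusion rules are enforced and
logged: cells without a Ca²⁺ response, and patches with currents above
5 nA. The wash-out fraction is the baseline-subtracted current 14 s after
agonist removal over the current immediately before removal.

The Boltzmann fit G(V) = G_max/(1 + exp((V_half − V)/slope)) uses
scipy least squares with deterministic data-driven initialisation
(G_max from the maximum, V_half from the half-maximum point, slope from
the voltage span/10); curves whose dynamic range is under 5% of their
maximum are flagged non-converged instead of fitted. The fit exists for
synthetic parameter-recovery checks; normalized G–V curves are reported
without fitting.

## Synthetic data

The bundle generator emulates the geometry of a peripheral four-helix
domain: ideal α-helices (rise 1.5 Å/residue, 100°/residue, Cα radius
2.3 Å) arranged antiparallel on an 8.5 Å circle, one chain, poly-Ala-like
backbones with a single side-chain marker atom carrying the residue
identity. A multi-atom ligand is planted with a small core at the bundle
centroid plus one arm atom per intended pocket residue, placed along the
residue→centroid direction at a distance tried in decreasing steps until a
brute-force scan confirms that **exactly** the intended residues fall
within 4 Å; infeasible requests raise. Controlled substitutions, Gaussian
coordinate noise, rigid motions and internal deletions provide planted
truth for alignment, gap and identity recovery. What the generator does
not emulate: real side-chain rotamers, loops connecting helices, protomer
interfaces, crystallographic disorder — so passing tests demonstrate
correctness of the geometric and bookkeeping logic, not robustness to
every artefact of experimental models.

The gating simulator is deliberately phenomenological (no kinetic scheme
is proposed by the analyses it supports): open probability follows a
Boltzmann equilibrium Po_∞(V) = 1/(1 + exp((V_half − V)/slope)) and
relaxes mono-exponentially with τ(V) ≡ τ; a step jumps instantly to
inst_share·Po_∞(V) + (1 − inst_share)·Po_hold and relaxes to Po_∞(V);
current is (leak_g + g_max·Po)·(V − V_rev) plus Gaussian noise. Default
magnitudes are chosen to be realistic for inside-out patches of a
Ca²⁺-activated monovalent channel: g_max 2 nS, leak 0.05 nS, noise 2 pA,
V_half 80 mV, slope 30 mV, τ 40 ms. The condition table maps
(Ca²⁺, cooling agent, construct) onto these parameters: Ca²⁺ scales g_max
and the instantaneous share with a 500 µM half-point; the cooling agent
left-shifts V_half and raises the instantaneous share (to ~1 on the
sensitised Ala→Gly background, not at all on the binding-deficient
Arg→His background) and slows unbinding (wash τ 3 s for Ca²⁺ alone, 7 s
with the agonist, 12 s on the sensitised background). Wash timecourses
decay exponentially after removal with that τ. All generators are
bit-reproducible per seed.

## Problem sizes and numerics

Test and acceptance runs use 60–72-residue bundles (4×15–18), five noise
replicates for alignment recovery, full substitution grids k = 0…m for
m ∈ {10, 18, 25}, and the 14-voltage default protocol at 10 kHz — sizes at
which every oracle (brute-force distance scans, SO(3) grid search,
exhaustive DP enumeration at n ≤ 7, closed-form window averages) is exact
and fast. Floating-point tie-breaks in the DP traceback prefer match, then
vertical gap, then horizontal gap; Kabsch reflections are corrected to
proper rotations; degenerate (collinear or short) inputs raise rather
than return garbage.

## Known limitations

* The aligner is rigid and reference-anchored; hinge motions between the
  S1–S4 and pore domains are not modelled (alignment regions should be
  restricted to the pre-S1→TRP-box span, as the shipped configuration
  does).
* Fingerprint chemistry ignores protonation states and uses a residue-type
  charge table; His is treated as positively charged.
* The identity denominator choice (gaps as mismatches) and the deposited
  accessions chosen for the distant-subfamily comparisons are recorded in
  the run report; alternative choices change the headline percentages and
  both variants are emitted.
* The gating simulator's condition table is a stand-in with the right
  qualitative structure, not a fitted model of any channel.
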