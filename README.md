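# pocketcons

Tools for two linked analyses of TRP-channel pharmacology:

1. **Binding-pocket conservation mapping.** TRPM8, the mammalian noxious-cold
   sensor, binds cooling agents such as icilin in a pocket formed entirely by
   its S1–S4 transmembrane helices, with a Ca²⁺ cofactor site at the pocket's
   cytoplasmic mouth. `pocketcons` defines that pocket on a reference
   structure from ligand proximity (any residue with a heavy atom within
   4 Å of the ligand in any accepted pose, plus Ca²⁺-coordinating residues),
   aligns other channel structures onto the reference with a TM-score-driven
   structural aligner, and reports the percentage of pocket residues whose
   structurally equivalent residue in each target has the same amino-acid
   type, together with per-column BLOSUM62 quality scores.
2. **Patch-clamp current-family quantification.** For inside-out voltage-step
   recordings of Ca²⁺-activated channels (e.g. TRPM4): leak subtraction
   against a 0-Ca²⁺ family, instantaneous (I_inst), steady-state (I_SS) and
   tail current extraction, normalized I–V and G–V relations, the
   instantaneous-current fraction I_inst/I_SS, wash-out kinetics, and
   Boltzmann G–V fits.

A synthetic-data module generates helical-bundle structures with planted
pockets and simulated current families with analytically known gating, so
every stage of both pipelines is testable without any downloads.

## The quantities at the core

* **Pocket identity.** For a reference pocket of *m* residues and a target
  with *i* structurally equivalent identical residues,
  identity = round(100·*i*/*m*), rounded half away from zero; positions with
  no equivalent residue (gaps) count as mismatches.
* **TM-score.** For aligned pairs at distances *dᵢ*,
  TM = (1/L_norm) Σᵢ 1/(1 + (dᵢ/d₀)²) with
  d₀ = max(1.24·∛(L_norm−15) − 1.8, 0.5) Å and L_norm the reference length.
  The pairwise aligner seeds superpositions from gapless threadings and
  contiguous fragments, then alternates Kabsch superposition with dynamic
  programming over the Cα distance matrix until the pairing converges.
* **Instantaneous fraction.** I_inst/I_SS at a maximally activating step
  (+160 mV), with I_inst a window mean just after the capacitive settle and
  I_SS a window mean at the end of the 200 ms step.
* **G–V relations.** From tail currents (constant driving force at the fixed
  tail voltage) or from I_SS/(V − V_rev); each cell normalized to its
  response at +160 mV in 500 µM Ca²⁺ before population averaging.

## Worked example

```python
from pocketcons import (BundleSpec, CaChain, make_helix_bundle, mutate_pocket,
                        family_alignment, pocket_identity, define_pocket)
from pocketcons.synthetic import perturb_structure

ref, truth = make_helix_bundle(BundleSpec(pocket_size=18, seed=1))
pocket = define_pocket([(ref, ref.ligands[0])], reference_id=ref.id)
mut, _, expected = mutate_pocket(ref, truth, 2, seed=3)          # expected = 89
target = perturb_structure(mut, noise_sd=0.5, rotation_deg=(30, 60, 15),
                           translation=(8, -2, 5), seed=4, new_id="tgt")
msa = family_alignment(CaChain.from_structure(ref, "A"),
                       [CaChain.from_structure(target, "A")])
res = pocket_identity(msa, pocket, "tgt")
print(len(pocket.residues), res.percent)
```

prints

```
18 89
```

i.e. the ligand-contact scan finds the 18 planted pocket residues, and after
re-aligning the rigidly moved, noisy copy the identity computation reports
round(100·16/18) = 89% — two of the eighteen pocket residues were
substituted.

Real structures are analysed the same way through a YAML configuration; see
`configs/trpm_conservation.yaml` for the TRPM-family run (reference mouse
TRPM8 7wre with poses from 7wre and 6nr3, targets TRPM5/TRPM4/TRPM2/TRPM3
and distant-subfamily structures). Coordinate files are not shipped; fetch
them with `python scripts/fetch_structures.py` (network required), then:

```sh
pocketcons report --config configs/trpm_conservation.yaml --out results/trpm
```

The ephys branch is driven the same way (`pocketcons ephys --config …`) from
CSV sweep tables plus a protocol descriptor, and `pocketcons simulate`
writes synthetic fixtures of either kind.

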