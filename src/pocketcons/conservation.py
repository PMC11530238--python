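"""Pocket/region identity percentages and per-column BLOSUM62 quality.

Identity between the reference pocket and a target channel counts, over
the ordered pocket residues, how many structurally equivalent target
residues share the amino-acid type.  Gaps (pocket positions with no
equivalent target residue within the column cutoff) count as mismatches in
the default "inclusive" denominator; an aligned-only variant is reported
alongside.  Percentages are rounded half away from zero to integers, the
precision at which such numbers are conventionally printed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .align import StructureMSA
from .model import ResidueRef, ResidueSet
from .pocket import PocketDefinition

__all__ = [
    "IdentityResult",
    "QualityProfile",
    "map_residues",
    "pocket_identity",
    "region_identity",
    "column_quality",
    "ortholog_numbering_map",
    "write_report",
    "round_half_away",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_MIN = float(np.min(_BLOSUM62))


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class IdentityResult:
    """Identity of a reference residue set against one target."""

    target_id: str
    n_pocket: int
    n_aligned: int
    n_identical: int
    per_residue: list[tuple[ResidueRef, ResidueRef | None, bool]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if not (0 <= self.n_identical <= self.n_aligned <= self.n_pocket):
            raise ValueError(
                f"inconsistent counts: {self.n_identical} identical, "
                f"{self.n_aligned} aligned, {self.n_pocket} total"
            )

    @property
    def percent(self) -> int:
        """Identity over all pocket positions (gaps count as mismatch)."""
        return round_half_away(100.0 * self.n_identical / self.n_pocket)

    @property
    def percent_aligned_only(self) -> int:
        """Identity over aligned positions only (gaps dropped from denominator)."""
        if self.n_aligned == 0:
            return 0
        return round_half_away(100.0 * self.n_identical / self.n_aligned)


def map_residues(
    msa: StructureMSA, pocket: PocketDefinition | ResidueSet, target_id: str
) -> list[tuple[ResidueRef, ResidueRef | None]]:
    """For each pocket residue in order, the target residue in its column (or gap)."""
    residues = pocket.residues if isinstance(pocket, PocketDefinition) else pocket
    if target_id == msa.reference.structure_id:
        return [(r, r) for r in residues]
    if target_id not in msa.targets:
        raise KeyError(f"target {target_id!r} not in alignment")
    out = []
    missing = []
    for r in residues:
        try:
            col = msa.column_of_seq_num(r.seq_num, r.icode)
        except KeyError:
            missing.append(str(r))
            continue
        out.append((r, msa.target_ref(target_id, col)))
    if missing:
        raise ValueError(
            "pocket residues outside the aligned region: " + ", ".join(missing)
        )
    return out


def _identity_from_mapping(
    mapping: list[tuple[ResidueRef, ResidueRef | None]], target_id: str
) -> IdentityResult:
    per_residue = []
    n_aligned = n_identical = 0
    for ref, tgt in mapping:
        if tgt is None:
            per_residue.append((ref, None, False))
            continue
        n_aligned += 1
        match = ref.comp_name == tgt.comp_name and ref.comp_name != ""
        n_identical += int(match)
        per_residue.append((ref, tgt, match))
    return IdentityResult(
        target_id=target_id,
        n_pocket=len(mapping),
        n_aligned=n_aligned,
        n_identical=n_identical,
        per_residue=per_residue,
    )


def pocket_identity(
    msa: StructureMSA, pocket: PocketDefinition | ResidueSet, target_id: str
) -> IdentityResult:
    """Identity of the pocket residues between reference and target."""
    return _identity_from_mapping(map_residues(msa, pocket, target_id), target_id)


def region_identity(
    msa: StructureMSA, region: ResidueSet, target_id: str
) -> IdentityResult:
    """Identity over an arbitrary reference region (same computation)."""
    return _identity_from_mapping(map_residues(msa, region, target_id), target_id)


@dataclass
class QualityProfile:
    """Per-column quality in [0, 1] from BLOSUM62 substitution scores."""

    scores: list[float]

    def __post_init__(self) -> None:
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise ValueError("quality scores must lie in [0, 1]")


def _pair_quality(a: str, b: str) -> float:
    """Normalised BLOSUM62 similarity of two residue types in [0, 1]."""
    try:
        s = float(_BLOSUM62[a, b])
        self_hi = float(max(_BLOSUM62[a, a], _BLOSUM62[b, b]))
    except (KeyError, IndexError):
        return 0.0
    if a == b:
        return 1.0
    return float(np.clip((s - _BLOSUM_MIN) / (self_hi - _BLOSUM_MIN), 0.0, 1.0))


def column_quality(
    msa: StructureMSA, gap_penalty_weight: float = 1.0
) -> QualityProfile:
    """Column-wise conservation quality of the structure MSA.

    Each column's quality is the mean pairwise normalised BLOSUM62
    similarity over its non-gap residues (reference included), scaled by
    the non-gap fraction raised to ``gap_penalty_weight``.  Columns of all
    gaps score 0 by convention; an all-identical non-gap column scores 1.
    """
    n_rows = 1 + len(msa.targets)
    scores: list[float] = []
    for i, col in enumerate(msa.columns):
        letters = [_one(msa.reference.refs[i])]
        for sid in msa.targets:
            idx = col.get(sid)
            letters.append(_one(msa.targets[sid].refs[idx]) if idx is not None else None)
        present = [l for l in letters if l is not None]
        if not present:
            scores.append(0.0)
            continue
        if len(present) == 1:
            base = 1.0
        else:
            pair_scores = [
                _pair_quality(present[a], present[b])
                for a in range(len(present))
                for b in range(a + 1, len(present))
            ]
            base = float(np.mean(pair_scores))
        occupancy = len(present) / n_rows
        scores.append(float(np.clip(base * occupancy**gap_penalty_weight, 0.0, 1.0)))
    return QualityProfile(scores)


def _one(ref: ResidueRef) -> str:
    from .model import STANDARD_AMINO_ACIDS

    return STANDARD_AMINO_ACIDS.get(ref.comp_name, "X")


# --------------------- ortholog renumbering ------------------------------

def ortholog_numbering_map(
    structure_seq: str,
    structure_nums: list[int],
    ortholog_seq: str,
    ortholog_start: int = 1,
) -> dict[int, int]:
    """Map structure author numbers to ortholog numbering.

    Deposited models can come from a different species than the numbering
    convention used in the functional literature (e.g. a human-channel
    deposition discussed with mouse numbering).  A global pairwise sequence
    alignment between the structure's polymer sequence and the ortholog
    sequence converts author numbers into ortholog numbers; gap-free
    helical cores make the mapping unambiguous.
    """
    if len(structure_seq) != len(structure_nums):
        raise ValueError("structure_seq and structure_nums must be parallel")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(structure_seq.replace("X", "A"), ortholog_seq.replace("X", "A"))[0]
    mapping: dict[int, int] = {}
    for (s_start, s_end), (o_start, o_end) in zip(*aln.aligned):
        for k in range(s_end - s_start):
            mapping[structure_nums[s_start + k]] = ortholog_start + o_start + k
    return mapping


# ----------------------------- reporting ---------------------------------

def write_report(
    pocket: PocketDefinition,
    identities: list[IdentityResult],
    quality: QualityProfile,
    msa: StructureMSA,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit CSV identity table, annotated aligned FASTA, and a JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # CSV identity table (ordered as given: most to least similar by caller)
    csv_path = out / "identity.csv"
    lines = ["target_id,n_pocket,n_aligned,n_identical,percent,percent_aligned_only"]
    for r in identities:
        lines.append(
            f"{r.target_id},{r.n_pocket},{r.n_aligned},{r.n_identical},"
            f"{r.percent},{r.percent_aligned_only}"
        )
    csv_path.write_text("\n".join(lines) + "\n")
    files["identity_csv"] = csv_path

    # aligned FASTA with a pocket-annotation row
    fasta_path = out / "alignment.fasta"
    pocket_cols = set()
    for r in pocket.residues:
        try:
            pocket_cols.add(msa.column_of_seq_num(r.seq_num, r.icode))
        except KeyError:
            pass
    rows = []
    ref_row = "".join(_one(r) for r in msa.reference.refs)
    rows.append((msa.reference.structure_id, ref_row))
    for sid, tgt in msa.targets.items():
        row = "".join(
            _one(tgt.refs[col[sid]]) if col.get(sid) is not None else "-"
            for col in msa.columns
        )
        rows.append((sid, row))
    annot = "".join("*" if i in pocket_cols else "." for i in range(len(msa.columns)))
    with fasta_path.open("w") as fh:
        for sid, row in rows:
            fh.write(f">{sid}\n{row}\n")
        fh.write(f">pocket_columns\n{annot}\n")
    files["alignment_fasta"] = fasta_path

    # machine-readable JSON
    json_path = out / "report.json"
    payload = {
        "reference": pocket.reference_id,
        "pocket": {
            "n_residues": len(pocket.residues),
            "residues": [
                {
                    "chain": r.chain_id,
                    "seq_num": r.seq_num,
                    "comp_name": r.comp_name,
                    "provenance": sorted(pocket.tags(r)),
                }
                for r in pocket.residues
            ],
        },
        "identities": [
            {
                "target_id": r.target_id,
                "n_pocket": r.n_pocket,
                "n_aligned": r.n_aligned,
                "n_identical": r.n_identical,
                "percent": r.percent,
                "percent_aligned_only": r.percent_aligned_only,
            }
            for r in identities
        ],
        "column_quality": [round(s, 6) for s in quality.scores],
        "alignment_stats": {
            sid: {
                "tm_score": round(a.tm, 6),
                "rmsd_aligned": round(a.rmsd_aligned, 4),
                "n_aligned": a.n_aligned,
            }
            for sid, a in msa.stats.items()
        },
        "failed_targets": msa.failed,
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    files["report_json"] = json_path

    # plain-text summary
    txt_path = out / "summary.txt"
    summary = [
        f"Reference {pocket.reference_id}: {len(pocket.residues)}-residue ligand "
        "binding pocket (ligand contacts + ion coordinators).",
        "Pocket sequence identity vs targets: "
        + ", ".join(f"{r.target_id} ({r.percent}%)" for r in identities),
    ]
    txt_path.write_text("\n".join(summary) + "\n")
    files["summary_txt"] = txt_path
    return files
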