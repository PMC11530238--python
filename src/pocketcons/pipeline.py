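"""Configuration-driven orchestration of the two analyses.

``run_conservation`` executes structure parsing → pocket definition →
structural alignment → identity/quality reporting for a reference channel
against a set of target structures.  ``run_ephys`` executes per-cell
current-family feature extraction, normalization and population
aggregation.  Both log every threshold and window into their reports so a
run is reproducible from its outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import ephys
from .align import AlignmentParams, CaChain, family_alignment
from .model import ResidueSet, Structure
from .pocket import PocketParams, define_pocket
from .structure_io import (
    extract_ligand_poses,
    extract_ligand_poses_by_formula,
    load_structure,
    polymer_sequence,
)

logger = logging.getLogger("pocketcons")

__all__ = ["load_config", "run_conservation", "run_ephys", "numbering_map_between"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def numbering_map_between(
    src: Structure, src_chain: str, ref: Structure, ref_chain: str
) -> dict[tuple, tuple]:
    """Residue-number map from one structure's chain onto another's via
    global sequence alignment (adequate for orthologs/paralogs of the same
    fold with gap-free helical cores)."""
    s_seq, s_nums = polymer_sequence(src, src_chain)
    r_seq, r_nums = polymer_sequence(ref, ref_chain)
    pos_map = cons.ortholog_numbering_map(s_seq, s_nums, r_seq, ortholog_start=0)
    # ortholog_start=0 returned indices into r_seq; convert to author numbers
    return {
        (src_chain, s_num, ""): (ref_chain, r_nums[idx], "")
        for s_num, idx in pos_map.items()
    }


def run_conservation(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the pocket-conservation pipeline; returns the report payload."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref_cfg = config["reference"]
    ref = load_structure(ref_cfg["path"], ref_cfg.get("format", "auto"))
    ref.id = ref_cfg.get("id", ref.id)
    ref_chain = ref_cfg["chain"]
    region = tuple(ref_cfg["region"])

    pocket_params = PocketParams(**config.get("pocket_params", {}))
    align_params = AlignmentParams(**config.get("alignment_params", {}))

    # ligand poses: reference structure + any additional pose structures;
    # the ligand may be named by component ID or matched by heavy-atom formula
    ligand = ref_cfg.get("ligand")
    formula = ref_cfg.get("ligand_formula")

    def _poses_of(s: Structure) -> list:
        if formula:
            return extract_ligand_poses_by_formula(s, formula)
        return extract_ligand_poses(s, ligand)

    poses = [(ref, p) for p in _poses_of(ref)]
    numbering_map: dict[str, dict] = {}
    for extra in config.get("pose_structures", []):
        s = load_structure(extra["path"], extra.get("format", "auto"))
        s.id = extra.get("id", s.id)
        numbering_map[s.id] = numbering_map_between(s, extra["chain"], ref, ref_chain)
        poses.extend((s, p) for p in _poses_of(s))
    if not poses:
        raise ValueError(f"no ligand poses matching {ligand or formula!r} found")

    ion_element = ref_cfg.get("ion", "CA")
    ions = [(ref, i) for i in ref.ions if i.element.upper() == ion_element.upper()]

    pocket = define_pocket(
        poses, ions, pocket_params, numbering_map or None, reference_id=ref.id
    )
    logger.info("pocket: %d residues (cutoff %.2f Å)", len(pocket.residues), pocket_params.ligand_cutoff)

    ref_region = CaChain.from_structure(ref, ref_chain, region)
    targets = []
    target_structs = {}
    for t in config.get("targets", []):
        s = load_structure(t["path"], t.get("format", "auto"))
        s.id = t.get("id", s.id)
        target_structs[s.id] = (s, t)
        targets.append(CaChain.from_structure(s, t["chain"], tuple(t.get("region")) if t.get("region") else None))
    msa = family_alignment(ref_region, targets, align_params)

    identities = [
        cons.pocket_identity(msa, pocket, tid) for tid in msa.targets
    ]
    identities.sort(key=lambda r: -r.percent)
    region_results = {}
    for name, rng in config.get("regions", {}).items():
        rset = ResidueSet(
            [r for r in (ref.ref(x) for x in ref.chain(ref_chain)) if rng[0] <= r.seq_num <= rng[1]]
        )
        try:
            region_results[name] = {
                tid: cons.region_identity(msa, rset, tid).percent for tid in msa.targets
            }
        except ValueError as exc:
            region_results[name] = {"error": str(exc)}

    quality = cons.column_quality(msa)
    files = cons.write_report(pocket, identities, quality, msa, out)

    payload = {
        "parameters": {
            "pocket": asdict(pocket_params),
            "alignment": asdict(align_params),
            "reference_region": list(region),
            "seed": seed,
        },
        "pocket_size": len(pocket.residues),
        "pocket_seq_nums": pocket.seq_nums,
        "identities": {r.target_id: r.percent for r in identities},
        "region_identities": region_results,
        "outputs": {k: str(v) for k, v in files.items()},
    }
    (out / "conservation_run.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def run_ephys(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the current-family analysis over a set of cells.

    Per cell: parse families per condition, enforce exclusion rules
    (no Ca2+ response; currents >5 nA), leak-subtract against the 0-Ca2+
    family, extract features, build normalized I–V and G–V curves; then
    aggregate population mean ± SEM of the per-cell normalized curves.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    windows = ephys.AnalysisWindows(**config.get("windows", {}))
    gv_source = config.get("gv_source", "tail")
    v_rev = float(config.get("V_rev", 0.0))
    ref_condition = config.get("reference_condition", "Ca500")
    ref_V = float(config.get("reference_V", 160.0))

    excluded_log = []
    cell_rows = []
    pop_iv: dict[str, list[ephys.CurveSet]] = {}
    pop_gv: dict[str, list[ephys.CurveSet]] = {}

    for cell in config["cells"]:
        cell_id = cell["id"]
        protocol = ephys.Protocol(**cell.get("protocol", {}))
        families = {}
        for cond_name, path in cell["families"].items():
            families[cond_name] = ephys.parse_sweeps(path, protocol)
        leak_key = cell.get("leak_condition", "Ca0")
        if leak_key not in families:
            raise ValueError(f"cell {cell_id}: leak (0 Ca2+) family {leak_key!r} missing")

        # exclusion: very large currents
        too_big = max(f.max_abs_current() for f in families.values())
        if too_big > ephys.MAX_CURRENT_PA:
            excluded_log.append(
                {"cell": cell_id, "reason": f"current {too_big:.0f} pA exceeds 5 nA"}
            )
            continue
        # exclusion: unresponsive to Ca2+
        leak = families[leak_key]
        responsive = False
        for cond_name, fam in families.items():
            if cond_name == leak_key:
                continue
            sub = ephys.leak_subtract(fam, leak)
            f = ephys.sweep_features(
                sub.sweeps[max(protocol.step_Vs)], windows, protocol.step_duration
            )
            if f.reliable and abs(f.I_SS) > 10 * f.noise_sd:
                responsive = True
        if not responsive:
            excluded_log.append({"cell": cell_id, "reason": "no response to Ca2+"})
            continue

        ivs, gvs = {}, {}
        for cond_name, fam in families.items():
            if cond_name == leak_key:
                continue
            sub = ephys.leak_subtract(fam, leak)
            ivs[cond_name] = ephys.build_iv(sub, windows)
            gvs[cond_name] = ephys.build_gv(sub, gv_source, v_rev, windows)
            for V in protocol.step_Vs:
                f = ephys.sweep_features(sub.sweeps[V], windows, protocol.step_duration)
                frac = ephys.inst_fraction(f) if V == max(protocol.step_Vs) else np.nan
                cell_rows.append(
                    {
                        "cell": cell_id,
                        "condition": cond_name,
                        "step_V": V,
                        "I_inst": f.I_inst,
                        "I_SS": f.I_SS,
                        "I_tail": f.I_tail,
                        "inst_fraction": frac,
                        "reliable": f.reliable,
                    }
                )
        ivs = ephys.normalize_curves(ivs, ref_condition, ref_V)
        # G–V normalized to its own reference curve value at ref_V
        gvs = ephys.normalize_curves(gvs, ref_condition, ref_V)
        for cond_name in ivs:
            pop_iv.setdefault(cond_name, []).append(ivs[cond_name])
            pop_gv.setdefault(cond_name, []).append(gvs[cond_name])

    features_df = pd.DataFrame(cell_rows)
    features_df.to_csv(out / "features.csv", index=False)

    def aggregate(curvesets: dict[str, list[ephys.CurveSet]]) -> pd.DataFrame:
        rows = []
        for cond, curves in curvesets.items():
            voltages = curves[0].voltages
            mat = np.array([[c.points[v] for v in voltages] for c in curves])
            mean = mat.mean(axis=0)
            sem = mat.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else np.zeros_like(mean)
            for v, m, s in zip(voltages, mean, sem):
                rows.append({"condition": cond, "step_V": v, "mean": m, "sem": s, "n": len(curves)})
        return pd.DataFrame(rows)

    iv_df = aggregate(pop_iv)
    gv_df = aggregate(pop_gv)
    iv_df.to_csv(out / "population_iv.csv", index=False)
    gv_df.to_csv(out / "population_gv.csv", index=False)

    payload = {
        "parameters": {
            "windows": asdict(windows),
            "gv_source": gv_source,
            "V_rev": v_rev,
            "reference_condition": ref_condition,
            "reference_V": ref_V,
            "max_current_pA": ephys.MAX_CURRENT_PA,
            "seed": seed,
        },
        "n_cells_analyzed": int(features_df["cell"].nunique()) if len(features_df) else 0,
        "excluded": excluded_log,
        "outputs": {
            "features_csv": str(out / "features.csv"),
            "population_iv_csv": str(out / "population_iv.csv"),
            "population_gv_csv": str(out / "population_gv.csv"),
        },
    }
    (out / "ephys_run.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload
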