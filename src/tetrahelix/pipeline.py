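"""End-to-end orchestration: sequence scanning and structural
characterization aggregated into a single reproducible report.

A structure report runs hydrogen-bond detection, pair/quartet
classification, crisscross detection and the geometry tables per model,
aggregates an ensemble consensus, and calls an overall topology:

* TYPE 1 AGCGA-quadruplex: a core of stacked GAGA-quartets (>= 2) together
  with at least one GCGC-quartet;
* TYPE 2 AGCGA-quadruplex: four central G-C pairs without GAGA-quartets but
  with peripheral G-A pairs;
* otherwise "neither".
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Config, DEFAULT_CONFIG
from .geometry import (ensemble_stats, groove_widths, model_torsions,
                       pair_mid_frame, pair_params, quartet_params,
                       step_params)

logger = logging.getLogger("tetrahelix")
from .pairing import (assemble_quartets, consensus, detect_crisscross,
                      find_hbonds, find_pairs, model_frames)
from .seqscan import (classify_sequence, read_fasta, write_bed,
                      write_match_tsv)
from .structio import StructureEnsemble, read_structure


@dataclass
class AnalysisReport:
    provenance: dict
    pairs: pd.DataFrame
    quartets: pd.DataFrame
    crisscross: pd.DataFrame
    pair_params: pd.DataFrame
    step_params: pd.DataFrame
    torsions: pd.DataFrame
    grooves: pd.DataFrame
    consensus_pairs: list
    consensus_quartets: list
    topology: str
    chi_classes: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "topology": self.topology,
            "chi_classes": self.chi_classes,
            "consensus_pairs": [
                {"residues": [list(p.res_i), list(p.res_j)],
                 "class": p.geometry_class} for p in self.consensus_pairs
            ],
            "consensus_quartets": [
                {"residues": [list(r) for r in q.residues],
                 "class": q.quartet_class} for q in self.consensus_quartets
            ],
            "crisscross": self.crisscross.to_dict("records"),
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.report.json").write_text(self.to_json())
        self.pairs.to_csv(f"{prefix}.pairs.tsv", sep="\t", index=False)
        self.quartets.to_csv(f"{prefix}.quartets.tsv", sep="\t", index=False)
        self.pair_params.to_csv(f"{prefix}.pair_params.tsv", sep="\t", index=False)
        self.step_params.to_csv(f"{prefix}.step_params.tsv", sep="\t", index=False)
        self.torsions.to_csv(f"{prefix}.torsions.tsv", sep="\t", index=False)
        self.grooves.to_csv(f"{prefix}.grooves.tsv", sep="\t", index=False)


def _pair_id(p) -> tuple:
    return (p.res_i, p.res_j, p.geometry_class)


def _quartet_id(q) -> tuple:
    return (tuple(sorted(q.residues)), q.quartet_class)


def _call_topology(quartet_classes: list[str], pair_classes: list[str],
                   cfg: Config) -> str:
    n_gaga = quartet_classes.count("GAGA")
    n_gcgc = sum(c.startswith("GCGC") for c in quartet_classes)
    n_gc = pair_classes.count("WC_GC")
    n_ga = pair_classes.count("GA_N1N7_CARBONYLAMINO")
    if n_gaga >= cfg.type1_min_gaga and n_gcgc >= cfg.type1_min_gcgc:
        return "TYPE 1"
    if n_gaga == 0 and n_gc >= cfg.type2_min_gc_pairs and n_ga >= 1:
        return "TYPE 2"
    return "neither"


def analyze_structure(
    source: str | Path | StructureEnsemble, config: Config | None = None
) -> AnalysisReport:
    """Full structural characterization of an ensemble (path or in-memory)."""
    cfg = config or DEFAULT_CONFIG
    if isinstance(source, StructureEnsemble):
        ens = source
        src_label = ens.provenance.get("source", "<in-memory>")
    else:
        ens = read_structure(source)
        src_label = str(source)

    warnings: list[str] = []
    pair_rows, quartet_rows, cc_rows = [], [], []
    pp_rows, sp_rows, torsion_frames, groove_frames = [], [], [], []
    per_model_pairs, per_model_quartets = [], []

    for model in ens.models:
        frames = model_frames(model)
        for key, fr in frames.items():
            if fr.distorted:
                warnings.append(
                    f"model {model.index}: distorted base at {key} "
                    f"(fit rmsd {fr.rmsd:.2f} A)"
                )
        hbonds = find_hbonds(model, d_max=cfg.hbond_d_max,
                             theta_min=cfg.hbond_theta_min,
                             base_only=cfg.hbond_base_only)
        pairs = find_pairs(model, hbonds, frames)
        quartets = assemble_quartets(pairs, hbonds, model)
        crisscross = detect_crisscross(
            pairs, frames, twist_min=cfg.crisscross_twist_min,
            rise_max=cfg.stack_rise_max,
        )
        per_model_pairs.append(pairs)
        per_model_quartets.append(quartets)

        for p in pairs:
            pair_rows.append({
                "model": model.index, "res_i": f"{p.res_i[0]}:{p.res_i[1]}",
                "res_j": f"{p.res_j[0]}:{p.res_j[1]}",
                "class": p.geometry_class, "n_hbonds": p.n_hbonds,
                "strand_relation": p.strand_relation,
                "hbonds": ";".join(
                    f"{b.donor_res[0]}:{b.donor_res[1]}:{b.donor_atom}"
                    f"->{b.acceptor_res[0]}:{b.acceptor_res[1]}:{b.acceptor_atom}"
                    for b in p.hbonds
                ),
            })
            pp = pair_params(frames[p.res_i], frames[p.res_j])
            pp_rows.append({
                "model": model.index,
                "res_i": f"{p.res_i[0]}:{p.res_i[1]}",
                "res_j": f"{p.res_j[0]}:{p.res_j[1]}",
                "class": p.geometry_class, **pp.as_dict(),
            })
        index = {r.key: r for r in model.residues()}
        for q in quartets:
            qp = None
            if q.constituent_pairs:
                pa, pb = q.constituent_pairs
                qp = quartet_params([index[k] for k in pa.residues],
                                    [index[k] for k in pb.residues])
            else:
                qp = quartet_params([index[q.residues[0]], index[q.residues[1]]],
                                    [index[q.residues[2]], index[q.residues[3]]])
            quartet_rows.append({
                "model": model.index,
                "residues": "+".join(f"{c}:{n}" for c, n in q.residues),
                "class": q.quartet_class, "n_hbonds": q.n_hbonds,
                "quartet_buckle": qp.quartet_buckle,
                "plane_rmsd": qp.plane_rmsd,
            })
        # steps between consecutive stacked units (quartets ordered by mean z
        # along the stacking direction of the first quartet)
        if len(quartets) >= 2:
            qframes = []
            for q in quartets:
                from .geometry import unit_frame
                qframes.append(unit_frame([frames[k] for k in q.residues]))
            axis = qframes[0].z
            order = np.argsort([f.origin @ axis for f in qframes])
            for a, b in zip(order[:-1], order[1:]):
                sp = step_params(qframes[a], qframes[b])
                sp_rows.append({
                    "model": model.index,
                    "unit_i": "+".join(f"{c}:{n}" for c, n in quartets[a].residues),
                    "unit_j": "+".join(f"{c}:{n}" for c, n in quartets[b].residues),
                    "class_i": quartets[a].quartet_class,
                    "class_j": quartets[b].quartet_class,
                    **sp.as_dict(),
                })
        for pa, pb in crisscross:
            fa = pair_mid_frame(frames[pa.res_i], frames[pa.res_j])
            fb = pair_mid_frame(frames[pb.res_i], frames[pb.res_j])
            sp = step_params(fa, fb)
            cc_rows.append({
                "model": model.index,
                "pair_a": f"{pa.res_i[0]}:{pa.res_i[1]}+{pa.res_j[0]}:{pa.res_j[1]}",
                "pair_b": f"{pb.res_i[0]}:{pb.res_i[1]}+{pb.res_j[0]}:{pb.res_j[1]}",
                "twist": sp.twist, "rise": sp.rise,
            })
        try:
            tdf = model_torsions(model)
            tdf.insert(0, "model", model.index)
            torsion_frames.append(tdf)
        except ValueError as exc:  # bases-only models carry no sugar atoms
            warnings.append(f"model {model.index}: torsions unavailable ({exc})")
        # groove widths for chain couples joined by inter-chain pairs
        couples = sorted({
            tuple(sorted((p.res_i[0], p.res_j[0]))) for p in pairs
            if p.res_i[0] != p.res_j[0]
        })
        if couples:
            gdf = groove_widths(model, couples, pp_offset=cfg.groove_pp_offset,
                                narrow=cfg.groove_narrow, wide=cfg.groove_wide)
            if not gdf.empty:
                gdf.insert(0, "model", model.index)
                groove_frames.append(gdf)

    for w in warnings:
        logger.warning(w)
    cons_pairs = consensus(per_model_pairs, _pair_id, cfg.consensus_fraction)
    cons_quartets = consensus(per_model_quartets, _quartet_id,
                              cfg.consensus_fraction)
    topology = _call_topology(
        [q.quartet_class for q in cons_quartets],
        [p.geometry_class for p in cons_pairs], cfg,
    )

    torsions = (pd.concat(torsion_frames, ignore_index=True)
                if torsion_frames else pd.DataFrame())
    chi_classes: dict[str, str] = {}
    if not torsions.empty:
        # majority chi class per residue over models
        for label, grp in torsions.groupby("residue_label"):
            chi_classes[label] = grp["chi_class"].mode().iloc[0]

    return AnalysisReport(
        provenance={
            "source": src_label, "n_models": ens.n_models,
            "version": __version__, "config_hash": cfg.hash(),
        },
        pairs=pd.DataFrame(pair_rows),
        quartets=pd.DataFrame(quartet_rows),
        crisscross=pd.DataFrame(cc_rows),
        pair_params=pd.DataFrame(pp_rows),
        step_params=pd.DataFrame(sp_rows),
        torsions=torsions,
        grooves=(pd.concat(groove_frames, ignore_index=True)
                 if groove_frames else pd.DataFrame()),
        consensus_pairs=cons_pairs,
        consensus_quartets=cons_quartets,
        topology=topology,
        chi_classes=chi_classes,
        warnings=warnings,
    )


def scan_fasta(path: str | Path, config: Config | None = None,
               out_prefix: str | Path | None = None) -> dict:
    """Scan every FASTA record with both consensus scanners."""
    cfg = config or DEFAULT_CONFIG
    seqs = read_fasta(path)
    summaries = [
        classify_sequence(
            s,
            agcga_kwargs=dict(
                min_spacer=cfg.agcga_min_spacer, max_spacer=cfg.agcga_max_spacer,
                both_strands=cfg.both_strands, report=cfg.report,
            ),
            g4_kwargs=dict(
                min_spacer=cfg.g4_min_spacer, max_spacer=cfg.g4_max_spacer,
                both_strands=cfg.both_strands, report=cfg.report,
            ),
        )
        for s in seqs
    ]
    matches = [m for s in summaries for m in s["agcga_matches"] + s["g4_matches"]]
    result = {
        "config_hash": cfg.hash(),
        "n_sequences": len(seqs),
        "n_with_4_repeats": sum(s["n_agcga_repeats"] >= 4 for s in summaries),
        "n_agcga_matches": sum(len(s["agcga_matches"]) for s in summaries),
        "n_g4_matches": sum(len(s["g4_matches"]) for s in summaries),
        "n_dual_consensus": sum(s["dual_consensus"] for s in summaries),
        "summaries": summaries,
        "matches": matches,
    }
    if out_prefix is not None:
        write_bed(matches, f"{out_prefix}.bed")
        write_match_tsv(matches, f"{out_prefix}.tsv")
    return result
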