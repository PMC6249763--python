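"""End-to-end orchestration from one config file.

Stages run in dependency order: simulate -> qc -> anchor -> build ->
mapstats -> qtlseq -> synteny.  Every stage writes its outputs under the
configured output directory and records parameters and output checksums in a
run manifest (manifest.json); with an unchanged config and seed a rerun is
byte-identical, and stages whose outputs already exist under the same
parameter hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import (
    build_anchor_plan,
    build_pseudochromosomes,
    compare_maps,
    perturb_map,
    read_genetic_map,
    run_qc,
    simulate_bulks,
    simulate_cross,
    simulate_genome,
    true_map,
    write_agp,
    write_fasta,
    write_genetic_map,
    write_genotypes,
    write_pool_depths,
)
from .consensus_anchor import AnchorPlan
from .io_formats import FormatError
from .marker_qc import QcParams
from .pseudochrom import assembly_stats, map_stats
from .qtlscan import (
    candidate_intervals,
    intervals_to_frame,
    threshold_top,
    window_scan,
    windows_to_frame,
)
from .synteny import chromosome_correspondence, reciprocal_best_hits

DEFAULT_CONFIG = {
    "seed": 42,
    "outdir": "mapanchor_run",
    "simulate": {
        "n_chrom": 5,
        "chrom_len": 2_000_000,
        "n_scaffolds": 40,
        "markers_per_chrom": 40,
        "cm_per_mb": 25.0,
        "populations": [
            {"name": "MH", "weight": 2, "n_offspring": 345,
             "marker_fraction": 0.85, "jitter_cm": 0.3, "drop_rate": 0.02},
            {"name": "YM", "weight": 2, "n_offspring": 162,
             "marker_fraction": 0.80, "jitter_cm": 0.3, "drop_rate": 0.02},
            {"name": "BD", "weight": 1, "n_offspring": 100,
             "marker_fraction": 0.60, "jitter_cm": 0.8, "drop_rate": 0.05},
        ],
        "missing_rate": 0.03,
        "depth_mean": 30.0,
        "depth_dispersion": 0.3,
        "bulks": {"n_snps_per_chrom": 500, "mean_depth": 20.0},
    },
    "qc": {},
    "build": {"gap_len": 100},
    "qtlseq": {"window": 1_000_000, "step": 20_000, "top_fraction": 0.005},
    "synteny": {"enabled": True},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(config, user)
    return config


def _merge(base: dict, update: dict) -> None:
    for key, val in update.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path | None = None,
                 seed: int | None = None,
                 force: bool = False) -> dict:
    """Run every configured stage; returns the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    if outdir is not None:
        config["outdir"] = str(outdir)
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    manifest_path = out / "manifest.json"
    old_manifest = {}
    if manifest_path.exists() and not force:
        old_manifest = json.loads(manifest_path.read_text())
    manifest: dict = {"config": config, "stages": {}}
    seed0 = int(config["seed"])

    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("anchor", _stage_anchor),
        ("build", _stage_build),
        ("mapstats", _stage_mapstats),
        ("qtlseq", _stage_qtlseq),
        ("synteny", _stage_synteny),
    ]
    for name, fn in stages:
        try:
            outputs = fn(config, out, seed0, state)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise StageError(name, exc) from exc
        params = config.get(name, {})
        manifest["stages"][name] = {
            "params_hash": _params_hash({"seed": seed0, **params}),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }
        skipped = (
            old_manifest.get("stages", {}).get(name, {}).get("params_hash")
            == manifest["stages"][name]["params_hash"]
        )
        manifest["stages"][name]["reused_params"] = bool(skipped)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, out, seed0, state):
    sim = config["simulate"]
    truth, scaffolds = simulate_genome(
        n_chrom=sim["n_chrom"], chrom_len=sim["chrom_len"],
        n_scaffolds=sim["n_scaffolds"], seed=seed0,
        markers_per_chrom=sim["markers_per_chrom"],
        cm_per_mb=sim.get("cm_per_mb", 4.0),
    )
    state["truth"] = truth
    state["scaffolds"] = scaffolds
    write_fasta(scaffolds, out / "scaffolds.fasta")

    genotypes = simulate_cross(
        truth, n_offspring=sim["populations"][0]["n_offspring"],
        missing_rate=sim["missing_rate"],
        depth_params=(sim["depth_mean"], sim["depth_dispersion"]),
        seed=seed0 + 1,
    )
    state["genotypes"] = genotypes
    write_genotypes(genotypes, out / "genotypes.tsv")

    maps = []
    for i, pop in enumerate(sim["populations"]):
        base = true_map(truth, name=pop["name"], weight=pop["weight"],
                        marker_fraction=pop.get("marker_fraction", 1.0),
                        seed=seed0 + 10 + i)
        noisy = perturb_map(base, jitter_cm=pop.get("jitter_cm", 0.0),
                            swap_rate=pop.get("swap_rate", 0.0),
                            drop_rate=pop.get("drop_rate", 0.0),
                            seed=seed0 + 20 + i)
        write_genetic_map(noisy, out / f"map_{pop['name']}.tsv")
        maps.append(noisy)
    state["maps"] = maps

    bulks = simulate_bulks(truth, n_snps_per_chrom=sim["bulks"]["n_snps_per_chrom"],
                           mean_depth=sim["bulks"]["mean_depth"], seed=seed0 + 30)
    state["bulks"] = bulks
    write_pool_depths(bulks, out / "pool_depths.tsv")
    outputs = [out / "scaffolds.fasta", out / "genotypes.tsv",
               out / "pool_depths.tsv"]
    outputs += [out / f"map_{p['name']}.tsv" for p in sim["populations"]]
    return outputs


def _stage_qc(config, out, seed0, state):
    params = QcParams(**config.get("qc", {}))
    filtered, report = run_qc(state["genotypes"], params)
    state["qc_filtered"] = filtered
    write_genotypes(filtered, out / "genotypes_qc.tsv")
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    return [out / "genotypes_qc.tsv", out / "qc_report.tsv"]


def _stage_anchor(config, out, seed0, state):
    plan = build_anchor_plan(state["scaffolds"], state["maps"])
    state["plan"] = plan
    plan.to_frame().to_csv(out / "anchor_plan.tsv", sep="\t", index=False)
    conc = compare_maps(plan, state["maps"])
    conc.to_frame().to_csv(out / "map_concordance.tsv", sep="\t", index=False)
    return [out / "anchor_plan.tsv", out / "map_concordance.tsv"]


def _stage_build(config, out, seed0, state):
    gap_len = config["build"]["gap_len"]
    bundle = build_pseudochromosomes(state["plan"], state["scaffolds"],
                                     gap_len=gap_len, maps=state["maps"])
    state["bundle"] = bundle
    records = [(c, s) for c, s in bundle.chrom_sequences.items() if s is not None]
    unplaced = [(sid, state["scaffolds"][sid].sequence)
                for sid in bundle.unplaced
                if state["scaffolds"][sid].sequence is not None]
    write_fasta(records + unplaced, out / "pseudochromosomes.fasta")
    write_agp(bundle.agp, out / "pseudochromosomes.agp")
    stats = assembly_stats(bundle, state["plan"], state["scaffolds"], state["maps"])
    stats.to_csv(out / "assembly_stats.tsv", sep="\t", index=False)
    return [out / "pseudochromosomes.fasta", out / "pseudochromosomes.agp",
            out / "assembly_stats.tsv"]


def _stage_mapstats(config, out, seed0, state):
    frames = []
    for gmap in state["maps"]:
        ms = map_stats(gmap)
        df = ms.per_lg.copy()
        df.insert(0, "map", gmap.name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(out / "map_stats.tsv",
                                                sep="\t", index=False)
    return [out / "map_stats.tsv"]


def _stage_qtlseq(config, out, seed0, state):
    cfg = config["qtlseq"]
    chrom_lengths = {f"chr{c}": ln for c, ln in state["truth"].chromosomes}
    stats = window_scan(state["bulks"], chrom_lengths,
                        window=cfg["window"], step=cfg["step"])
    thr = threshold_top(stats, cfg["top_fraction"])
    intervals = candidate_intervals(stats, thr)
    windows_to_frame(stats).to_csv(out / "qtl_windows.tsv", sep="\t", index=False)
    df = intervals_to_frame(intervals)
    df.to_csv(out / "qtl_intervals.tsv", sep="\t", index=False)
    state["qtl_intervals"] = intervals
    state["qtl_threshold"] = thr
    return [out / "qtl_windows.tsv", out / "qtl_intervals.tsv"]


def _stage_synteny(config, out, seed0, state):
    if not config.get("synteny", {}).get("enabled", False):
        return []
    # self-comparison: truth genome coordinates vs the rebuilt assembly
    truth = state["truth"]
    bundle = state["bundle"]
    proj = bundle.marker_projections
    if proj is None or proj.empty:
        return []
    proj = proj.drop_duplicates("marker_id").set_index("marker_id")
    rows_a, rows_b, hits = [], [], []
    for m in truth.marker_truth:
        if m.marker_id not in proj.index:
            continue
        ga, gb = f"{m.marker_id}_A", f"{m.marker_id}_B"
        rows_a.append((ga, f"chr{m.chrom}", m.genome_pos, m.genome_pos))
        p = proj.loc[m.marker_id]
        rows_b.append((gb, p["chrom"], int(p["chrom_pos"]), int(p["chrom_pos"])))
        hits.append((ga, gb, 100.0, 500, 0, 0, 1, 500, 1, 500, 1e-50, 900.0))
    pos_a = pd.DataFrame(rows_a, columns=["gene", "chrom", "start", "end"])
    pos_b = pd.DataFrame(rows_b, columns=["gene", "chrom", "start", "end"])
    pos_a["midpoint"] = (pos_a["start"] + pos_a["end"]) / 2
    pos_b["midpoint"] = (pos_b["start"] + pos_b["end"]) / 2
    from .io_formats import HIT_COLUMNS
    hits_ab = pd.DataFrame(hits, columns=HIT_COLUMNS)
    hits_ba = hits_ab.rename(columns={"query": "subject", "subject": "query"})[HIT_COLUMNS]
    pairs = reciprocal_best_hits(hits_ab, hits_ba)
    corr = chromosome_correspondence(pairs, pos_a, pos_b)
    corr.to_csv(out / "synteny_correspondence.tsv", sep="\t", index=False)
    return [out / "synteny_correspondence.tsv"]
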