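"""End-to-end orchestration: simulate -> map -> quant -> call -> diff.

Stages hand off through plain TSV/FASTA/FASTQ files so each one is
independently invocable; a JSON run manifest records the config snapshot,
seeds, per-file SHA-256 checksums, spike-in QC verdicts and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io, simulate
from .call import FilterThresholds, call_sites
from .diff import call_differential
from .mapping import index_reference, map_all
from .quant import pileup, spikein_conversion
from .simulate import DEFAULT_CONDITIONS, SimConfig

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """Demo configuration: two conditions x two replicates, one planted
    three-C cluster (unmethylated in EV, 0.8 upon restoration)."""
    return {
        "n_transcripts": 6,
        "length": 1000,
        "gc_fraction": 0.5,
        "n_spikeins": 2,
        "cluster_levels": {"EV": 0.0, "NSUN7": 0.8},
        "n_background_sites": 0,
        "sim": dataclasses.asdict(SimConfig()),
        "k": 20,
        "max_mismatch_fraction": 0.05,
        "thresholds": dataclasses.asdict(FilterThresholds()),
        "alpha": 0.01,
        "min_delta": 0.1,
        "spikein_qc_threshold": 0.99,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ensure_cluster(transcripts, rng_seed: int):
    """Pick (or create) a transcript with a CCC run for cluster planting."""
    for tx in transcripts:
        if tx.is_spikein:
            continue
        runs = simulate.find_c_runs(tx, 3)
        if runs:
            return tx, runs[len(runs) // 2]
    # no CCC run anywhere: splice one into the first non-spike-in transcript
    tx = next(t for t in transcripts if not t.is_spikein)
    mid = len(tx) // 2
    seq = tx.sequence[:mid] + "CCC" + tx.sequence[mid + 3:]
    patched = simulate.Transcript(tx.id, seq, tx.is_spikein)
    transcripts[transcripts.index(tx)] = patched
    return patched, mid


def run_all(config: dict | None = None, out_dir="m5ckit_run", seed: int = 0) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    A stage failure propagates after the manifest (with the failing stage
    recorded) has been written.
    """
    cfg = default_config()
    cfg.update(config or {})
    cfg["sim"]["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "m5ckit",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": [],
        "files": {},
        "spikein_qc": {},
        "warnings": [],
        "failed_stage": None,
    }
    sim_cfg = SimConfig(**cfg["sim"])
    thresholds = FilterThresholds(**cfg["thresholds"])
    conditions = DEFAULT_CONDITIONS
    try:
        # --- simulate ---------------------------------------------------
        transcripts = simulate.make_transcriptome(
            cfg["n_transcripts"], cfg["length"], cfg["gc_fraction"],
            cfg["n_spikeins"], seed=seed,
        )
        cluster_tx, cluster_start = _ensure_cluster(transcripts, seed)
        truth = simulate.assign_truth(
            transcripts,
            n_random=cfg["n_background_sites"],
            random_levels=cfg.get("background_levels", {"EV": 0.3, "NSUN7": 0.3}),
            seed=seed,
        )
        cluster = simulate.plant_cluster(
            truth, cluster_tx, cluster_start, cfg["cluster_levels"]
        )
        manifest["planted_cluster"] = {
            "transcript_id": cluster_tx.id,
            "positions_0based": cluster,
        }
        io.write_fasta(transcripts, out / "reference.fa")
        io.write_truth_tsv(truth, out / "truth.tsv")
        reads_by = {}
        for cond in conditions:
            for rep in range(sim_cfg.n_replicates):
                reads = simulate.bisulfite_reads(transcripts, truth, sim_cfg, cond, rep)
                reads_by[(cond, rep)] = reads
                io.write_fastq(reads, out / f"reads_{cond}_rep{rep}.fq")
        manifest["stages"].append("simulate")
        # --- map + quant ------------------------------------------------
        index = index_reference(transcripts, k=cfg["k"])
        pileups = {}
        for (cond, rep), reads in reads_by.items():
            alns, summary = map_all(reads, index, cfg["max_mismatch_fraction"])
            io.write_tsv(io.alignments_to_frame(alns), out / f"aln_{cond}_rep{rep}.tsv")
            manifest.setdefault("mapping", {})[f"{cond}_rep{rep}"] = dataclasses.asdict(summary)
            pu = pileup(alns, {r.id: r.sequence for r in reads}, transcripts, rep)
            pileups[(cond, rep)] = pu
            io.write_tsv(pu, out / f"pileup_{cond}_rep{rep}.tsv")
        manifest["stages"].extend(["map", "quant"])
        # --- spike-in QC ------------------------------------------------
        for cond in conditions:
            stacked = pd.concat(
                [pileups[(cond, rep)] for rep in range(sim_cfg.n_replicates)],
                ignore_index=True,
            )
            report = spikein_conversion(stacked, transcripts, cfg["spikein_qc_threshold"])
            manifest["spikein_qc"][cond] = {
                "status": report.status,
                "efficiency": report.efficiency,
                "passed": report.passed,
            }
            if report.status != "ok" or not all(report.passed.values()):
                manifest["warnings"].append(f"spike-in conversion QC flagged for {cond}")
        # --- call -------------------------------------------------------
        candidates = {}
        for cond in conditions:
            stacked = pd.concat(
                [pileups[(cond, rep)] for rep in range(sim_cfg.n_replicates)],
                ignore_index=True,
            )
            cand = call_sites(stacked, thresholds)
            candidates[cond] = cand
            io.write_tsv(cand, out / f"candidates_{cond}.tsv")
        manifest["stages"].append("call")
        # --- diff -------------------------------------------------------
        union = set()
        for cand in candidates.values():
            if not cand.empty:
                union |= {
                    (r["transcript_id"], int(r["pos_0based"]))
                    for _, r in cand[cand["is_candidate"]].iterrows()
                }
        pu_a = pd.concat(
            [pileups[(conditions[0], r)] for r in range(sim_cfg.n_replicates)],
            ignore_index=True,
        )
        pu_b = pd.concat(
            [pileups[(conditions[1], r)] for r in range(sim_cfg.n_replicates)],
            ignore_index=True,
        )
        diff = call_differential(
            pu_a, pu_b, union, alpha=cfg["alpha"], min_delta=cfg["min_delta"]
        )
        io.write_tsv(diff, out / "diff.tsv")
        manifest["stages"].append("diff")
    except Exception as exc:  # record the failing stage, then re-raise
        done = set(manifest["stages"])
        order = ["simulate", "map", "quant", "call", "diff"]
        manifest["failed_stage"] = next((s for s in order if s not in done), "diff")
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["files"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def verify_manifest(out_dir) -> None:
    """Re-checksum every file the manifest references; raise on mismatch."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        path = out / name
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file {name}")
        if _sha256(path) != digest:
            raise RuntimeError(f"checksum mismatch for {name}")
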