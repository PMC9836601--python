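"""End-to-end orchestration: simulate -> align -> reconstruct -> damage ->
liftover, with a single config, deterministic seeding and a run log.

Config layout (YAML or dict)::

    seed: 7
    inputs:                # either this section ...
      fastq: [r1.fastq, r2.fastq]
      query: query.fasta
      annotation: features.tsv      # optional
    simulate:              # ... or this one
      truth_length: 16000
      divergence: 0.05
      depth: 20            # or n_pairs
      read_len: 150
      insert_mean: 150
      insert_sd: 30
      endogenous_fraction: 1.0
      seq_error: 0.0
      damage: {d_max: 0.3, decay: 0.5, floor: 0.01}
    align:
      preset: high
    call:
      min_depth_call: 1
      min_minor_count: 1
      min_minor_frac: 0.25
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .consensus import CallPolicy, build_pileup, reconstruct, write_calls_tsv
from .damage import deamination_asymmetry, summarize_ambiguities
from .errors import ConfigError
from .kalign import PRESETS, align_reads, write_alignments
from .liftover import feature_missingness, liftover_annotation
from .seqio import (
    Annotation,
    NamedSequence,
    read_annotation,
    read_fasta,
    read_fastq,
    write_fasta,
    write_feature_table,
)
from .simlib import (
    DamageParams,
    LibraryParams,
    mutate_genome,
    random_genome,
    simulate_library,
    write_library,
)

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _policy_from_config(cfg: dict) -> CallPolicy:
    call = cfg.get("call", {}) or {}
    return CallPolicy(
        min_depth_call=int(call.get("min_depth_call", 1)),
        min_minor_count=int(call.get("min_minor_count", 1)),
        min_minor_frac=float(call.get("min_minor_frac", 0.25)),
        max_alleles=int(call.get("max_alleles", 4)),
    )


def _n_pairs_for_depth(depth: float, truth_length: int, read_len: int,
                       endogenous_fraction: float) -> int:
    """Pairs needed so the mitochondrial genome sees ~`depth`x coverage."""
    endo = max(endogenous_fraction, 1e-12)
    return max(0, round(depth * truth_length / (2 * read_len) / endo))


def run_simulation(sim_cfg: dict, seed: int, out_dir: Path) -> dict:
    """Materialize a synthetic dataset (truth, query, FASTQ pair, truth
    table) under out_dir; returns paths plus the in-memory objects."""
    truth_length = int(sim_cfg.get("truth_length", 16000))
    truth = random_genome(truth_length, seed=seed,
                          gc=float(sim_cfg.get("gc", 0.45)))
    divergence = float(sim_cfg.get("divergence", 0.05))
    query = mutate_genome(truth, divergence,
                          ts_tv_ratio=float(sim_cfg.get("ts_tv_ratio", 2.0)),
                          seed=seed + 1)
    query.id = "query"
    read_len = int(sim_cfg.get("read_len", 150))
    endo = float(sim_cfg.get("endogenous_fraction", 1.0))
    if "n_pairs" in sim_cfg:
        n_pairs = int(sim_cfg["n_pairs"])
    else:
        n_pairs = _n_pairs_for_depth(float(sim_cfg.get("depth", 20.0)),
                                     truth_length, read_len, endo)
    lib = LibraryParams(
        n_pairs=n_pairs,
        read_len=read_len,
        insert_mean=float(sim_cfg.get("insert_mean", 150.0)),
        insert_sd=float(sim_cfg.get("insert_sd", 30.0)),
        endogenous_fraction=endo,
        seq_error=float(sim_cfg.get("seq_error", 0.0)),
        seed=seed + 2,
    )
    dmg_cfg = sim_cfg.get("damage") or {}
    dmg = DamageParams(
        d_max=float(dmg_cfg.get("d_max", 0.0)),
        decay=float(dmg_cfg.get("decay", 0.5)),
        floor=float(dmg_cfg.get("floor", 0.0)),
    )
    reads1, reads2, truths = simulate_library(truth, None, lib, dmg)
    fq1, fq2, tt = write_library(reads1, reads2, truths, out_dir / "sim")
    write_fasta([truth], out_dir / "truth.fasta")
    write_fasta([query], out_dir / "query.fasta")
    return {
        "truth": truth, "query": query,
        "reads": reads1 + reads2,
        "fastq": [str(fq1), str(fq2)], "truth_table": str(tt),
        "lib_params": lib, "damage_params": dmg,
    }


def run_end_to_end(config: dict, out_dir: str | Path) -> dict:
    """Run the full chain; returns the bundle manifest (also written as
    run_log.json). Partial outputs are removed on failure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run_end_to_end(config, out_dir, created)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def _track(created: list[Path], path: Path) -> Path:
    created.append(path)
    return path


def _run_end_to_end(config: dict, out_dir: Path, created: list[Path]) -> dict:
    seed = int(config.get("seed", 0))
    preset_name = str((config.get("align") or {}).get("preset", "high"))
    if preset_name not in PRESETS:
        raise ConfigError(f"unknown preset {preset_name!r}")
    preset = PRESETS[preset_name]
    policy = _policy_from_config(config)

    annotation: Annotation | None = None
    if "simulate" in config:
        sim = run_simulation(config["simulate"], seed, out_dir)
        created += [Path(p) for p in sim["fastq"] + [sim["truth_table"]]]
        created += [out_dir / "truth.fasta", out_dir / "query.fasta"]
        query: NamedSequence = sim["query"]
        reads: list[tuple[str, str]] = [(rid, s) for rid, s in sim["reads"]]
        input_desc = {"simulated": True, "fastq": sim["fastq"],
                      "truth_table": sim["truth_table"]}
    elif "inputs" in config:
        inputs = config["inputs"] or {}
        missing = [k for k in ("fastq", "query") if k not in inputs]
        if missing:
            raise ConfigError(f"inputs section lacks {missing}")
        fastq_paths = list(inputs["fastq"])
        for p in fastq_paths + [inputs["query"]]:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        query = read_fasta(inputs["query"])[0]
        query.circular = bool(inputs.get("circular", True))
        reads = []
        for p in fastq_paths:
            reads += [(r.id, r.residues) for r in read_fastq(p)]
        if inputs.get("annotation"):
            annotation = read_annotation(inputs["annotation"],
                                         genome_length=len(query))
        input_desc = {"simulated": False, "fastq": fastq_paths,
                      "query": str(inputs["query"])}
    else:
        raise ConfigError("config needs an 'inputs' or 'simulate' section")

    if not reads:
        logger.warning("no input reads: reconstruction will be all N")

    alignments, aln_summary = align_reads(reads, query, preset)
    write_alignments(alignments, str(_track(created, out_dir / "alignments.tsv")))

    pileup = build_pileup(alignments, dict(reads), query)
    recon = reconstruct(pileup, query, policy,
                        provenance={"preset": preset.name, "seed": seed,
                                    "align_summary": aln_summary})
    write_fasta([recon.sequence], _track(created, out_dir / "reconstruction.fasta"))
    write_calls_tsv(recon, pileup, query,
                    str(_track(created, out_dir / "calls.tsv")))
    tally = recon.tally()
    _track(created, out_dir / "tally.json").write_text(
        json.dumps(tally, indent=2) + "\n")

    summary = summarize_ambiguities(recon, query)
    summary.to_tsv(str(_track(created, out_dir / "ambiguity_matrix.tsv")))
    dmg_report = deamination_asymmetry(summary)
    _track(created, out_dir / "damage.json").write_text(
        json.dumps(dmg_report.to_dict(), indent=2) + "\n")
    _track(created, out_dir / "damage.txt").write_text(dmg_report.to_text() + "\n")

    feature_report_path = None
    if annotation is not None:
        lifted = liftover_annotation(annotation, recon)
        report = feature_missingness(recon, lifted)
        feature_report_path = _track(created, out_dir / "features.tsv")
        report.to_csv(feature_report_path, sep="\t", index=False)
        write_feature_table(lifted, _track(created, out_dir / "reconstruction.tbl"))

    manifest = {
        "version": __version__,
        "seed": seed,
        "preset": preset.name,
        "policy": recon.provenance["policy"],
        "inputs": input_desc,
        "align_summary": aln_summary,
        "tally": tally,
        "damage": dmg_report.to_dict(),
        "outputs": sorted(str(p.relative_to(out_dir)) for p in created
                          if p.exists()),
    }
    (out_dir / "run_log.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
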