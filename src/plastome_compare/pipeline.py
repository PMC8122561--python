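"""End-to-end pipeline: structure -> junctions -> loci -> diversity -> hotspots -> tree.

A :class:`RunConfig` captures every knob (inputs, thresholds, seed, output
directory) and round-trips losslessly through JSON, so a run can be
reproduced byte-for-byte from its recorded configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from plastome_compare import __version__
from plastome_compare.diversity import diversity_table, rank_hotspots
from plastome_compare.io import PlastomeRecord, read_genbank, write_panel_table
from plastome_compare.junctions import junction_table
from plastome_compare.loci import LocusAlignment, as_alignment, extract_loci, filter_loci
from plastome_compare.quadripartite import (
    NoInvertedRepeatError,
    detect_inverted_repeat,
    summarize_panel,
)
from plastome_compare.trees import nj_tree, p_distance_matrix, write_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON round-trippable)."""

    inputs: list[str] = field(default_factory=list)
    out_dir: str = "plastome_out"
    min_ir_len: int = 1000
    flank_window: int = 1500
    filter_min_len: int = 200
    filter_min_variable: int = 1
    gap_policy: str = "complete_deletion"
    window: int = 100
    step: int = 25
    top_coding: int = 9
    top_noncoding: int = 12
    build_tree: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_ir_len", "flank_window", "filter_min_len",
                     "filter_min_variable", "window", "step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(
    config: RunConfig, records: list[PlastomeRecord] | None = None
) -> dict[str, Path]:
    """Run every stage and write all report tables under ``config.out_dir``.

    ``records`` may be passed directly (e.g. a simulated panel); otherwise
    ``config.inputs`` are read as GenBank files.  Per-genome failures are
    logged and recorded in the run log; later stages proceed with the
    remaining genomes.  Returns the mapping of artifact name to path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        if not config.inputs:
            raise ValueError("no input files given")
        records = [read_genbank(p) for p in config.inputs]
    if not records:
        raise ValueError("no records to analyze")

    artifacts: dict[str, Path] = {}
    failures: dict[str, str] = {}

    partition_map = {}
    for rec in records:
        try:
            partition_map[rec.accession] = detect_inverted_repeat(
                rec, min_ir_len=config.min_ir_len
            )
        except (NoInvertedRepeatError, ValueError) as exc:
            failures[rec.accession] = str(exc)
            logger.warning("%s: %s", rec.accession, exc)
    usable = [r for r in records if r.accession in partition_map]

    table = summarize_panel(usable, min_ir_len=config.min_ir_len)
    artifacts["structure"] = out / "structure.tsv"
    write_panel_table(table, artifacts["structure"])

    jt = junction_table(
        [(r, partition_map[r.accession]) for r in usable],
        flank_window=config.flank_window,
    )
    artifacts["junctions"] = out / "junctions.tsv"
    jt.to_csv(artifacts["junctions"], sep="\t", index=False)

    loci = extract_loci(usable, partition_map)
    alignments: list[LocusAlignment] = []
    for ls in loci:
        try:
            alignments.append(as_alignment(ls))
        except ValueError as exc:
            logger.warning("locus %s skipped: %s", ls.name, exc)
    kept = filter_loci(
        alignments,
        min_len=config.filter_min_len,
        min_variable_sites=config.filter_min_variable,
    )
    artifacts["loci"] = out / "loci_kept.tsv"
    with open(artifacts["loci"], "w") as fh:
        fh.write("name\tcategory\tn\taligned_length\n")
        for a in kept:
            fh.write(f"{a.name}\t{a.category}\t{a.n}\t{a.aligned_length}\n")

    div = diversity_table(kept, gap_policy=config.gap_policy)
    artifacts["diversity"] = out / "diversity.tsv"
    div.round(5).to_csv(artifacts["diversity"], sep="\t", index=False)

    ranking = rank_hotspots(
        div, top_coding=config.top_coding, top_noncoding=config.top_noncoding
    )
    artifacts["hotspots"] = out / "hotspots.tsv"
    with open(artifacts["hotspots"], "w") as fh:
        fh.write(f"# selection rule: {ranking.rule}\n")
        for cat, sub in (("coding", ranking.coding), ("noncoding", ranking.noncoding)):
            sub = sub.copy()
            sub.insert(0, "rank", range(1, len(sub) + 1))
            fh.write(sub.round(5).to_csv(sep="\t", index=False))

    if config.build_tree and len(usable) >= 3:
        try:
            whole = LocusAlignment(
                "whole_genome", "coding", {r.accession: r.sequence for r in usable}
            )
            dm = p_distance_matrix(whole)
            artifacts["tree"] = out / "nj_tree.nwk"
            write_newick(nj_tree(dm), artifacts["tree"])
        except ValueError as exc:
            logger.warning("tree skipped: %s", exc)

    log = {
        "version": __version__,
        "config": asdict(config),
        "n_records": len(records),
        "n_usable": len(usable),
        "failures": failures,
        "n_loci_extracted": len(loci),
        "n_loci_kept": len(kept),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
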