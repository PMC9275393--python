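"""End-to-end orchestration: preprocess -> annotate -> clonotype -> assign -> analyze.

A single YAML config drives all stages; every run writes a manifest recording
the tool version, config hash, seeds, input digests and per-stage record
counts, so each number in the outputs is auditable. Stages are resumable from
their on-disk outputs; identical config and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_all, read_airr_tsv, write_airr_tsv
from .clonotype import cluster_frame
from .cohort import stratify
from .preprocess import (
    consensus_pass,
    read_fastq_with_umi,
    read_samplesheet,
    write_consensus_fasta,
    write_rejection_log,
)
from .reference import AnalysisParameters, default_clan_table, read_germline_fasta
from .stereotypy import ResidueClassTable, assign_frame, load_subset_definitions

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration fails schema validation."""


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    version: str
    config_hash: str
    seed: int | None
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def check_funnel(self) -> None:
        """Stage conservation: reads >= consensus >= rearrangements >= clonotypes."""
        order = ["reads_in", "consensus_kept", "rearrangements", "clonotypes"]
        present = [k for k in order if k in self.counts]
        for a, b in zip(present, present[1:]):
            if self.counts[a] < self.counts[b]:
                raise RuntimeError(
                    f"funnel violation: {a}={self.counts[a]} < {b}={self.counts[b]}"
                )
        if {"consensus_kept", "consensus_rejected", "umi_groups"} <= set(self.counts):
            if (
                self.counts["consensus_kept"] + self.counts["consensus_rejected"]
                != self.counts["umi_groups"]
            ):
                raise RuntimeError("consensus conservation violated")

    def write(self, path: str | Path) -> None:
        """Atomic write (tmp file + rename)."""
        path = Path(path)
        data = {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "counts": self.counts,
        }
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


REQUIRED_KEYS = {"germline", "outdir"}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    missing = REQUIRED_KEYS - set(cfg)
    if missing:
        raise ConfigError(f"config missing required keys: {sorted(missing)}")
    for key in ("germline", "subsets", "samplesheet", "rearrangements"):
        if key in cfg and cfg[key] is not None and not Path(cfg[key]).exists():
            raise ConfigError(f"config {key} path does not exist: {cfg[key]}")
    return cfg


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute all stages per the config; returns the run manifest.

    Entry points: either ``samplesheet`` (+ per-file FASTQ, UMI-tagged) for the
    full preprocess->annotate path, or ``rearrangements`` (an AIRR TSV) to
    start at clonotyping.
    """
    cfg = load_config(config_path)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    params = AnalysisParameters(**cfg.get("parameters", {}))
    clans = default_clan_table()
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        seed=cfg.get("seed"),
    )

    germline = read_germline_fasta(cfg["germline"], clans)
    manifest.input_digests["germline"] = _digest(Path(cfg["germline"]))

    if cfg.get("samplesheet"):
        sheet = read_samplesheet(cfg["samplesheet"])
        base = Path(cfg["samplesheet"]).parent
        reads = []
        for fname, frac in sheet.items():
            fpath = base / fname
            manifest.input_digests[fname] = _digest(fpath)
            reads.extend(
                read_fastq_with_umi(
                    fpath, frac, cfg.get("umi_location", "header")
                )
            )
        logger.info("stage=preprocess reads_in=%d", len(reads))
        manifest.counts["reads_in"] = len(reads)
        kept, rejected = consensus_pass(reads, params)
        manifest.counts["umi_groups"] = len(kept) + len(rejected)
        manifest.counts["consensus_kept"] = len(kept)
        manifest.counts["consensus_rejected"] = len(rejected)
        write_consensus_fasta(kept, outdir / "consensus.fasta")
        write_rejection_log(rejected, outdir / "rejections.tsv")

        logger.info("stage=annotate consensus=%d", len(kept))
        rearr, failures = annotate_all(kept, germline, params)
        rearr = [r for r in rearr if r.productive]
        manifest.counts["rearrangements"] = len(rearr)
        manifest.counts["annotation_failures"] = len(failures)
        write_airr_tsv(rearr, outdir / "rearrangements.tsv")
        rearr_df = read_airr_tsv(outdir / "rearrangements.tsv")
    elif cfg.get("rearrangements"):
        manifest.input_digests["rearrangements"] = _digest(
            Path(cfg["rearrangements"])
        )
        rearr_df = read_airr_tsv(cfg["rearrangements"])
        rearr_df = rearr_df[rearr_df["productive"]]
        manifest.counts["rearrangements"] = len(rearr_df)
    else:
        raise ConfigError("config needs either 'samplesheet' or 'rearrangements'")

    logger.info("stage=clonotype rearrangements=%d", len(rearr_df))
    clono = cluster_frame(rearr_df, scope=cfg.get("clonotype_scope", "donor"))
    manifest.counts["clonotypes"] = len(clono)
    clono.to_csv(outdir / "clonotypes.tsv", sep="\t", index=False)

    if cfg.get("subsets"):
        manifest.input_digests["subsets"] = _digest(Path(cfg["subsets"]))
        defs = load_subset_definitions(cfg["subsets"], clans)
        logger.info("stage=assign clonotypes=%d subsets=%d", len(clono), len(defs))
        clono["mut_status"] = np.where(
            clono["v_mutation_pct"] >= params.mutation_threshold_pct, "M", "U"
        )
        assigned = assign_frame(clono, defs, clans, ResidueClassTable(), params)
        manifest.counts["clsig_assigned"] = int(assigned["is_clsig"].sum())
        assigned.to_csv(outdir / "assignments.tsv", sep="\t", index=False)

        for design in cfg.get("designs", [["cd5", "mut_status"]]):
            rec = stratify(assigned, list(design), params)
            name = "freq_" + "_".join(design) + ".tsv"
            rec.to_csv(outdir / name, sep="\t", index=False)

    manifest.check_funnel()
    manifest.write(outdir / "manifest.json")
    return manifest
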