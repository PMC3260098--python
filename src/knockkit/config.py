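"""Run configuration and the end-to-end design pipeline entry point."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import reports
from .genome_io import Genome, load_annotation, load_genome
from .markers import BUILTIN_MARKERS, MarkerSystem, builtin_marker
from .primer_design import (
    DesignConstraints,
    design_genome,
    get_preset,
)

log = logging.getLogger("knockkit")


@dataclass
class RunConfig:
    genome: str
    annotation: str
    out_dir: str
    marker: str = "pyr4"
    preset: str = "database"
    constraint_overrides: dict = field(default_factory=dict)
    screen: bool = True
    write_cassettes: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.marker not in BUILTIN_MARKERS:
            raise ValueError(
                f"marker must be one of {BUILTIN_MARKERS}, got {self.marker!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def constraints(self) -> DesignConstraints:
        base = get_preset(self.preset)
        if not self.constraint_overrides:
            return base
        valid = {f.name for f in dataclasses.fields(DesignConstraints)}
        unknown = set(self.constraint_overrides) - valid
        if unknown:
            raise ValueError(f"unknown constraint keys: {sorted(unknown)}")
        return dataclasses.replace(base, **self.constraint_overrides)


def run_design(cfg: RunConfig) -> dict:
    """Genome-wide knockout design: primer + screen tables, summary JSON.

    Per-gene design failures are data (status/reason columns), not errors;
    a nonzero exit is reserved for unreadable inputs or internal faults.
    """
    logging.basicConfig(level=cfg.log_level)
    genome = load_genome(cfg.genome)
    annotation = load_annotation(cfg.annotation, genome)
    marker = builtin_marker(cfg.marker)
    constraints = cfg.constraints()
    log.info(
        "designing %d genes on %d contigs (marker=%s, preset=%s)",
        len(annotation), len(genome.contig_names), cfg.marker, cfg.preset,
    )
    designs, summary = design_genome(
        genome, annotation, constraints, marker, screen=cfg.screen
    )

    os.makedirs(cfg.out_dir, exist_ok=True)
    reports.write_tsv(
        reports.primer_table(designs), os.path.join(cfg.out_dir, "primer_table.tsv")
    )
    if cfg.screen:
        reports.write_tsv(
            reports.screen_table((d.gene_id, d.screen) for d in designs),
            os.path.join(cfg.out_dir, "screen_table.tsv"),
        )
    if cfg.write_cassettes:
        from .assembly import assemble_cassette

        entries = []
        for d in designs:
            if d.status == "full":
                asm = assemble_cassette(d, marker)
                if asm.ok:
                    entries.append((f"cassette_{d.gene_id}", asm.cassette_seq))
        reports.write_cassette_fasta(
            entries, os.path.join(cfg.out_dir, "cassettes.fa")
        )

    out = {
        "summary": summary,
        "config": {
            "genome": cfg.genome,
            "annotation": cfg.annotation,
            "marker": cfg.marker,
            "preset": cfg.preset,
            "constraint_overrides": cfg.constraint_overrides,
            "screen": cfg.screen,
            "seed": cfg.seed,
        },
    }
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
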