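"""End-to-end orchestration: simulate/load -> QC -> normalize -> DE ->
region score -> gene-score correlation -> reports.

A single integer seed drives every stochastic stage; per-stage seeds are
derived deterministically from it, so a run is byte-stable given its
config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as scio
from .containers import CountMatrix
from .destats import QCThresholds, find_markers, qc_filter
from .spatial import (lognormalize, score_and_correlate,
                      select_correlated_genes)
from .synthetic import SimCountConfig, generate_counts

logger = logging.getLogger("spacecat.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """One document controlling a full run.

    Either ``counts_path``/``metadata_path`` point at existing inputs, or
    ``simulate`` holds :class:`~spacecat.synthetic.SimCountConfig` fields
    and the input is generated. ``groupby``/``group_a`` name the metadata
    column and label defining the tagged region for DE; the up-regulated
    genes of that comparison become the region-score gene set.
    """

    outdir: str = "spacecat_run"
    seed: int = 0
    counts_path: str | None = None
    metadata_path: str | None = None
    simulate: dict = field(default_factory=lambda: {"n_cells": 1500})
    min_genes_per_cell: int = 200
    scale: float = 10_000.0
    groupby: str = "region_label"
    group_a: str = "border"
    de_test: str = "bimod"
    de_alpha: float = 0.05
    n_permutations: int = 999
    correlation_alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.counts_path is None) != (self.metadata_path is None):
            raise ValueError("counts_path and metadata_path must be given "
                             "together")
        if self.counts_path is not None:
            for p in (self.counts_path, self.metadata_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")


@dataclass
class RunReport:
    """Per-stage bookkeeping for a pipeline run."""

    seed: int = 0
    stages: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def mark(self, stage: str, **metrics) -> None:
        self.stages.append(stage)
        self.counts[stage] = metrics
        logger.info("stage=%s %s", stage, metrics)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _derive_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; writes artifacts under ``config.outdir``.

    Artifacts: counts/ (MTX), metadata.csv, qc_report.csv, de_markers.csv,
    region_score.csv, gene_correlations.csv, genes_positive.txt,
    genes_negative.txt, report.json (with per-file checksums).
    """
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20))
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    sim_seed, perm_seed = _derive_seeds(config.seed, 2)

    # -- input ---------------------------------------------------------
    if config.counts_path is not None:
        counts = scio.read_counts(config.counts_path)
        meta = scio.read_metadata(config.metadata_path)
    else:
        sim_cfg = SimCountConfig(**{**config.simulate, "seed": sim_seed})
        counts, meta, _ = generate_counts(sim_cfg)
    if config.groupby not in meta.columns:
        raise KeyError(f"metadata is missing column {config.groupby!r}")
    meta = meta.loc[list(counts.cells)]
    report.mark("input", n_genes=counts.n_genes, n_cells=counts.n_cells)

    # -- qc ------------------------------------------------------------
    counts, qc_report = qc_filter(
        counts, QCThresholds(min_genes_per_cell=config.min_genes_per_cell)
    )
    meta = meta.loc[list(counts.cells)]
    report.mark("qc", n_cells=counts.n_cells,
                n_removed=int((~qc_report["retained"]).sum()))

    # -- normalize -----------------------------------------------------
    expr = lognormalize(counts, scale=config.scale)
    report.mark("normalize", scale=config.scale)

    # -- differential expression ---------------------------------------
    groups = np.where(meta[config.groupby].astype(str) == str(config.group_a),
                      config.group_a, "rest")
    if (groups == config.group_a).sum() < 2 or (groups == "rest").sum() < 2:
        raise ValueError(
            f"group {config.group_a!r} of column {config.groupby!r} must "
            "split cells into two groups of >= 2"
        )
    markers = find_markers(expr, groups, test=config.de_test,
                           alpha=config.de_alpha)
    de = markers[config.group_a]
    up_genes = list(de.loc[(de["p_adj"] < config.de_alpha)
                           & (de["effect"] > 0), "gene"])
    report.mark("de", test=config.de_test, n_up=len(up_genes),
                n_down=int(((de["p_adj"] < config.de_alpha)
                            & (de["effect"] < 0)).sum()))
    if not up_genes:
        raise RuntimeError("no upregulated genes found; cannot build a "
                           "region score")

    # -- score + correlate ---------------------------------------------
    result = score_and_correlate(expr, up_genes,
                                 n_perm=config.n_permutations,
                                 seed=perm_seed)
    negative, positive = select_correlated_genes(
        result.correlations, alpha=config.correlation_alpha
    )
    report.mark("score", n_score_genes=len(up_genes))
    report.mark("correlate", n_positive=len(positive),
                n_negative=len(negative),
                n_permutations=config.n_permutations)

    # -- write artifacts ------------------------------------------------
    scio.write_counts(counts, outdir / "counts")
    scio.write_metadata(meta, outdir / "metadata.csv")
    qc_report.to_csv(outdir / "qc_report.csv")
    de.to_csv(outdir / "de_markers.csv", index=False)
    score_frame = result.score.to_frame()
    score_frame["rank"] = result.score.rank(ascending=False,
                                            method="first").astype(int)
    score_frame.to_csv(outdir / "region_score.csv", index_label="cell")
    corr = result.correlations.copy()
    corr["class"] = "ns"
    corr.loc[positive, "class"] = "pos"
    corr.loc[negative, "class"] = "neg"
    corr.to_csv(outdir / "gene_correlations.csv")
    (outdir / "genes_positive.txt").write_text("\n".join(positive) + "\n")
    (outdir / "genes_negative.txt").write_text("\n".join(negative) + "\n")

    artifacts = sorted(p for p in outdir.rglob("*") if p.is_file()
                       and p.name != "report.json")
    report.counts["checksums"] = {
        str(p.relative_to(outdir)): _checksum(p) for p in artifacts
    }
    (outdir / "report.json").write_text(report.to_json())
    report.mark("done", n_artifacts=len(artifacts))
    return report
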