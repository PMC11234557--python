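"""End-to-end pipeline orchestration with run manifests.

Stages run in a fixed order — qc, detect, summarize, consensus, islands,
annotate, grm, assoc — each writing its TSV artifact plus a JSON manifest
(input hashes, parameters, row counts) so a rerun with identical inputs is
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import association, consensus as consensus_mod, grm as grm_mod, roh
from .genotype_io import (GenotypeMatrix, QCParams, apply_qc,
                          read_phenotypes, read_plink_binary, read_plink_text)

log = logging.getLogger(__name__)

STAGES = ("qc", "detect", "summarize", "consensus", "islands", "annotate",
          "grm", "assoc")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str
    ped: str | None = None
    map: str | None = None
    bed: str | None = None
    bim: str | None = None
    fam: str | None = None
    phenotypes: str | None = None
    annotation: str | None = None
    annotation_format: str = "gff3"
    qc: QCParams = field(default_factory=QCParams)
    scan: roh.ROHScanParams = field(default_factory=roh.ROHScanParams)
    consensus_min_snps: int = 5
    consensus_min_freq: float = 0.05
    island_freq: float = 0.80
    traits: list | None = None
    alpha: float = 0.01
    stop_after: str | None = None
    seed: int = 17

    def __post_init__(self) -> None:
        if self.stop_after is not None and self.stop_after not in STAGES:
            raise ValueError(f"stop_after must be one of {STAGES}")
        has_text = self.ped and self.map
        has_binary = self.bed and self.bim and self.fam
        if not (has_text or has_binary):
            raise ValueError("config needs ped+map or bed+bim+fam genotype paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "scan" in raw:
            raw["scan"] = roh.ROHScanParams(**raw["scan"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (sorted(v) if isinstance(v, (set, frozenset)) else v)
            for k, v in d.items()}


class PipelineRun:
    """Executes the stages, accumulating artifacts and manifests."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.warnings: list[str] = []

    def _manifest(self, stage: str, **payload) -> None:
        payload = {"stage": stage, **payload, "warnings": self.warnings[-5:]}
        with open(self.out / f"{stage}.manifest.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    def _load_genotypes(self) -> GenotypeMatrix:
        c = self.config
        if c.ped and c.map:
            return read_plink_text(c.ped, c.map)
        return read_plink_binary(c.bed, c.bim, c.fam)

    def run(self) -> dict:
        c = self.config
        artifacts: dict = {}

        g = self._load_genotypes()
        g, qc_report = apply_qc(g, c.qc)
        qc_report.to_frame().to_csv(self.out / "qc_report.tsv", sep="\t", index=False)
        inputs = {p: _sha256(p) for p in (c.ped, c.map, c.bed, c.bim, c.fam) if p}
        self._manifest("qc", inputs=inputs, params=_params_dict(c.qc),
                       n_individuals=g.n_individuals, n_snps=g.n_snps)
        artifacts["genotypes"] = g
        artifacts["qc_report"] = qc_report
        if c.stop_after == "qc":
            return artifacts

        min_snps = roh.resolve_min_snps(g, c.scan)
        segments = roh.detect_roh(g, c.scan)
        seg_df = roh.segments_to_frame(segments)
        seg_df.to_csv(self.out / "roh_segments.tsv", sep="\t", index=False)
        scan_params = _params_dict(c.scan)
        scan_params["min_snps_effective"] = min_snps
        self._manifest("detect", params=scan_params, n_segments=len(segments))
        artifacts["segments"] = segments
        if c.stop_after == "detect":
            return artifacts

        summary = roh.summarize_roh(segments, g.individuals)
        summary.per_individual.to_csv(self.out / "roh_per_individual.tsv",
                                      sep="\t", index=False)
        summary.per_class.to_csv(self.out / "roh_per_class.tsv", sep="\t", index=False)
        self._manifest("summarize", n_individuals=len(summary.per_individual))
        artifacts["summary"] = summary
        if c.stop_after == "summarize":
            return artifacts

        pools = consensus_mod.pool_segments(segments, g.n_individuals)
        cons = consensus_mod.select_consensus(pools, g.snps,
                                              min_snps=c.consensus_min_snps,
                                              min_freq=c.consensus_min_freq)
        consensus_mod.consensus_to_frame(cons).to_csv(
            self.out / "consensus.tsv", sep="\t", index=False)
        consensus_mod.write_bed(cons, self.out / "consensus.bed")
        self._manifest("consensus", n_pools=len(pools), n_consensus=len(cons),
                       params={"min_snps": c.consensus_min_snps,
                               "min_freq": c.consensus_min_freq})
        artifacts["pools"] = pools
        artifacts["consensus"] = cons
        if c.stop_after == "consensus":
            return artifacts

        islands = consensus_mod.select_islands(cons, island_freq=c.island_freq)
        consensus_mod.consensus_to_frame(islands).to_csv(
            self.out / "islands.tsv", sep="\t", index=False)
        self._manifest("islands", n_islands=len(islands),
                       params={"island_freq": c.island_freq})
        artifacts["islands"] = islands
        if c.stop_after == "islands":
            return artifacts

        gene_overlaps = None
        if c.annotation:
            genes = annotate_mod.load_annotation(c.annotation, c.annotation_format)
            gene_overlaps = annotate_mod.intersect_genes(cons, genes)
            annotate_mod.annotation_table(islands, genes).to_csv(
                self.out / "islands_annotated.tsv", sep="\t", index=False)
            self._manifest("annotate", inputs={c.annotation: _sha256(c.annotation)},
                           n_genes=len(genes))
        artifacts["gene_overlaps"] = gene_overlaps
        if c.stop_after == "annotate":
            return artifacts

        gm = grm_mod.vanraden_grm(g)
        gm, stab_info = grm_mod.stabilize(gm)
        grm_mod.write_grm(gm, self.out / "grm")
        self._manifest("grm", n=gm.n, stabilize=stab_info)
        artifacts["grm"] = gm
        if c.stop_after == "grm":
            return artifacts

        if c.phenotypes:
            phenos = read_phenotypes(c.phenotypes)
            carriers = consensus_mod.carrier_matrix(cons, g.individuals)
            results = association.run_association(
                phenos, cons, carriers, gm, traits=c.traits, alpha=c.alpha)
            results.to_csv(self.out / "association.tsv", sep="\t", index=False)
            report = association.significant_report(results, cons, gene_overlaps)
            report.to_csv(self.out / "significant_regions.tsv", sep="\t", index=False)
            n_sig = int(results["significant"].sum()) if len(results) else 0
            self._manifest("assoc", inputs={c.phenotypes: _sha256(c.phenotypes)},
                           params={"alpha": c.alpha}, n_tests=len(results),
                           n_significant=n_sig)
            artifacts["association"] = results
            artifacts["significant_regions"] = report
        return artifacts


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages (or up to ``config.stop_after``); returns artifacts."""
    return PipelineRun(config).run()
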