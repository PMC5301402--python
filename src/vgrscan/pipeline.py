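"""End-to-end orchestration: simulate or load genotypes, QC, differentiation
scans, kinship + EMMAX, region calling, cross-method intersection, candidate
gene annotation, Manhattan plots, and a run manifest.

Every stage is a pure function of (inputs, config, seed); re-running with
the same configuration reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .annotation import (DEFAULT_FLANK_BP, annotate_regions, hits_to_dataframe,
                         read_gene_intervals)
from .genotype_io import GenotypeDataset, QCParams, apply_qc, read_ped_map, write_ped_map
from .mixed_model import emma_reml, emmax_scan, ibs_kinship, population_phenotype
from .regions import (RegionParams, call_regions, intersect_region_sets,
                      recovery_score, regions_to_bed, vgrs_to_dataframe)
from .simulate import SimConfig, simulate_dataset
from .stats import bonferroni_threshold, fisher_track, fst_track, genomic_inflation

logger = logging.getLogger("vgrscan")

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline",
           "scan_dataset", "ScanOutputs"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # input: either a simulation config or PED/MAP paths
    sim: Optional[SimConfig] = None
    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    genes_path: Optional[str] = None
    genes_format: str = "bed"
    qc: QCParams = field(default_factory=QCParams)
    regions: RegionParams = field(default_factory=RegionParams)
    flank_bp: int = DEFAULT_FLANK_BP
    kinship_chroms: str = "autosomes"
    emmax_test: str = "chi2"
    alpha: float = 0.05
    recovery_slack_bp: int = 1_500_000
    out_dir: Optional[str] = None
    make_plots: bool = True
    write_genotypes: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and (self.ped_path is None or self.map_path is None):
            raise ValueError("provide either a SimConfig or PED/MAP paths")
        for p in (self.ped_path, self.map_path, self.genes_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict = field(default_factory=dict)
    inflation: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    recovery: Optional[dict] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


@dataclass
class ScanOutputs:
    """In-memory results of QC + both scans + region calling."""

    dataset: GenotypeDataset
    qc_report: object
    fst: object
    fisher: object
    emmax: object
    kinship: object
    vc: object
    fst_regions: list
    emmax_regions: list
    vgrs: list


def scan_dataset(dataset: GenotypeDataset, qc: QCParams = QCParams(),
                 region_params: RegionParams = RegionParams(),
                 kinship_chroms: str = "autosomes",
                 emmax_test: str = "chi2") -> ScanOutputs:
    """QC -> Fst + Fisher tracks -> kinship/REML/EMMAX -> regions -> VGRs."""
    qcd, report = apply_qc(dataset, qc)
    if qcd.n_markers == 0:
        raise ValueError("no markers survive QC")
    fst = fst_track(qcd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fisher = fisher_track(qcd)
    kin = ibs_kinship(qcd, chroms=kinship_chroms)
    y = population_phenotype(qcd)
    vc = emma_reml(y, None, kin)
    emx = emmax_scan(qcd, y, kin, vc, test=emmax_test)
    fst_regions = call_regions(fst, region_params, direction="desc")
    emx_regions = call_regions(emx.to_track(), region_params, direction="asc")
    vgrs = intersect_region_sets(fst_regions, emx_regions)
    return ScanOutputs(qcd, report, fst, fisher, emx, kin, vc,
                       fst_regions, emx_regions, vgrs)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage, serializing each output under ``config.out_dir``.

    Aborts with :class:`PipelineError` naming the failing stage, after
    writing the partial manifest.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config=_config_snapshot(config))

    def record(path: Path) -> None:
        manifest.outputs.append(str(path))

    state: dict = {}

    def stage_input():
        if config.sim is not None:
            dataset, truth = simulate_dataset(config.sim)
            state["truth"] = truth
            if out:
                truth.planted_to_bed(out / "truth_planted.bed")
                record(out / "truth_planted.bed")
                truth.loci_dataframe().to_csv(out / "truth_loci.tsv", sep="\t",
                                              index=False, float_format="%.10g")
                record(out / "truth_loci.tsv")
                if config.write_genotypes:
                    write_ped_map(dataset, out / "genotypes.ped", out / "genotypes.map")
                    record(out / "genotypes.ped")
                    record(out / "genotypes.map")
        else:
            dataset = read_ped_map(config.ped_path, config.map_path)
        state["dataset"] = dataset
        manifest.stages["input"] = {"n_samples": dataset.n_samples,
                                    "n_markers": dataset.n_markers}

    def stage_scan():
        res = scan_dataset(state["dataset"], config.qc, config.regions,
                           config.kinship_chroms, config.emmax_test)
        state["res"] = res
        manifest.stages["qc"] = {"n_input": res.qc_report.n_input,
                                 "n_pass": res.qc_report.n_pass,
                                 "removals": res.qc_report.removals}
        n_tests = res.dataset.n_markers
        manifest.stages["assoc"] = {
            "n_markers": n_tests,
            "bonferroni_threshold": bonferroni_threshold(config.alpha, n_tests),
            "reml_delta": res.vc.delta,
        }
        manifest.inflation["fisher"] = genomic_inflation(res.fisher.values)
        manifest.inflation["emmax"] = genomic_inflation(res.emmax.p_values)
        logger.info("QC: %d/%d markers pass; lambda fisher=%.3f emmax=%.3f",
                    res.qc_report.n_pass, res.qc_report.n_input,
                    manifest.inflation["fisher"], manifest.inflation["emmax"])
        if out:
            res.fst.to_tsv(out / "fst_track.tsv")
            res.fisher.to_tsv(out / "fisher_track.tsv")
            res.emmax.to_dataframe().to_csv(out / "emmax_track.tsv", sep="\t",
                                            index=False, float_format="%.10g")
            res.kinship.to_tsv(out / "kinship.tsv")
            for p in ("fst_track.tsv", "fisher_track.tsv", "emmax_track.tsv",
                      "kinship.tsv"):
                record(out / p)

    def stage_regions():
        res = state["res"]
        manifest.stages["regions"] = {"fst": len(res.fst_regions),
                                      "emmax": len(res.emmax_regions),
                                      "vgr": len(res.vgrs)}
        if "truth" in state:
            sens, fp = recovery_score(res.vgrs, state["truth"].planted_intervals,
                                      slack_bp=config.recovery_slack_bp)
            manifest.recovery = {"sensitivity": sens, "false_positives": fp}
        if out:
            regions_to_bed(res.fst_regions, out / "fst_regions.bed")
            regions_to_bed(res.emmax_regions, out / "emmax_regions.bed")
            df = vgrs_to_dataframe(res.vgrs)
            df.to_csv(out / "vgr.tsv", sep="\t", index=False, float_format="%.6g")
            with open(out / "vgr.bed", "w") as fh:
                for v in res.vgrs:
                    fh.write(f"{v.chrom}\t{v.start_bp - 1}\t{v.end_bp}\tVGR{v.index}\n")
            for p in ("fst_regions.bed", "emmax_regions.bed", "vgr.tsv", "vgr.bed"):
                record(out / p)

    def stage_annotate():
        if config.genes_path is None:
            return
        genes = read_gene_intervals(config.genes_path, config.genes_format)
        hits = annotate_regions(state["res"].vgrs, genes, config.flank_bp)
        manifest.stages["annotation"] = {"n_genes": len(genes), "n_hits": len(hits)}
        if out:
            hits_to_dataframe(hits).to_csv(out / "annotation_hits.tsv", sep="\t",
                                           index=False)
            record(out / "annotation_hits.tsv")

    def stage_plot():
        if not (config.make_plots and out):
            return
        import matplotlib.pyplot as plt

        from .plotting import manhattan_plot
        res = state["res"]
        thr = manifest.stages["assoc"]["bonferroni_threshold"]
        for name, track, regs in (("manhattan_fst", res.fst, res.fst_regions),
                                  ("manhattan_emmax", res.emmax.to_track(),
                                   res.emmax_regions)):
            fig = manhattan_plot(track, regs, out / f"{name}.png",
                                 threshold=thr if name.endswith("emmax") else None)
            plt.close(fig)
            record(out / f"{name}.png")

    stages = [("input", stage_input), ("scan", stage_scan),
              ("regions", stage_regions), ("annotation", stage_annotate),
              ("plot", stage_plot)]
    for name, fn in stages:
        try:
            fn()
        except Exception as e:  # noqa: BLE001 - abort w/ stage name + partial manifest
            if out:
                manifest.to_json(out / "manifest.json")
            raise PipelineError(name, e) from e
    if out:
        manifest.to_json(out / "manifest.json")
        record(out / "manifest.json")
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
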