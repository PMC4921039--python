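"""End-to-end pipeline: simulate/load -> trial models -> QC -> diversity ->
structure -> scan -> multi-QTL -> report.

Driven by a single YAML config; every stage writes its artefacts to the
output directory and the run is summarised in a JSON manifest (seed,
thresholds, per-stage record counts).  Identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import dice_matrix, neighbor_joining
from .markers import MarkerMatrix, filter_maf, find_duplicate_markers
from .multiqtl import forward_select, report_ase
from .pheno import (PhenotypeTable, compute_blue_table, compute_heritability,
                    fit_trial_model)
from .scan import scan_all
from .simdata import SimConfig, simulate_population, simulate_trials
from .structure import infer_structure

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("canegwas")

STAGES = ["simulate", "pheno", "qc", "diversity", "structure", "scan",
          "multiqtl", "report"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    simulate: bool = True
    genotypes_file: Path | None = None
    phenotypes_file: Path | None = None
    metadata_file: Path | None = None
    maf: float = 0.1
    pca_alpha: float = 0.05
    fdr: float = 0.05
    report_fdr: float = 0.01
    entry_p: float = 0.01
    per_group: int = 1
    plot_area_m2: float = 48.0
    trait_units: dict = field(default_factory=lambda: {"CY": "kg_per_plot",
                                                       "SC": "percent"})
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, lo, hi in (("maf", 0.0, 0.5), ("pca_alpha", 0.0, 1.0),
                             ("fdr", 0.0, 1.0), ("report_fdr", 0.0, 1.0),
                             ("entry_p", 0.0, 1.0)):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"threshold {name}={v} outside ({lo}, {hi}]")
        if self.plot_area_m2 <= 0:
            raise ValueError("plot_area_m2 must be positive")
        if not self.simulate:
            for name in ("genotypes_file", "phenotypes_file"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.setdefault("out_dir", "canegwas_out")
        for key in ("out_dir", "genotypes_file", "phenotypes_file",
                    "metadata_file"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "thresholds": {"maf": config.maf, "pca_alpha": config.pca_alpha,
                               "fdr": config.fdr,
                               "report_fdr": config.report_fdr,
                               "entry_p": config.entry_p},
                "stages": {}}
    stage = "simulate"
    try:
        # -- simulate or load -------------------------------------------
        if config.simulate:
            sim = SimConfig(seed=config.seed, **config.sim_overrides)
            markers, truth = simulate_population(sim)
            phenos = simulate_trials(markers, truth, sim)
            markers.to_tsv(out / "genotypes.tsv", out / "markers_meta.tsv")
            phenos.to_tsv(out / "phenotypes.tsv")
            with open(out / "truth.txt", "w") as fh:
                for trait, ids in truth.qtl_markers.items():
                    fh.write(f"qtl.{trait}\t{','.join(ids)}\n")
                for g, f in truth.family_of.items():
                    fh.write(f"family.{g}\t{f}\n")
        else:
            markers = MarkerMatrix.from_tsv(config.genotypes_file,
                                            config.metadata_file)
            phenos = PhenotypeTable.from_tsv(config.phenotypes_file)
        manifest["stages"]["simulate"] = {
            "n_genotypes": markers.n_genotypes,
            "n_markers": markers.n_markers,
            "n_plots": len(phenos.records)}
        log.info("simulate/load: %s", manifest["stages"]["simulate"])

        # -- phenotype models -------------------------------------------
        stage = "pheno"
        blues = compute_blue_table(phenos)
        blues.to_tsv(out / "blues.tsv")
        herit = []
        for trait in phenos.traits:
            sub = phenos.subset(trait=trait)
            for year in sorted(sub["year"].unique()):
                for loc in sorted(sub["location"].unique()):
                    h = compute_heritability(phenos, trait, year, loc)
                    herit.append({"trait": trait, "year": year,
                                  "location": loc, "h2": h.h2,
                                  "sigma2_g": h.sigma2_g,
                                  "sigma2_e": h.sigma2_e,
                                  "replicates": h.replicates})
        pd.DataFrame(herit).to_csv(out / "heritability.tsv", sep="\t",
                                   index=False)
        manifest["stages"]["pheno"] = {
            "n_trait_years": blues.values.shape[1],
            "n_heritabilities": len(herit)}

        # -- marker QC ---------------------------------------------------
        stage = "qc"
        kept, excluded = filter_maf(markers, config.maf)
        dup_groups = find_duplicate_markers(kept)
        excluded.to_csv(out / "markers_excluded.tsv", sep="\t")
        manifest["stages"]["qc"] = {"kept": kept.n_markers,
                                    "excluded": len(excluded),
                                    "duplicate_groups": len(dup_groups)}

        # -- diversity ----------------------------------------------------
        stage = "diversity"
        dmat = dice_matrix(kept)
        tree = neighbor_joining(dmat)
        dmat.to_tsv(out / "dice.tsv")
        (out / "tree.nwk").write_text(tree.newick + "\n")
        manifest["stages"]["diversity"] = {"n_leaves": len(tree.leaf_names),
                                           "clamped_branches": tree.clamped}

        # -- structure ----------------------------------------------------
        stage = "structure"
        model = infer_structure(kept, per_group=config.per_group,
                                seed=config.seed, alpha=config.pca_alpha)
        model.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        model.tw_table.to_csv(out / "tracy_widom.tsv", sep="\t", index=False)
        model.q.to_csv(out / "q_design.tsv", sep="\t")
        manifest["stages"]["structure"] = {
            "n_pca_markers": len(model.marker_ids),
            "significant_axes": model.k}

        # -- scan + multi-QTL --------------------------------------------
        stage = "scan"
        scan_counts = {}
        models = {}
        for trait, year in blues.values.columns:
            y = blues.column(trait, year)
            res = scan_all(y, kept, model.q, alpha=config.fdr,
                           report_alpha=config.report_fdr)
            res.to_tsv(out / f"scan_{trait}_{year}.tsv")
            scan_counts[f"{trait}:{year}"] = {
                "tested": len(res.table),
                "candidates": int(len(res.candidates)),
                "reported": int(len(res.reported))}
            models[(trait, year)] = (y, res)
        manifest["stages"]["scan"] = scan_counts

        stage = "multiqtl"
        mq_counts = {}
        for (trait, year), (y, res) in models.items():
            mq = forward_select(y, list(res.reported), kept, model.q,
                                entry_p=config.entry_p, order_by=res)
            units = config.trait_units.get(trait, "percent")
            rep = report_ase(mq, units, config.plot_area_m2)
            rep.index.name = "marker"
            rep.to_csv(out / f"multiqtl_{trait}_{year}.tsv", sep="\t")
            mq_counts[f"{trait}:{year}"] = {"selected": len(mq.selected)}
        manifest["stages"]["multiqtl"] = mq_counts

        stage = "report"
        manifest["stages"]["report"] = {"artifacts": sorted(
            p.name for p in out.iterdir() if p.is_file())}
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
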