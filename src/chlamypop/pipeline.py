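"""End-to-end orchestration: simulate/load -> filter -> annotate -> analyse.

A declarative YAML config drives the run: either an ``inputs`` block
(VCF + GFF3 + FASTA + callable BED + metadata) or a ``simulation``
block (forwarded to :class:`chlamypop.simulate.SimulationConfig`).
Every table is written as TSV with a header comment recording the seed,
and a machine-readable ``summary.json`` collects the headline numbers.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diversity, io_annotation, ld, sfs, structure
from .simulate import SimulationConfig, emit_files, simulate_panel

log = logging.getLogger("chlamypop")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    output_dir: str = "chlamypop_out"
    simulation: dict | None = None
    inputs: dict | None = None
    window_size: int = 100_000
    ld_bin_width: int = 25_000
    rho_bin_width: int = 2_000
    max_distance: int | None = None
    quality_threshold: float = 30.0
    mode: str = "strict"
    duplicate_threshold: float = 0.01
    r_per_base: float = 1e-7
    markers: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "config needs exactly one of 'simulation' or 'inputs'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write_tsv(frame: pd.DataFrame, path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chlamypop seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``output_dir``."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    seed = config.seed
    summary: dict[str, Any] = {"seed": seed}

    # ---- stage: inputs (simulate or load) -----------------------------
    if config.simulation is not None:
        sim_config = SimulationConfig(**{**config.simulation, "seed": seed})
        log.info("simulating panel (n=%d, theta=%g, rho=%g)",
                 sim_config.n_samples, sim_config.theta_per_base,
                 sim_config.rho_per_base)
        panel = simulate_panel(sim_config)
        paths = emit_files(panel, os.path.join(out, "simulated"))
        inputs = {"vcf": paths["vcf"], "gff3": paths["gff3"],
                  "fasta": paths["fasta"], "callable": paths["callable"],
                  "metadata": paths["metadata"]}
    else:
        inputs = dict(config.inputs)

    # ---- stage: filter ------------------------------------------------
    matrix = io_annotation.read_genotype_table(
        inputs["vcf"], quality_threshold=config.quality_threshold)
    log.info("filter: %d SNPs retained, %d indel records routed aside",
             matrix.n_sites, getattr(matrix, "n_indels", 0))
    summary["n_snps"] = matrix.n_sites
    summary["n_indels"] = int(getattr(matrix, "n_indels", 0))

    # ---- stage: annotate ----------------------------------------------
    reference = io_annotation.read_fasta(inputs["fasta"])
    annotation = io_annotation.classify_sites(inputs["gff3"], inputs["fasta"])
    mask = io_annotation.read_callable_mask(
        inputs["callable"], {c: len(s) for c, s in reference.items()})
    summary["n_callable"] = mask.n_callable()
    log.info("annotate: %d callable sites", summary["n_callable"])

    metadata = pd.read_csv(inputs["metadata"], sep="\t")
    groups = dict(zip(metadata["strain"], metadata["group"].astype(str)))
    latitude = dict(zip(metadata["strain"], metadata["latitude"]))

    # ---- stage: near-duplicate exclusion ------------------------------
    dmat = structure.distance_matrix(matrix)
    dup_pairs, excluded = structure.flag_near_duplicates(
        dmat, threshold=config.duplicate_threshold)
    if excluded:
        log.info("excluding near-duplicate strains: %s", ", ".join(excluded))
        matrix = matrix.take_strains(
            [s for s in matrix.strain_ids if s not in excluded])
        dmat = structure.distance_matrix(matrix)
    summary["excluded_strains"] = excluded

    # ---- stage: diversity ---------------------------------------------
    class_table = diversity.class_diversity(matrix, annotation, mask,
                                            mode=config.mode)
    _write_tsv(class_table, os.path.join(out, "class_diversity.tsv"), seed)
    overall = class_table[class_table["site_class"] == "all"].iloc[0]
    summary["theta_w"] = float(overall["theta_w"])
    summary["theta_pi"] = float(overall["theta_pi"])

    windows = diversity.windowed_diversity(
        matrix, mask, window_size=config.window_size, mode=config.mode)
    windows_genic = diversity.windowed_diversity(
        matrix, mask, window_size=config.window_size,
        exclude_intergenic=True, annotation=annotation, mode=config.mode)
    _write_tsv(windows, os.path.join(out, "windows.tsv"), seed)
    _write_tsv(windows_genic, os.path.join(out, "windows_genic.tsv"), seed)

    qc = io_annotation.window_qc(reference, annotation, mask,
                                 config.window_size)
    _write_tsv(qc, os.path.join(out, "window_qc.tsv"), seed)

    # contrast the most intergenic-rich chromosome against the rest
    mean_ig = qc.groupby("chromosome")["fraction_intergenic"].mean()
    focal = str(mean_ig.idxmax())
    summary["contrast_chromosome"] = focal
    try:
        summary["contrast"] = diversity.chromosome_contrast(windows, focal)
    except ValueError as exc:
        log.warning("chromosome contrast skipped: %s", exc)
        summary["contrast"] = None
    merged = windows.merge(qc, on=["chromosome", "start", "end"])
    ok = merged["theta_w"].notna()
    ig_corr = diversity.spearman_correlation(
        merged.loc[ok, "fraction_intergenic"], merged.loc[ok, "theta_w"])
    summary["intergenic_vs_theta_w"] = ig_corr

    # ---- stage: sfs -----------------------------------------------------
    variant_classes = io_annotation.classify_variants(matrix, annotation,
                                                      reference)
    spectra = sfs.folded_sfs_by_class(matrix, annotation, variant_classes)
    rows = []
    for label, spec in spectra.items():
        if spec.S == 0:
            continue
        expected = sfs.neutral_folded_expectation(spec.n, spec.S)
        for i, (o, e) in enumerate(zip(spec.counts, expected), start=1):
            rows.append({"class": label, "minor_count": i,
                         "observed": int(o), "expected": e,
                         "observed_prop": o / spec.S,
                         "expected_prop": e / spec.S})
    _write_tsv(pd.DataFrame(rows), os.path.join(out, "sfs.tsv"), seed)
    skew = sfs.spectrum_skew(spectra["all"])
    summary["sfs_skew"] = {k: v for k, v in skew.items() if k != "residuals"}

    # ---- stage: structure ----------------------------------------------
    _write_tsv(dmat.to_frame().reset_index(names="strain"),
               os.path.join(out, "distances.tsv"), seed)
    tree = structure.neighbor_joining(dmat)
    io_annotation.write_newick(tree, os.path.join(out, "tree.nwk"))
    scores, explained = structure.pca(matrix)
    _write_tsv(scores.reset_index(names="strain"),
               os.path.join(out, "pca_scores.tsv"), seed)
    kept_groups = {s: groups[s] for s in matrix.strain_ids}
    summary["groups_are_clades"] = structure.groups_are_clades(tree,
                                                               kept_groups)
    fixed = structure.fixed_difference_fraction(matrix, kept_groups)
    summary["fixed_differences"] = {
        "n_fixed": fixed.n_fixed, "n_total": fixed.n_total,
        "fraction": fixed.fraction}
    lat = np.array([latitude[s] for s in matrix.strain_ids], dtype=float)
    summary["latitude_vs_pc"] = {
        col: diversity.spearman_correlation(scores[col].to_numpy(), lat)
        for col in scores.columns}

    # ---- stage: LD and recombination ------------------------------------
    decay = ld.ld_decay(matrix, bin_width=config.ld_bin_width,
                        max_distance=config.max_distance, scope="genome")
    decay_chrom = ld.ld_decay(matrix, bin_width=config.ld_bin_width,
                              max_distance=config.max_distance,
                              scope="chromosome")
    _write_tsv(pd.concat([decay, decay_chrom], ignore_index=True),
               os.path.join(out, "ld_decay.tsv"), seed)
    populated = decay[decay["n_pairs"] > 0]
    if len(populated):
        summary["r2_first_bin"] = float(populated["mean_r2"].iloc[0])

    four = ld.four_gamete_pairs(matrix)
    _write_tsv(pd.DataFrame(
        [{"chromosome": c, "violating_pairs": v}
         for c, v in four["per_chromosome"].items()]),
        os.path.join(out, "four_gamete.tsv"), seed)
    summary["four_gamete_pairs"] = four["total"]

    rho, estimates = ld.genome_rho(matrix, bin_width=config.rho_bin_width,
                                   max_distance=config.max_distance)
    _write_tsv(pd.DataFrame(
        [{"chromosome": e.chromosome, "rho_per_base": e.rho_per_base,
          "rho_per_mb": e.rho_per_mb, "n_bins": e.n_bins} for e in estimates]),
        os.path.join(out, "rho.tsv"), seed)
    outcrossing = ld.outcrossing_generations(rho, config.r_per_base)
    summary["rho_per_base"] = rho
    summary["rho_per_mb"] = rho * 1e6
    summary["outcrossing_generations"] = outcrossing.generations

    # ---- stage: Marey map (optional) ------------------------------------
    if config.markers:
        markers = pd.read_csv(config.markers, sep="\t")
        fits = []
        for chrom, sub in markers.groupby("chromosome"):
            try:
                fit = ld.marey_fit(sub[["bp", "cM"]], chromosome=str(chrom))
            except ValueError as exc:
                log.warning("marey %s: %s", chrom, exc)
                continue
            fits.append({"chromosome": fit.chromosome, "lower": fit.lower,
                         "upper": fit.upper, "midpoint": fit.midpoint,
                         "slope": fit.slope, "rss": fit.rss})
        _write_tsv(pd.DataFrame(fits), os.path.join(out, "marey.tsv"), seed)
        summary["marey_chromosomes"] = len(fits)

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    _write_text_summary(summary, os.path.join(out, "summary.txt"))
    return summary


def _write_text_summary(summary: dict, path: str) -> None:
    lines = [
        "chlamypop pipeline summary",
        f"seed: {summary['seed']}",
        f"SNPs retained: {summary['n_snps']} "
        f"(+{summary['n_indels']} indel records set aside)",
        f"callable sites: {summary['n_callable']}",
        f"theta_W: {summary['theta_w']:.6g} /base   "
        f"theta_pi: {summary['theta_pi']:.6g} /base",
        f"singleton excess vs neutral folded SFS: "
        f"{summary['sfs_skew']['singleton_excess']:.4f}",
        f"two groups form NJ clades: {summary['groups_are_clades']}",
        f"fixed-difference fraction: "
        f"{summary['fixed_differences']['fraction']:.4f}",
        f"four-gamete violating pairs: {summary['four_gamete_pairs']}",
        f"rho: {summary['rho_per_base']:.3g} /base "
        f"({summary['rho_per_mb']:.1f} /Mb)",
        f"outcrossing generations: "
        f"{summary['outcrossing_generations']:.0f}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
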