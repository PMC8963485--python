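"""End-to-end orchestration: ingest -> variant stats -> hybrid diagnosis
-> introgression -> structure, as one configured, seeded, logged run.

Every number in the emitted reports is reproducible by calling the
corresponding module operation in isolation; identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hybrid_diagnosis import DiagnosticPanel, diagnose_samples, diagnostic_a_dosages, assign_nuclear_type
from .introgression import FourTaxonAlignment, dstat_test
from .io_formats import (ReferenceConfig, metadata_frame, read_fasta,
                         read_metadata, read_vcf, write_json)
from .structure import (geographic_distance_matrix, ld_prune, mantel_test,
                        nei_distance_matrix, pca_genotypes)
from .variant_stats import call_heterozygous_positions, heterozygosity_percent, summarize_samples

log = logging.getLogger("hybridtrace")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    vcf: str
    cp_fasta: str
    metadata: str
    panel_genes: str
    panel_sites: str
    diagnostic_sites: str
    reference_json: str = ""
    outdir: str = "hybridtrace_out"
    four_taxon_fasta: str = ""
    seed: int = 0
    # analysis toggles
    run_varstats: bool = True
    run_diagnosis: bool = True
    run_dstat: bool = True
    run_structure: bool = True
    # thresholds (defaults are the study's stated parameters where printed)
    min_het_allele_freq: float = 0.25
    early_factor: float = 1.5
    het_site_fraction: float = 0.5
    min_diag_sites: int = 20
    prune_window_bp: int = 50_000
    prune_step: int = 10
    prune_r2: float = 0.2
    n_perm: int = 999
    n_blocks: int = 4
    pca_components: int = 2
    dstat_alpha: float = 0.05
    genome_size_A_bp: int = 384_800_000
    genome_size_B_bp: int = 354_900_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_het_allele_freq <= 0.5:
            raise ValueError("min_het_allele_freq must be in [0, 0.5]")
        if self.early_factor <= 0 or self.het_site_fraction <= 0:
            raise ValueError("factors must be positive")
        if self.n_perm < 1 or self.n_blocks < 1 or self.prune_step < 1:
            raise ValueError("counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @classmethod
    def for_fixture_dir(cls, fixture_dir: str | Path, outdir: str | Path,
                        seed: int = 0, **overrides) -> "RunConfig":
        d = Path(fixture_dir)
        ref_json = d / "reference.json"
        cfg = cls(
            vcf=str(d / "genotypes.vcf"),
            cp_fasta=str(d / "chloroplasts.fasta"),
            metadata=str(d / "metadata.tsv"),
            panel_genes=str(d / "panel_genes.tsv"),
            panel_sites=str(d / "panel_sites.tsv"),
            diagnostic_sites=str(d / "diagnostic_sites.tsv"),
            reference_json=str(ref_json) if ref_json.exists() else "",
            four_taxon_fasta=str(d / "four_taxon_alignment.fasta"),
            outdir=str(outdir),
            seed=seed,
            **overrides,
        )
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the input."""


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the configured stages; write reports and a run manifest.

    Returns the in-memory report bundle (dataframes and result objects).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}

    if config.reference_json:
        raw = json.loads(Path(config.reference_json).read_text())
        config.genome_size_A_bp = int(raw.get("genome_size_A_bp", config.genome_size_A_bp))
        config.genome_size_B_bp = int(raw.get("genome_size_B_bp", config.genome_size_B_bp))
        config.min_het_allele_freq = float(
            raw.get("min_het_allele_freq", config.min_het_allele_freq))

    # --- ingest -----------------------------------------------------------
    try:
        variant_table, gm = read_vcf(config.vcf)
        cp_seqs = read_fasta(config.cp_fasta)
        meta = read_metadata(config.metadata)
        panel = DiagnosticPanel.from_tsv(config.panel_genes, config.panel_sites)
        diag_sites = pd.read_csv(config.diagnostic_sites, sep="\t",
                                 dtype={"chrom": str})
    except Exception as exc:
        raise StageError(f"ingest failed: {exc}") from exc
    meta_df = metadata_frame(meta)
    log.info("ingest: %d samples, %d variant rows, %d SNV sites",
             gm.n_samples, len(variant_table), gm.n_sites)
    bundle["genotypes"] = gm
    bundle["variant_table"] = variant_table

    refconf = ReferenceConfig(
        genome_size_A_bp=config.genome_size_A_bp,
        genome_size_B_bp=config.genome_size_B_bp,
        cp_ref_A=cp_seqs.get("cpA", ""),
        cp_ref_B=cp_seqs.get("cpB", ""),
        min_het_allele_freq=config.min_het_allele_freq,
    )

    # nuclear typing first: the genome size entering the heterozygosity
    # formula follows each sample's assigned nuclear type
    nuclear_types = {}
    for s in gm.samples:
        ntype, _ = assign_nuclear_type(
            diagnostic_a_dosages(gm, s, diag_sites),
            min_sites=config.min_diag_sites)
        nuclear_types[s] = ntype
    genome_sizes = {s: refconf.genome_size_for(nuclear_types[s]) for s in gm.samples}

    # --- variant stats ----------------------------------------------------
    if config.run_varstats:
        try:
            summary = summarize_samples(variant_table, genome_sizes,
                                        config.min_het_allele_freq)
        except Exception as exc:
            raise StageError(f"varstats failed on {config.vcf}: {exc}") from exc
        summary.to_csv(outdir / "sample_summary.tsv", sep="\t")
        bundle["sample_summary"] = summary
        log.info("varstats: %d samples summarised", len(summary))

    # --- hybrid diagnosis -------------------------------------------------
    het_sets = call_heterozygous_positions(variant_table, config.min_het_allele_freq)
    het_pcts = {s: heterozygosity_percent(len(het_sets.get(s, ())), genome_sizes[s])
                for s in gm.samples}
    if config.run_diagnosis:
        parental = [s for s in gm.samples
                    if s in meta_df.index
                    and meta_df.loc[s, "taxon_label"] in ("parental_A", "parental_B")]
        try:
            report = diagnose_samples(
                gm, {s: cp_seqs[s] for s in gm.samples if s in cp_seqs},
                refconf.cp_ref_A, refconf.cp_ref_B, panel, diag_sites,
                het_pcts, parental,
                het_site_fraction=config.het_site_fraction,
                early_factor=config.early_factor,
                min_diag_sites=config.min_diag_sites,
            )
        except Exception as exc:
            raise StageError(f"diagnosis failed: {exc}") from exc
        report.to_csv(outdir / "hybrid_report.tsv", sep="\t")
        bundle["hybrid_report"] = report
        log.info("diagnosis: %d discordant samples",
                 int((report["cytonuclear_status"] == "discordant").sum()))

    # --- introgression ----------------------------------------------------
    if config.run_dstat and config.four_taxon_fasta:
        try:
            seqs = read_fasta(config.four_taxon_fasta)
            aln = FourTaxonAlignment.from_fasta(seqs)
            res = dstat_test(aln, n_blocks=config.n_blocks, alpha=config.dstat_alpha)
        except Exception as exc:
            raise StageError(
                f"dstat failed on {config.four_taxon_fasta}: {exc}") from exc
        rows = [
            (start, end, a, b)
            for (start, end), (a, b) in zip(res.block_boundaries, res.block_counts)
        ]
        dstat_df = pd.DataFrame(rows, columns=["block_start", "block_end",
                                               "n_ABBA", "n_BABA"])
        dstat_df["D"] = res.d
        dstat_df["Z"] = res.z
        dstat_df["p_value"] = res.p_value
        dstat_df["direction"] = res.direction
        dstat_df.to_csv(outdir / "dstat_report.tsv", sep="\t", index=False)
        bundle["dstat"] = res
        log.info("dstat: D=%.4f Z=%.2f direction=%s", res.d, res.z, res.direction)

    # --- structure --------------------------------------------------------
    if config.run_structure:
        try:
            dosage = gm.dosage()
            retained = ld_prune(dosage, gm.chrom, gm.pos,
                                window_bp=config.prune_window_bp,
                                step=config.prune_step, r2_max=config.prune_r2)
            pruned = dosage[:, retained]
            pca = pca_genotypes(pruned, k=config.pca_components)
            nei = nei_distance_matrix(dosage)
            lat = meta_df.loc[gm.samples, "latitude"].to_numpy(float)
            lon = meta_df.loc[gm.samples, "longitude"].to_numpy(float)
            geo = geographic_distance_matrix(lat, lon)
            mantel = mantel_test(nei, geo, n_perm=config.n_perm, seed=config.seed)
        except Exception as exc:
            raise StageError(f"structure failed: {exc}") from exc
        pd.DataFrame({"site_index": retained,
                      "chrom": gm.chrom[retained],
                      "pos": gm.pos[retained]}).to_csv(
            outdir / "retained_sites.tsv", sep="\t", index=False)
        pca_df = pd.DataFrame(
            pca.coordinates, index=gm.samples,
            columns=[f"PC{i+1}" for i in range(config.pca_components)])
        pca_df.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
        pd.DataFrame({"axis": [f"PC{i+1}" for i in range(config.pca_components)],
                      "percent_variance": np.round(pca.percent_variance, 4)}
                     ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        pd.DataFrame(nei, index=gm.samples, columns=gm.samples).to_csv(
            outdir / "nei_distances.tsv", sep="\t")
        pd.DataFrame(geo, index=gm.samples, columns=gm.samples).to_csv(
            outdir / "geographic_distances.tsv", sep="\t")
        write_json(outdir / "mantel.json", {
            "r_observed": mantel.r_observed, "p_value": mantel.p_value,
            "n_permutations": mantel.n_permutations, "seed": mantel.seed,
            "n_pairs": mantel.n_pairs,
        })
        iu = np.triu_indices(len(gm.samples), k=1)
        pd.DataFrame({"nei_distance": nei[iu], "geographic_km": geo[iu]}).to_csv(
            outdir / "ibd_scatter.tsv", sep="\t", index=False)
        bundle["pca"] = pca
        bundle["retained_sites"] = retained
        bundle["mantel"] = mantel
        log.info("structure: %d/%d sites retained, PC1 %.1f%%, Mantel p=%.3f",
                 len(retained), gm.n_sites, pca.percent_variance[0],
                 mantel.p_value)

    manifest = {"config": asdict(config), "version": __version__,
                "n_samples": gm.n_samples, "n_snv_sites": gm.n_sites,
                "nuclear_types": nuclear_types}
    write_json(outdir / "run_manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle
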