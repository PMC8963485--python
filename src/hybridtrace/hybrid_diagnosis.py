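"""Cytonuclear classification of putative hybrids.

Each sample gets (1) a chloroplast type by nearest-reference variant
counting against the two parental plastomes, (2) a nuclear type from the
fraction of taxon-A alleles at diagnostic (fixed-difference) sites,
(3) a cytonuclear status — discordance between the two is the signature
of chloroplast capture, (4) AB/AA/BB calls at the six diagnostic genes,
and (5) an early/later hybrid-generation class from genome-wide
heterozygosity relative to the parental maximum observed in the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, HET, HOM_ALT, HOM_REF

LOCUS_CALLS = ("AA", "AB", "BB", "inconclusive")


@dataclass(frozen=True)
class PanelGene:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")


@dataclass
class DiagnosticPanel:
    """Six-gene diagnostic panel with per-site parental alleles.

    ``sites`` has columns gene, chrom, pos, allele_A, allele_B; parental
    alleles must differ at every panel site and gene intervals must not
    overlap on a chromosome.
    """

    genes: list[PanelGene]
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[PanelGene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist = sorted(glist, key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                if b.start <= a.end:
                    raise ValueError(f"panel intervals overlap: {a.name}/{b.name}")
        same = self.sites["allele_A"] == self.sites["allele_B"]
        if bool(same.any()):
            raise ValueError("parental alleles identical at some panel sites")

    def gene(self, name: str) -> PanelGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def sites_for(self, name: str) -> pd.DataFrame:
        return self.sites[self.sites["gene"] == name]

    @classmethod
    def from_tsv(cls, genes_path, sites_path) -> "DiagnosticPanel":
        gdf = pd.read_csv(genes_path, sep="\t", dtype={"chrom": str})
        genes = [PanelGene(r.name_, str(r.chrom), int(r.start), int(r.end))
                 for r in gdf.rename(columns={"name": "name_"}).itertuples()]
        sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
        return cls(genes, sites)

    def to_tsv(self, genes_path, sites_path) -> None:
        pd.DataFrame(
            [(g.name, g.chrom, g.start, g.end) for g in self.genes],
            columns=["name", "chrom", "start", "end"],
        ).to_csv(genes_path, sep="\t", index=False)
        self.sites.to_csv(sites_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chloroplast typing

def count_variant_events(seq_a: str, seq_b: str) -> int:
    """Variant events between two equal-length aligned sequences.

    Substitution columns count individually; a maximal run of columns in
    which exactly one sequence is gapped counts as a single indel event
    (variant-style counting).  Columns gapped in both are ignored.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    events = 0
    in_gap_run = False
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x == "-" and y == "-":
            continue
        if (x == "-") != (y == "-"):
            if not in_gap_run:
                events += 1
                in_gap_run = True
            continue
        in_gap_run = False
        if x != y:
            events += 1
    return events


def assign_chloroplast_type(
    sample_cp_seq: str, cp_ref_A: str, cp_ref_B: str
) -> tuple[str, int, int]:
    """Nearest-reference plastome assignment.

    Returns ``(cp_type, variants_vs_A, variants_vs_B)``; an equidistant
    sample is reported as ``"unassigned"``.
    """
    count_a = count_variant_events(sample_cp_seq, cp_ref_A)
    count_b = count_variant_events(sample_cp_seq, cp_ref_B)
    if count_a == count_b:
        return ("unassigned", count_a, count_b)
    return ("A" if count_a < count_b else "B", count_a, count_b)


# ---------------------------------------------------------------------------
# nuclear typing

def assign_nuclear_type(
    a_allele_dosages: Sequence[int],
    min_sites: int = 20,
    a_threshold: float = 0.9,
    b_threshold: float = 0.1,
) -> tuple[str, float]:
    """Nuclear type from taxon-A allele dosage at diagnostic sites.

    ``a_allele_dosages`` holds, per called diagnostic site, the number of
    taxon-A alleles in the genotype (0, 1 or 2).  fraction_A >= 0.9 -> A,
    <= 0.1 -> B, otherwise admixed; too few called sites -> inconclusive.
    """
    dos = np.asarray(list(a_allele_dosages), dtype=float)
    if dos.size < min_sites:
        return ("inconclusive", math.nan)
    frac_a = float(dos.sum() / (2 * dos.size))
    if frac_a >= a_threshold:
        return ("A", frac_a)
    if frac_a <= b_threshold:
        return ("B", frac_a)
    return ("admixed", frac_a)


def diagnostic_a_dosages(
    gm: GenotypeMatrix, sample_id: str, diag_sites: pd.DataFrame
) -> list[int]:
    """Taxon-A allele dosages for one sample at the given diagnostic sites.

    ``diag_sites`` has columns chrom, pos, allele_A, allele_B.  Sites not
    in the matrix, with missing calls, or whose ref/alt do not match the
    two parental alleles are skipped.
    """
    lookup = gm.site_lookup()
    i = gm.sample_index(sample_id)
    dosages: list[int] = []
    for row in diag_sites.itertuples():
        j = lookup.get((str(row.chrom), int(row.pos)))
        if j is None:
            continue
        code = int(gm.codes[i, j])
        if code < 0:
            continue
        ref, alt = gm.ref[j], gm.alt[j]
        if ref == row.allele_A and alt == row.allele_B:
            dosages.append(2 - code)
        elif ref == row.allele_B and alt == row.allele_A:
            dosages.append(code)
    return dosages


# ---------------------------------------------------------------------------
# cytonuclear status

def classify_cytonuclear(cp_type: str, nuclear_type: str) -> tuple[str, str]:
    """Concordance of chloroplast and nuclear assignments.

    An admixed nuclear genome is reported discordant against the
    chloroplast donor (the maternal parent).  Returns
    ``(status, direction_note)``.
    """
    if cp_type not in ("A", "B") or nuclear_type not in ("A", "B", "admixed"):
        return ("inconclusive", "")
    if nuclear_type == "admixed":
        return ("discordant", f"maternal parent {cp_type}")
    if cp_type == nuclear_type:
        return ("concordant", "")
    return ("discordant", f"maternal parent {cp_type}")


# ---------------------------------------------------------------------------
# diagnostic-locus calls

def site_genotype_labels(
    gm: GenotypeMatrix, sample_id: str, gene_sites: pd.DataFrame
) -> list[str]:
    """Per-site labels (hom_A / het_AB / hom_B) for one sample at panel sites."""
    labels = []
    for d in diagnostic_a_dosages(gm, sample_id, gene_sites):
        labels.append({2: "hom_A", 1: "het_AB", 0: "hom_B"}[d])
    return labels


def call_diagnostic_locus(
    site_labels: Sequence[str],
    het_site_fraction: float = 0.5,
    min_sites: int = 1,
) -> str:
    """AB/AA/BB call for a gene from its per-site genotype labels.

    AB if at least ``het_site_fraction`` of called sites are A/B
    heterozygous; otherwise the majority homozygous class; ties or too
    few sites are inconclusive.
    """
    labels = [l for l in site_labels if l in ("hom_A", "het_AB", "hom_B")]
    n = len(labels)
    if n < min_sites:
        return "inconclusive"
    n_het = labels.count("het_AB")
    if n_het / n >= het_site_fraction:
        return "AB"
    n_a = labels.count("hom_A")
    n_b = labels.count("hom_B")
    if n_a == n_b:
        return "inconclusive"
    return "AA" if n_a > n_b else "BB"


# ---------------------------------------------------------------------------
# generation classification

def classify_generation(
    het_genome_pct: float,
    parental_reference_het_max: float,
    early_factor: float = 1.5,
) -> str:
    """Early (F1/F2) vs later-generation hybrid from genome heterozygosity.

    ``early`` iff het% >= early_factor * the maximum heterozygosity
    observed among labeled parental samples; boundary values are early.
    """
    if not parental_reference_het_max > 0:
        raise ValueError("parental_reference_het_max must be positive "
                         "(are there labeled parental samples?)")
    return "early" if het_genome_pct >= early_factor * parental_reference_het_max else "later"


# ---------------------------------------------------------------------------
# per-run report

def diagnose_samples(
    gm: GenotypeMatrix,
    cp_seqs: Mapping[str, str],
    cp_ref_A: str,
    cp_ref_B: str,
    panel: DiagnosticPanel,
    diag_sites: pd.DataFrame,
    het_pcts: Mapping[str, float],
    parental_samples: Sequence[str],
    het_site_fraction: float = 0.5,
    early_factor: float = 1.5,
    min_diag_sites: int = 20,
) -> pd.DataFrame:
    """Build the per-sample hybrid characterisation report.

    ``diag_sites`` is the full diagnostic-site table (panel plus
    genome-wide background fixed differences) used for nuclear typing;
    ``parental_samples`` anchors the generation threshold.
    """
    parental_max = max((het_pcts[s] for s in parental_samples), default=0.0)
    gene_names = [g.name for g in panel.genes]
    rows = []
    for sample in gm.samples:
        cp_type, c_a, c_b = (
            assign_chloroplast_type(cp_seqs[sample], cp_ref_A, cp_ref_B)
            if sample in cp_seqs else ("unassigned", -1, -1)
        )
        nuc_type, frac_a = assign_nuclear_type(
            diagnostic_a_dosages(gm, sample, diag_sites), min_sites=min_diag_sites
        )
        status, note = classify_cytonuclear(cp_type, nuc_type)
        calls = {
            g: call_diagnostic_locus(
                site_genotype_labels(gm, sample, panel.sites_for(g)),
                het_site_fraction=het_site_fraction,
            )
            for g in gene_names
        }
        evidence = status == "discordant" or any(c == "AB" for c in calls.values())
        if evidence:
            gen = classify_generation(het_pcts[sample], parental_max, early_factor)
        else:
            gen = "non_hybrid"
        rows.append(
            (sample, cp_type, c_a, c_b, nuc_type, round(frac_a, 4), status, note,
             *[calls[g] for g in gene_names], round(het_pcts[sample], 2), gen)
        )
    cols = (["sample_id", "cp_type", "cp_variants_vs_A", "cp_variants_vs_B",
             "nuclear_type", "fraction_A_alleles", "cytonuclear_status",
             "direction_note"] + [f"locus_{g}" for g in gene_names]
            + ["het_genome_pct", "generation_class"])
    return pd.DataFrame(rows, columns=cols).set_index("sample_id")
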