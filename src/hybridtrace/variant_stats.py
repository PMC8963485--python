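"""Per-sample variant classification and heterozygosity statistics.

Implements the two report-level formulas used throughout:

* SNV / InDel percentage = 100 * n_class / n_total_variants
* genome heterozygosity % = 100 * n_het_SNV_positions / genome_size_bp

together with the variant-class rules (SNV, MNV, insertion, deletion,
replacement), heterozygous-position calling with a minor-allele-frequency
floor, and per-sample *unique* heterozygous SNPs (het positions present
in no other sample).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

VARIANT_CLASSES = ("SNV", "MNV", "insertion", "deletion", "replacement")

_NUCS = frozenset("ACGT")


def classify_variant(ref_allele: str, alt_allele: str) -> str:
    """Classify a ref/alt allele pair.

    Rules: equal length 1 -> SNV; equal length > 1 -> MNV; ALT strictly
    extends REF (REF is a prefix or suffix of ALT) -> insertion; REF
    strictly extends ALT -> deletion; any other length-changing pair ->
    replacement.
    """
    if not ref_allele or not alt_allele:
        raise ValueError("empty allele string")
    if not (_NUCS.issuperset(ref_allele) and _NUCS.issuperset(alt_allele)):
        raise ValueError(f"non-nucleotide characters in {ref_allele!r}/{alt_allele!r}")
    lr, la = len(ref_allele), len(alt_allele)
    if lr == la:
        return "SNV" if lr == 1 else "MNV"
    if la > lr and (alt_allele.startswith(ref_allele) or alt_allele.endswith(ref_allele)):
        return "insertion"
    if lr > la and (ref_allele.startswith(alt_allele) or ref_allele.endswith(alt_allele)):
        return "deletion"
    return "replacement"


def snp_indel_percentages(class_counts: Mapping[str, int]) -> tuple[float, float]:
    """Percentage of SNVs and of InDels among all variants.

    Returns ``(nan, nan)`` for an empty count table (undefined).
    """
    total = sum(class_counts.get(c, 0) for c in VARIANT_CLASSES)
    if total <= 0:
        return (math.nan, math.nan)
    snv_pct = 100.0 * class_counts.get("SNV", 0) / total
    indel_pct = 100.0 * (class_counts.get("insertion", 0)
                         + class_counts.get("deletion", 0)) / total
    return snv_pct, indel_pct


def heterozygosity_percent(n_het_positions: int, genome_size_bp: int) -> float:
    """Genome-wide heterozygosity: 100 * het SNV positions / genome size.

    Reported tables round this to 2 decimals; full precision is returned.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    if n_het_positions < 0:
        raise ValueError("n_het_positions must be non-negative")
    return 100.0 * n_het_positions / genome_size_bp


def call_heterozygous_positions(
    variant_table: pd.DataFrame,
    min_het_allele_freq: float = 0.25,
) -> dict[str, set[tuple[str, int]]]:
    """Per-sample sets of heterozygous SNV positions (chrom, pos).

    A position is heterozygous for a sample iff its called genotype has
    two distinct alleles and, when an allele frequency is available, the
    minor allele frequency is at least ``min_het_allele_freq`` (default
    0.25, the variant caller's 25% minimum-frequency setting).
    """
    out: dict[str, set[tuple[str, int]]] = {
        s: set() for s in variant_table["sample_id"].unique()
    }
    snv = variant_table[
        (variant_table["variant_class"] == "SNV") & variant_table["called"]
    ]
    het = snv[snv["allele1"] != snv["allele2"]]
    af = het["allele_frequency"].to_numpy(dtype=float)
    minor = np.minimum(af, 1.0 - af)
    keep = np.isnan(af) | (minor >= min_het_allele_freq)
    for sample, chrom, pos in zip(
        het["sample_id"].to_numpy()[keep],
        het["chrom"].to_numpy()[keep],
        het["pos"].to_numpy()[keep],
    ):
        out[sample].add((str(chrom), int(pos)))
    return out


def unique_heterozygous_snps(
    het_sets: Mapping[str, set[tuple[str, int]]],
) -> dict[str, tuple[int, float]]:
    """Per-sample count and percentage of heterozygous SNPs private to it.

    A sample's unique het SNPs are its het positions present in no other
    sample's het set; the percentage is relative to the sample's own het
    total (NaN when the sample has no het positions).
    """
    if len(het_sets) < 2:
        raise ValueError("uniqueness is undefined for fewer than 2 samples")
    counts: dict[tuple[str, int], int] = {}
    for s in het_sets.values():
        for p in s:
            counts[p] = counts.get(p, 0) + 1
    out: dict[str, tuple[int, float]] = {}
    for sample, s in het_sets.items():
        n_unique = sum(1 for p in s if counts[p] == 1)
        pct = 100.0 * n_unique / len(s) if s else math.nan
        out[sample] = (n_unique, pct)
    return out


def per_sample_class_counts(variant_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of each variant class per sample (variants the sample carries)."""
    carried = variant_table[variant_table["called"] & variant_table["has_alt"]]
    tab = (
        carried.groupby(["sample_id", "variant_class"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for c in VARIANT_CLASSES:
        if c not in tab.columns:
            tab[c] = 0
    return tab[list(VARIANT_CLASSES)]


def summarize_samples(
    variant_table: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    min_het_allele_freq: float = 0.25,
) -> pd.DataFrame:
    """Per-sample variant summary (total variants, SNV/InDel %, het stats).

    ``genome_sizes`` maps sample_id to the genome size (bp) of the
    sample's assigned nuclear type.
    """
    class_counts = per_sample_class_counts(variant_table)
    het_sets = call_heterozygous_positions(variant_table, min_het_allele_freq)
    uniques = (
        unique_heterozygous_snps(het_sets) if len(het_sets) >= 2
        else {s: (0, math.nan) for s in het_sets}
    )
    rows = []
    for sample in variant_table["sample_id"].unique():
        counts = (
            class_counts.loc[sample].to_dict() if sample in class_counts.index
            else {}
        )
        total = int(sum(counts.values()))
        snv_pct, indel_pct = snp_indel_percentages(counts) if total else (math.nan, math.nan)
        n_het = len(het_sets.get(sample, ()))
        het_pct = heterozygosity_percent(n_het, genome_sizes[sample])
        n_uni, uni_pct = uniques[sample]
        rows.append((sample, total, snv_pct, indel_pct, n_het,
                     round(het_pct, 2), n_uni, uni_pct))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "total_variants", "snv_pct", "indel_pct",
                 "n_het_positions", "het_genome_pct", "n_unique_het",
                 "unique_het_pct"],
    ).set_index("sample_id")
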