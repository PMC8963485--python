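"""Published reference values for the Australian wild-rice system.

These are the reported characterisation numbers for the resequenced
Australian *Oryza* accessions (raw reads deposited as BioProject
PRJNA758754): genome sizes of the two parental taxa, the diagnostic-gene
genotype calls of the five natural hybrids, genome-wide heterozygous-SNP
counts, and the four-taxon alignment geometry.  They serve as worked
inputs for the report-level formulas and as frozen expectations in tests;
nothing here is computed by this package.
"""

from __future__ import annotations

#: nuclear genome sizes (bp): A = O. rufipogon-like taxon, B = O. meridionalis
GENOME_SIZE_BP = {"A": 384_800_000, "B": 354_900_000}

#: diagnostic genes, in reporting order
DIAGNOSTIC_GENES = ("sh4", "GBSSI", "SSI", "SBEI", "ALK", "GBSSII")

#: published genomic intervals (1-based inclusive) where printed
PUBLISHED_GENE_INTERVALS = {
    "sh4": ("4", 34_231_186, 34_233_221),
    "ALK": ("6", 6_748_398, 6_753_302),
    "GBSSII": ("7", 12_916_883, 12_924_202),
}

#: per-hybrid AB/BB locus calls at the six diagnostic genes
HYBRID_LOCUS_CALLS = {
    "WR44": {"sh4": "AB", "GBSSI": "BB", "SSI": "BB", "SBEI": "AB", "ALK": "BB", "GBSSII": "AB"},
    "WR52": {"sh4": "BB", "GBSSI": "BB", "SSI": "BB", "SBEI": "AB", "ALK": "BB", "GBSSII": "AB"},
    "WR62": {"sh4": "AB", "GBSSI": "AB", "SSI": "AB", "SBEI": "AB", "ALK": "AB", "GBSSII": "AB"},
    "WR153": {"sh4": "BB", "GBSSI": "BB", "SSI": "BB", "SBEI": "AB", "ALK": "AB", "GBSSII": "AB"},
    "WR161": {"sh4": "AB", "GBSSI": "BB", "SSI": "AB", "SBEI": "AB", "ALK": "BB", "GBSSII": "AB"},
}

#: heterozygous-SNP counts and assigned nuclear type for the five hybrids
HYBRID_HET_SNPS = {
    "WR44": (2_464_823, "B"),
    "WR52": (1_137_527, "B"),
    "WR62": (2_318_878, "A"),
    "WR153": (1_111_890, "B"),
    "WR161": (1_189_627, "B"),
}

#: reported generation class of each hybrid (early = F1/F2)
HYBRID_GENERATIONS = {
    "WR44": "early", "WR52": "later", "WR62": "early",
    "WR153": "later", "WR161": "later",
}

#: chloroplast / nuclear genome types of the five hybrids (bidirectional capture)
HYBRID_CYTONUCLEAR = {
    "WR44": ("A", "B"),   # (cp_type, nuclear_type)
    "WR52": ("A", "B"),
    "WR62": ("B", "A"),
    "WR153": ("A", "B"),
    "WR161": ("A", "B"),
}

#: het-SNP counts for the two reference parental accessions
PARENTAL_HET_SNPS = {
    "WR24": (632_272, "A"),    # O. rufipogon-like, 0.16% of genome
    "WR81": (1_365_802, "B"),  # O. meridionalis, 0.38% of genome
}

#: maximum reported parental genome heterozygosity (%), O. meridionalis WR81
PARENTAL_HET_PCT_MAX = 0.38

#: concatenated four-gene alignment used for the four-taxon tests
FOUR_TAXON_ALIGNMENT_LENGTH = 4_473
FOUR_TAXON_N_BLOCKS = 4

#: ABBA/BABA counts in the first jackknife block, per hybrid (P3)
FOUR_TAXON_BLOCK1_COUNTS = {
    "WR44": (168, 10),
    "WR52": (133, 6),
    "WR62": (66, 18),
    "WR153": (73, 18),
    "WR161": (55, 0),
}

#: divergence between the two reference plastomes (variant events)
CP_REFERENCE_DIVERGENCE = 36
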