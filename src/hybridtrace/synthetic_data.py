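"""Synthetic two-taxon + hybrid data with the structure the analyses assume.

The generator emulates the sampled wild-rice system: two parental taxa
with fixed diagnostic allele differences and distinct background
heterozygosity (taxon A ~0.16% of genome, taxon B ~0.30%), F1/F2 and
repeatedly backcrossed hybrids with maternally inherited chloroplasts,
and four-taxon alignments with a tunable introgression fraction.  Sites
are unlinked (site-wise statistics only) and four-taxon columns carry a
single-origin derived allele, which makes ABBA/BABA polarization exact
and the D = 0 null analytic.

The default scenario (``two_taxa_plus_hybrids``) is a scaled-down genome:
200 kb over chromosomes 4/6/7, 1,400 fixed interspecific SNV differences
(0.7% of the genome, placing F1/F2 heterozygosity in the observed
early-hybrid range), 280 fixed non-SNV differences, 4,000 background
polymorphic sites, and 26 samples — 1 parental A, 20 parental B and five
hybrids (F1, F2, BC3, BC4, BC4) with both chloroplast donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets
from .hybrid_diagnosis import DiagnosticPanel, PanelGene
from .introgression import FourTaxonAlignment
from .io_formats import (GenotypeMatrix, SampleMetadata, write_fasta,
                         write_json, write_metadata, write_vcf)
from .variant_stats import classify_variant

_NUC = np.array(list("ACGT"))

# --- default scenario conditions -------------------------------------------

CHROM_LENGTHS = {"4": 60_000, "6": 80_000, "7": 60_000}
GENE_INTERVALS = {
    "sh4": ("4", 20_001, 24_000),
    "GBSSI": ("6", 10_001, 14_000),
    "SSI": ("6", 30_001, 34_000),
    "SBEI": ("6", 46_001, 50_000),
    "ALK": ("6", 62_001, 66_000),
    "GBSSII": ("7", 30_001, 34_000),
}
N_PANEL_SITES_PER_GENE = 25
N_SCATTERED_DIAG = {"4": 375, "6": 500, "7": 375}
N_SV = {"4": 84, "6": 112, "7": 84}
N_BG = {"4": 1_200, "6": 1_600, "7": 1_200}
BG_HET_RATE_A = 0.08   # 4,000 sites -> E[het] = 320 = 0.16% of 200 kb
BG_HET_RATE_B = 0.15   # -> 600 = 0.30% of 200 kb
# drift concentrations giving E[2p(1-p)] = (1/3) c/(c+1) = the rates above
BG_DRIFT_C_A = 0.24 / (1 - 0.24)
BG_DRIFT_C_B = 0.45 / (1 - 0.45)
CP_LENGTH = 2_000
CP_PRIVATE_MUTATIONS = 2

#: 26-sample plan mirroring the study composition
N_PARENTAL_A = 1
N_PARENTAL_B = 20


def child_seed(seed: int, k: int) -> int:
    """Deterministic sub-seed below 2^31."""
    return (seed * 1_000_003 + 7_919 * (k + 1)) % (2**31 - 1)


@dataclass
class TaxonModel:
    """Genotype-generating model for one parental taxon."""

    name: str                          # "A" or "B"
    n_sites: int
    diagnostic_site_indices: np.ndarray   # fixed-difference SNVs
    fixed_site_indices: np.ndarray        # diagnostic SNVs + non-SNV fixed diffs
    background_site_indices: np.ndarray
    allele_A_per_site: np.ndarray         # at diagnostic sites
    allele_B_per_site: np.ndarray
    fixed_code: int                    # 0 (= ref, taxon A) or 2 (taxon B)
    background_het_rate: float         # mean expected per-site het probability
    cp_haplotype: str                  # "cpA" / "cpB"
    cp_sequence: str
    #: optional per-background-site alternate-allele frequencies within the
    #: taxon; when given, genotypes are Binomial(2, p) draws (drifted shared
    #: polymorphism), otherwise sites are het with background_het_rate
    background_allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_het_rate <= 1.0:
            raise ValueError("background_het_rate must be in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("empty model")
        if np.any(self.allele_A_per_site == self.allele_B_per_site):
            raise ValueError("diagnostic alleles must differ between taxa")


@dataclass
class CrossSpec:
    """A hybrid pedigree: F1, F2 (= F1 selfed once) or BC_n to a recurrent parent."""

    kind: str                  # "F1" | "F2" | "BC"
    n_backcrosses: int = 0
    recurrent_parent: str = "B"
    maternal_parent: str = "A"   # chloroplast donor of the founding cross
    selfing_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("F1", "F2", "BC"):
            raise ValueError(f"unknown cross kind {self.kind!r}")
        if self.kind == "BC" and self.n_backcrosses < 1:
            raise ValueError("BC crosses require n_backcrosses >= 1")
        if self.kind != "BC" and self.n_backcrosses:
            raise ValueError("n_backcrosses only applies to BC crosses")
        if self.recurrent_parent not in ("A", "B") or self.maternal_parent not in ("A", "B"):
            raise ValueError("parents must be 'A' or 'B'")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")

    @property
    def label(self) -> str:
        if self.kind == "BC":
            return f"BC{self.n_backcrosses}"
        return self.kind


@dataclass
class Scenario:
    """A fully specified simulated study: site map, taxon models, panel."""

    seed: int
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    category: np.ndarray          # "diag" | "sv" | "bg"
    variant_class: np.ndarray
    panel: DiagnosticPanel
    diag_sites: pd.DataFrame      # chrom, pos, allele_A, allele_B (all diagnostic SNVs)
    model_A: TaxonModel
    model_B: TaxonModel
    cp_refs: dict[str, str]       # {"cpA": seq, "cpB": seq}
    genome_size_bp: int

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def snv_mask(self) -> np.ndarray:
        return self.category != "sv"

    def model(self, taxon: str) -> TaxonModel:
        return self.model_A if taxon == "A" else self.model_B

    def genotype_matrix(self, sample_ids: Sequence[str],
                        codes: np.ndarray) -> GenotypeMatrix:
        """Biallelic-SNV GenotypeMatrix view of simulated genotype codes."""
        m = self.snv_mask
        return GenotypeMatrix(list(sample_ids), self.chrom[m], self.pos[m],
                              self.ref[m], self.alt[m],
                              np.atleast_2d(codes)[:, m])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NUC[rng.integers(0, 4, length)])


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    sites = rng.choice(len(arr), size=n_mut, replace=False)
    for s in sites:
        choices = [b for b in "ACGT" if b != arr[s]]
        arr[s] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _nonsnv_alleles(rng: np.random.Generator, vclass: str) -> tuple[str, str]:
    base = _random_seq(rng, 1)
    if vclass == "insertion":
        return base, base + _random_seq(rng, int(rng.integers(1, 4)))
    if vclass == "deletion":
        return base + _random_seq(rng, int(rng.integers(1, 4))), base
    if vclass == "MNV":
        ref = _random_seq(rng, 2)
        alt = "".join(
            [b for b in "ACGT" if b != c][rng.integers(0, 3)] for c in ref
        )
        return ref, alt
    # replacement: length-changing, non-nested
    ref = "AT" if rng.random() < 0.5 else "CG"
    alt = ("GCA" if ref == "AT" else "TAG")
    return ref, alt


def default_scenario(seed: int = 0) -> Scenario:
    """Build the ``two_taxa_plus_hybrids`` scenario deterministically."""
    rng = np.random.default_rng(child_seed(seed, 0))
    chroms, poss, cats = [], [], []

    panel_rows = []
    gene_positions: dict[str, np.ndarray] = {}
    for gene, (chrom, start, end) in GENE_INTERVALS.items():
        p = np.sort(rng.choice(np.arange(start, end + 1), N_PANEL_SITES_PER_GENE,
                               replace=False))
        gene_positions[gene] = p
        for x in p:
            chroms.append(chrom)
            poss.append(int(x))
            cats.append("diag")
            panel_rows.append(gene)

    for chrom, length in CHROM_LENGTHS.items():
        in_gene = np.zeros(length + 1, dtype=bool)
        for gene, (gc, start, end) in GENE_INTERVALS.items():
            if gc == chrom:
                in_gene[start:end + 1] = True
        allowed = np.flatnonzero(~in_gene[1:]) + 1
        n_total = N_SCATTERED_DIAG[chrom] + N_SV[chrom] + N_BG[chrom]
        chosen = rng.choice(allowed, size=n_total, replace=False)
        labels = (["diag"] * N_SCATTERED_DIAG[chrom] + ["sv"] * N_SV[chrom]
                  + ["bg"] * N_BG[chrom])
        for x, lab in zip(chosen, labels):
            chroms.append(chrom)
            poss.append(int(x))
            cats.append(lab)
            panel_rows.append("")

    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(poss, dtype=np.int64)
    cat_arr = np.array(cats, dtype=object)
    gene_arr = np.array(panel_rows, dtype=object)
    chrom_order = {c: i for i, c in enumerate(CHROM_LENGTHS)}
    order = np.lexsort((pos_arr, np.array([chrom_order[c] for c in chrom_arr])))
    chrom_arr, pos_arr, cat_arr, gene_arr = (
        chrom_arr[order], pos_arr[order], cat_arr[order], gene_arr[order]
    )

    n_sites = len(pos_arr)
    ref = np.empty(n_sites, dtype=object)
    alt = np.empty(n_sites, dtype=object)
    vclass = np.empty(n_sites, dtype=object)
    sv_classes = ["insertion"] * 160 + ["deletion"] * 90 + ["MNV"] * 20 + ["replacement"] * 10
    sv_iter = iter(sv_classes)
    for j in range(n_sites):
        if cat_arr[j] == "sv":
            c = next(sv_iter)
            ref[j], alt[j] = _nonsnv_alleles(rng, c)
            vclass[j] = classify_variant(ref[j], alt[j])
            assert vclass[j] == c
        else:
            r = _NUC[rng.integers(0, 4)]
            a = [b for b in "ACGT" if b != r][rng.integers(0, 3)]
            ref[j], alt[j] = r, a
            vclass[j] = "SNV"

    diag_idx = np.flatnonzero(cat_arr == "diag")
    sv_idx = np.flatnonzero(cat_arr == "sv")
    bg_idx = np.flatnonzero(cat_arr == "bg")
    fixed_idx = np.sort(np.concatenate([diag_idx, sv_idx]))

    # taxon A alleles = reference (the A taxon is closer to the mapping
    # reference), taxon B alleles = alternate
    allele_A = ref[diag_idx].astype(object)
    allele_B = alt[diag_idx].astype(object)

    cp_a = _random_seq(rng, CP_LENGTH)
    cp_b = _mutate(cp_a, datasets.CP_REFERENCE_DIVERGENCE, rng)

    # shared ancestral frequency per background site, drifted independently
    # in each taxon (keeps within-taxon polymorphism and between-taxon
    # frequency divergence, as in the real populations)
    q = np.clip(rng.random(len(bg_idx)), 0.01, 0.99)
    bg_freq_a = rng.beta(q * BG_DRIFT_C_A, (1 - q) * BG_DRIFT_C_A)
    bg_freq_b = rng.beta(q * BG_DRIFT_C_B, (1 - q) * BG_DRIFT_C_B)

    diag_sites = pd.DataFrame({
        "gene": gene_arr[diag_idx],
        "chrom": chrom_arr[diag_idx].astype(str),
        "pos": pos_arr[diag_idx],
        "allele_A": allele_A,
        "allele_B": allele_B,
    })
    panel_sites = diag_sites[diag_sites["gene"] != ""].reset_index(drop=True)
    genes = [PanelGene(g, c, s, e) for g, (c, s, e) in GENE_INTERVALS.items()]
    panel = DiagnosticPanel(genes, panel_sites)

    common = dict(
        n_sites=n_sites,
        diagnostic_site_indices=diag_idx,
        fixed_site_indices=fixed_idx,
        background_site_indices=bg_idx,
        allele_A_per_site=allele_A,
        allele_B_per_site=allele_B,
    )
    model_a = TaxonModel(name="A", fixed_code=0, background_het_rate=BG_HET_RATE_A,
                         cp_haplotype="cpA", cp_sequence=cp_a,
                         background_allele_freqs=bg_freq_a, **common)
    model_b = TaxonModel(name="B", fixed_code=2, background_het_rate=BG_HET_RATE_B,
                         cp_haplotype="cpB", cp_sequence=cp_b,
                         background_allele_freqs=bg_freq_b, **common)
    return Scenario(
        seed=seed, chrom=chrom_arr, pos=pos_arr, ref=ref, alt=alt,
        category=cat_arr, variant_class=vclass, panel=panel,
        diag_sites=diag_sites.drop(columns=["gene"]).assign(gene=gene_arr[diag_idx])[
            ["gene", "chrom", "pos", "allele_A", "allele_B"]],
        model_A=model_a, model_B=model_b,
        cp_refs={"cpA": cp_a, "cpB": cp_b},
        genome_size_bp=sum(CHROM_LENGTHS.values()),
    )


# ---------------------------------------------------------------------------
# simulators

def simulate_parental_individuals(
    model: TaxonModel, n: int, seed: int
) -> tuple[np.ndarray, list[str]]:
    """Simulate n parental individuals: genotype codes + chloroplast sequences.

    Each individual is homozygous for its taxon's fixed alleles;
    background sites are independently heterozygous with the taxon's
    background rate; the chloroplast is the taxon haplotype plus a small
    number of private substitutions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = np.zeros((n, model.n_sites), dtype=np.int8)
    codes[:, model.fixed_site_indices] = model.fixed_code
    bg = model.background_site_indices
    if model.background_allele_freqs is not None:
        codes[:, bg] = rng.binomial(2, model.background_allele_freqs,
                                    size=(n, len(bg))).astype(np.int8)
    else:
        het = rng.random((n, len(bg))) < model.background_het_rate
        for i in range(n):
            codes[i, bg[het[i]]] = 1
    cp_seqs = [_mutate(model.cp_sequence, CP_PRIVATE_MUTATIONS, rng) for _ in range(n)]
    return codes, cp_seqs


def expected_nonrecurrent_fraction(spec: CrossSpec) -> float:
    """Expected genome fraction from the non-recurrent parent."""
    w = 0.5
    if spec.kind == "BC":
        w *= 0.5 ** spec.n_backcrosses
    return w


def simulate_hybrid(
    model_a: TaxonModel, model_b: TaxonModel, spec: CrossSpec
) -> tuple[np.ndarray, str, str]:
    """Simulate one hybrid: genotype codes, chloroplast sequence, truth label.

    Fixed-difference sites start heterozygous in the F1 and then follow
    Mendelian transmission through unlinked backcross/selfing rounds:
    each backcross keeps a heterozygous site heterozygous with
    probability 1/2 (else homozygous for the recurrent parent); each
    selfing generation halves heterozygosity in expectation.  The
    chloroplast is the maternal parent's haplotype (the hybrid lineage
    is carried maternally through the pedigree).
    """
    if model_a.n_sites != model_b.n_sites:
        raise ValueError("taxon models disagree on the site map")
    rng = np.random.default_rng(spec.seed)
    n_fixed = len(model_a.fixed_site_indices)
    state = np.ones(n_fixed, dtype=np.int8)  # 0 = hom-A, 1 = het, 2 = hom-B

    recurrent_code = 0 if spec.recurrent_parent == "A" else 2
    n_self = spec.selfing_generations + (1 if spec.kind == "F2" else 0)
    if spec.kind == "BC":
        for _ in range(spec.n_backcrosses):
            u = rng.random(n_fixed)
            was_het = state == 1
            was_other = (state != 1) & (state != recurrent_code)
            state[was_het & (u < 0.5)] = recurrent_code
            state[was_other] = 1  # hom non-recurrent x hom recurrent -> het
    for _ in range(n_self):
        u = rng.random(n_fixed)
        was_het = state == 1
        state[was_het & (u < 0.25)] = 0
        state[was_het & (u >= 0.75)] = 2

    codes = np.zeros(model_a.n_sites, dtype=np.int8)
    codes[model_a.fixed_site_indices] = state

    w_a = expected_nonrecurrent_fraction(spec) if spec.recurrent_parent == "B" else \
        1.0 - expected_nonrecurrent_fraction(spec)
    bg = model_a.background_site_indices
    if (model_a.background_allele_freqs is not None
            and model_b.background_allele_freqs is not None):
        p_mix = (w_a * model_a.background_allele_freqs
                 + (1 - w_a) * model_b.background_allele_freqs)
        codes[bg] = rng.binomial(2, p_mix).astype(np.int8)
    else:
        bg_rate = (w_a * model_a.background_het_rate
                   + (1 - w_a) * model_b.background_het_rate)
        codes[bg[rng.random(len(bg)) < bg_rate]] = 1

    maternal = model_a if spec.maternal_parent == "A" else model_b
    cp_seq = _mutate(maternal.cp_sequence, CP_PRIVATE_MUTATIONS, rng)
    return codes, cp_seq, spec.label


def simulate_four_taxon_alignment(
    length: int,
    per_branch_substitution_prob: float = 0.05,
    f_introgression: float = 0.0,
    donor: str = "P2",
    seed: int = 0,
) -> FourTaxonAlignment:
    """Four-taxon alignment under topology (((P1, P2), P3), outgroup).

    Each column has an ancestral state (carried by the outgroup) and a
    single derived allele that arises independently with the given
    probability on each of the P1, P2, P3 and (P1,P2)-ancestor branches.
    A fraction ``f_introgression`` of columns have P3's state replaced by
    the donor lineage's state.  With f = 0 the construction is symmetric
    in (P1, P2), so E[D] = 0.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    p = per_branch_substitution_prob
    if not (0.0 <= p <= 1.0 and 0.0 <= f_introgression <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    if donor not in ("P1", "P2"):
        raise ValueError("donor must be 'P1' or 'P2'")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, length)
    der = (anc + rng.integers(1, 4, length)) % 4
    m1, m2, m3, m12 = (rng.random((4, length)) < p)
    d1 = m1 | m12
    d2 = m2 | m12
    d3 = m3 | m12
    intro = rng.random(length) < f_introgression
    donor_state = d2 if donor == "P2" else d1
    d3 = np.where(intro, donor_state, d3)

    def seq(derived_mask: np.ndarray) -> str:
        return "".join(_NUC[np.where(derived_mask, der, anc)])

    return FourTaxonAlignment(seq(d1), seq(d2), seq(d3), "".join(_NUC[anc]))


# ---------------------------------------------------------------------------
# fixture sets

HYBRID_PLAN: list[tuple[str, CrossSpec]] = [
    ("HYB01", CrossSpec(kind="F1", maternal_parent="A", recurrent_parent="B")),
    ("HYB02", CrossSpec(kind="F2", maternal_parent="B", recurrent_parent="B")),
    ("HYB03", CrossSpec(kind="BC", n_backcrosses=3, maternal_parent="A",
                        recurrent_parent="B")),
    ("HYB04", CrossSpec(kind="BC", n_backcrosses=4, maternal_parent="A",
                        recurrent_parent="B")),
    ("HYB05", CrossSpec(kind="BC", n_backcrosses=4, maternal_parent="A",
                        recurrent_parent="B")),
]


@dataclass
class FixtureSet:
    """In-memory view of one simulated study."""

    scenario: Scenario
    sample_ids: list[str]
    codes: np.ndarray             # samples x sites
    cp_seqs: dict[str, str]
    metadata: list[SampleMetadata]
    truth: pd.DataFrame


def simulate_fixture_set(seed: int = 0) -> FixtureSet:
    """Simulate the default 26-sample study (1 A + 20 B + 5 hybrids)."""
    scenario = default_scenario(seed)
    codes_a, cp_a = simulate_parental_individuals(
        scenario.model_A, N_PARENTAL_A, child_seed(seed, 1))
    codes_b, cp_b = simulate_parental_individuals(
        scenario.model_B, N_PARENTAL_B, child_seed(seed, 2))

    sample_ids = [f"WRA{i+1:02d}" for i in range(N_PARENTAL_A)]
    sample_ids += [f"WRB{i+1:02d}" for i in range(N_PARENTAL_B)]
    all_codes = [codes_a, codes_b]
    cp_seqs = dict(zip(sample_ids, cp_a + cp_b))
    truth_rows = [(s, "parental_A", "", "A", "cpA") for s in sample_ids[:N_PARENTAL_A]]
    truth_rows += [(s, "parental_B", "", "B", "cpB")
                   for s in sample_ids[N_PARENTAL_A:]]

    hybrid_codes = []
    for k, (name, spec) in enumerate(HYBRID_PLAN):
        spec = replace(spec, seed=child_seed(seed, 10 + k))
        codes, cp, label = simulate_hybrid(scenario.model_A, scenario.model_B, spec)
        sample_ids.append(name)
        hybrid_codes.append(codes)
        cp_seqs[name] = cp
        truth_rows.append((name, "hybrid", label, spec.maternal_parent,
                           "cpA" if spec.maternal_parent == "A" else "cpB"))
    all_codes.append(np.vstack(hybrid_codes))
    codes = np.vstack(all_codes)

    rng = np.random.default_rng(child_seed(seed, 3))
    metadata = []
    for i, s in enumerate(sample_ids):
        label = ("parental_A" if s.startswith("WRA")
                 else "parental_B" if s.startswith("WRB") else "putative_hybrid")
        metadata.append(SampleMetadata(
            sample_id=s,
            latitude=float(np.round(-16.5 + 5.0 * rng.random(), 5)),
            longitude=float(np.round(142.0 + 3.5 * rng.random(), 5)),
            collection_year=2015 if i < 22 else 2016,
            taxon_label=label,
        ))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "true_taxon", "cross_kind", "maternal_parent",
                 "cp_haplotype"],
    )
    return FixtureSet(scenario=scenario, sample_ids=sample_ids, codes=codes,
                      cp_seqs=cp_seqs, metadata=metadata, truth=truth)


def write_fixture_set(outdir: str | Path, scenario: str = "two_taxa_plus_hybrids",
                      seed: int = 0) -> FixtureSet:
    """Write a complete simulated study to disk (VCF/FASTA/TSV/JSON).

    Re-running with the same seed produces byte-identical files.
    """
    if scenario != "two_taxa_plus_hybrids":
        raise ValueError(f"unknown scenario {scenario!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = simulate_fixture_set(seed)
    sc = fx.scenario

    write_vcf(outdir / "genotypes.vcf", fx.sample_ids, sc.chrom, sc.pos,
              sc.ref, sc.alt, fx.codes, contig_lengths=CHROM_LENGTHS)
    cp = {"cpA": sc.cp_refs["cpA"], "cpB": sc.cp_refs["cpB"]}
    cp.update({s: fx.cp_seqs[s] for s in fx.sample_ids})
    write_fasta(outdir / "chloroplasts.fasta", cp)
    write_metadata(outdir / "metadata.tsv", fx.metadata)
    fx.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sc.panel.to_tsv(outdir / "panel_genes.tsv", outdir / "panel_sites.tsv")
    sc.diag_sites.to_csv(outdir / "diagnostic_sites.tsv", sep="\t", index=False)
    aln = simulate_four_taxon_alignment(
        length=datasets.FOUR_TAXON_ALIGNMENT_LENGTH,
        per_branch_substitution_prob=0.05,
        f_introgression=0.3, donor="P2", seed=child_seed(seed, 4))
    write_fasta(outdir / "four_taxon_alignment.fasta",
                {"P1": aln.p1, "P2": aln.p2, "P3": aln.p3, "outgroup": aln.outgroup})
    write_json(outdir / "reference.json", {
        "scenario": scenario,
        "seed": seed,
        "genome_size_A_bp": sc.genome_size_bp,
        "genome_size_B_bp": sc.genome_size_bp,
        "min_het_allele_freq": 0.25,
        "chrom_lengths": CHROM_LENGTHS,
    })
    return fx
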