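# Methods

## The analysis model

Two sympatric diploid taxa — an *O. rufipogon*-like taxon (A, genome
384.8 Mb) and *O. meridionalis* (B, 354.9 Mb) — exchange genes through
rare hybridisation.  Three signals identify a hybrid and its history:

1. **Cytonuclear discordance.**  Chloroplasts are maternally inherited,
   so a hybrid lineage keeps its founding mother's plastome no matter
   how often it backcrosses.  A sample whose nearest reference plastome
   disagrees with its nuclear assignment has captured a chloroplast.
   Plastome typing counts variant events against each reference
   (substitution columns individually, a run of gap columns as one
   event); ties are reported unassigned rather than guessed.
2. **Allele additivity at diagnostic loci.**  At genes where the taxa
   carry fixed, distinct alleles, an F1 is heterozygous (AB) at every
   site; backcrossing to a recurrent parent halves the probability a
   locus stays AB each generation.  A gene is called AB when at least
   half of its called panel sites are A/B heterozygous (the het-site
   fraction is configurable because real gene alignments are
   heterozygous at a handful of positions, not all), otherwise the
   majority homozygous class, with ties inconclusive.
3. **Genome-wide heterozygosity.**  `H% = 100·n_het/G` with the genome
   size of the sample's assigned nuclear type.  Hybrid generations are
   classed *early* (F1/F2) when `H% >= early_factor × max(parental H%)`
   with `early_factor = 1.5` by default: the published system shows
   early hybrids at 0.60–0.69% against a parental maximum of 0.38% and
   later hybrids at 0.31–0.34%, and 1.5 separates those ranges cleanly
   while being anchored to the parental samples observed in the run
   rather than to an absolute cutoff.  Boundary values are early.

Nuclear typing uses the fraction of taxon-A alleles over called
diagnostic sites (A ≥ 0.9, B ≤ 0.1, otherwise admixed; at least 20
called sites).  An admixed nuclear genome is reported discordant
against the chloroplast donor, which is exactly the F1/F2 situation.

## Introgression test

For an alignment ordered (((P1, P2), P3), outgroup), a column is
informative when it is gap/N-free, biallelic across the four sequences,
and the outgroup carries one of the two states (that state is read as
ancestral; columns where the outgroup carries a third allele are
skipped, the standard polarization convention).  D = (nABBA −
nBABA)/(nABBA + nBABA); significance uses an unweighted delete-one
block jackknife over contiguous blocks, dropping blocks without
informative sites (with a warning), and a two-sided normal p-value.
Degenerate cases are flagged, not raised: no informative sites gives
D = NaN, identical per-block estimates give SE = 0 and an infinite Z.
Both partition conventions in use are provided — a fixed number of
equal blocks (the remainder absorbed by the last block) and fixed
~1,000-bp blocks — because the published analyses quote both.

The per-block D and Z values printed for the real gene alignments are
not reproducible from the printed ABBA/BABA counts by this (standard)
estimator, so the implementation is validated against arithmetic
oracles and Monte-Carlo calibration instead: under the symmetric null
the empirical type-I error of |Z| > 1.96 is checked to sit at
0.05 ± 0.03, and with 30% introgression from P2 the test must recover
D > 0 with direction P2–P3 in at least 95% of replicates.

## Structure stage

LD pruning follows the greedy sliding-window scheme: within each
≤ 50 kb window all retained pairs are checked and the later site of any
pair with r² > 0.2 removed, the window start then advances by 10
retained sites, and passes repeat until stable (idempotent,
deterministic).  The published setting says a "step window size of
10 bp" while the cited tool's step is counted in sites; the
implementation uses 10 retained *sites* with the 50-kb span, both
configurable.  Note the step > 1 shortcut means a retained pair can in
principle exceed the threshold if no window start covered both — with
step = 1 the invariant is strict, and the test suite checks it there.

PCA mean-imputes missing dosages per site, centres, and reports percent
variance per axis relative to total variance; component signs are fixed
deterministically.  Nei's standard distance is computed between
individual genotypes using within-individual allele frequencies
(0, 0.5, 1), as the published distances are between 26 genotypes, not
populations.  The Mantel test is one-sided (greater — the
isolation-by-distance alternative is positive correlation) with the
+1-corrected Monte-Carlo p over seeded simultaneous row/column
permutations, so p is bitwise reproducible given the seed.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume,
at desk scale (a 200-kb genome over chromosomes 4, 6 and 7 rather than
~380 Mb; simulations and the test suite complete in about a minute):

* 1,400 fixed interspecific SNV differences (0.7% of the genome) —
  chosen so F1/F2 heterozygosity (0.9%/0.6–0.8%) brackets the observed
  early-hybrid range relative to parental levels; 150 of them form the
  six-gene panel (25 sites per gene), the rest are scattered
  ancestry-informative sites; 280 fixed non-SNV differences give the
  variant-class mix its indel component.
* 4,000 background sites with *drifted shared polymorphism*: a shared
  ancestral frequency per site, independently drifted in each taxon
  with Beta concentrations tuned so the expected per-individual
  heterozygosity is 0.16% of genome in taxon A and 0.30% in taxon B
  (the observed parental contrast).  Frequency divergence at these
  sites is what keeps a taxon axis in the PCA after LD pruning, as in
  the real data; a pure private-heterozygosity model would put all
  ancestry information into perfectly-correlated fixed sites that
  pruning removes.  For contract-level tests a simpler mode (site
  heterozygous with a flat probability) is available on the taxon
  model.
* Hybrids follow unlinked Mendelian transmission from an
  all-heterozygous F1: each backcross keeps a diagnostic site
  heterozygous with probability 1/2, each selfing generation halves
  heterozygosity in expectation; background genotypes draw alleles from
  the ancestry-weighted mixture frequency (a deliberate simplification
  that slightly understates F1 background heterozygosity; diagnostic
  sites dominate the classification margin).  Chloroplasts are the
  maternal haplotype plus two private substitutions; the two reference
  plastomes differ by 36 variants, the published divergence.
* The four-taxon simulator drops a single-origin derived allele per
  column independently on the P1, P2, P3 and (P1,P2)-ancestor branches
  (probability 0.05 per branch, giving per-1,118-bp-block informative
  counts of the same order as the real gene alignments) and copies a
  fraction *f* of P3's states from the donor lineage.  With f = 0 the
  construction is exchangeable in (P1, P2), so D = 0 analytically.

Unmodelled features of real data: linkage and recombination maps (all
sites are independent, so windowed LD structure is purely
population-level), sequencing error and coverage variation (allele
frequencies are exact 0/0.5/1), gene conversion, and selection.
Passing tests therefore demonstrate correctness of the estimators and
classification logic under the stated generative model, not robustness
to alignment or calling artefacts.

The default 26-sample scenario (1 A, 20 B, five hybrids F1/F2/BC3/BC4/
BC4 with four cpA and one cpB maternal donors) mirrors the published
sample composition and bidirectional chloroplast capture.  Same seed
gives byte-identical fixture files.

## Numerical conventions

* Coordinates 1-based inclusive throughout; blocks tile [1, L].
* Genotypes are unordered; phase is discarded on input.  Split
  multi-allelic genotypes that involve a third allele stay in the
  variant table (so heterozygosity counting sees them) but are coded
  missing in the genotype matrix, keeping them out of panel calls.
* Heterozygous-position calling requires two distinct alleles and,
  when an allele frequency is present, a minor allele frequency
  ≥ 0.25 (the variant caller's minimum-frequency setting).
* Percentages are reported to two decimals; internal values keep full
  precision.  Division-by-zero situations (no variants, no informative
  sites, zero-variance r²) return flagged NaN/inf rather than raising,
  except where the input is structurally invalid.
* All randomness flows through `numpy.random.default_rng` seeds derived
  with a single `child_seed(seed, k)` helper (always < 2³¹), so every
  simulation, permutation test and fixture is reproducible bitwise.

## Known limitations

* F1 and F2 are not distinguished (the observed system does not allow
  it either); the generation rule is two-class by design.
* Genomic intervals for *GBSSI*, *SSI* and *SBEI* are not published and
  are configuration inputs; the synthetic panel uses scaled-down
  intervals on the same chromosomes.
* Diploid-frequency D, admixture-fraction estimators and windowed
  genome scans are out of scope; the D test operates on haploid
  consensus sequences as in the published gene alignments.
* The Mantel test assumes complete distance matrices; missing pairwise
  distances are not supported.
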