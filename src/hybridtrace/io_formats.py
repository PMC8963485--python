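"""Readers/writers for the standard formats the pipeline touches.

The nuclear backbone of every analysis is :class:`GenotypeMatrix` — an
unphased samples x biallelic-SNV matrix with 1-based VCF coordinates.
Per-sample variant records of *all* classes (SNV, MNV, insertion,
deletion, replacement) live in a long-form pandas ``VariantTable``.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (VCF convention).
* Genotypes are unordered allele pairs; phase in the input is discarded.
* Multi-allelic VCF records are split into one biallelic row per ALT.
  A genotype that carries an allele *other* than the row's REF/ALT is
  kept in the variant table (its true allele pair recorded) but coded
  as missing in the genotype matrix, so it never enters diagnostic-panel
  calls while still being countable as a heterozygous position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .variant_stats import classify_variant

TAXON_LABELS = frozenset({"parental_A", "parental_B", "putative_hybrid", "unknown"})

#: column order of the long-form per-sample variant table
VARIANT_TABLE_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
    "allele1", "allele2", "called", "has_alt", "allele_frequency",
]


class VcfFormatError(ValueError):
    """Raised when a VCF lacks required fields or cannot be parsed."""


@dataclass(frozen=True)
class SampleMetadata:
    """One collection record: who, where, when, and the field taxon call."""

    sample_id: str
    latitude: float
    longitude: float
    collection_year: int
    taxon_label: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range for {self.sample_id}: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range for {self.sample_id}: {self.longitude}")
        if self.taxon_label not in TAXON_LABELS:
            raise ValueError(f"unknown taxon label for {self.sample_id}: {self.taxon_label!r}")


@dataclass
class ReferenceConfig:
    """Genome sizes and chloroplast references for the two parental taxa.

    Taxon A is the O. rufipogon-like taxon (384.8 Mb genome), taxon B is
    O. meridionalis (354.9 Mb).  ``min_het_allele_freq`` mirrors the
    variant caller's 25% minimum allele-frequency setting.
    """

    genome_size_A_bp: int = 384_800_000
    genome_size_B_bp: int = 354_900_000
    cp_ref_A: str = ""
    cp_ref_B: str = ""
    min_het_allele_freq: float = 0.25

    def __post_init__(self) -> None:
        if self.genome_size_A_bp <= 0 or self.genome_size_B_bp <= 0:
            raise ValueError("genome sizes must be positive")

    def genome_size_for(self, nuclear_type: str) -> int:
        if nuclear_type == "A":
            return self.genome_size_A_bp
        # admixed / B samples use the meridionalis genome size, as the
        # recurrent parent of the backcrossed hybrids
        return self.genome_size_B_bp


# genotype codes in GenotypeMatrix
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNV genotype codes with site coordinates.

    ``codes[i, j]`` is 0 (hom-ref), 1 (het), 2 (hom-alt) or -1 (missing)
    for sample ``samples[i]`` at site ``(chrom[j], pos[j])``.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.pos)):
            raise ValueError("codes shape does not match samples x sites")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage matrix (float, missing -> NaN)."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d

    def sites_in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites within [start, end] (1-based inclusive) on chrom."""
        return np.flatnonzero(
            (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)
        )

    def site_lookup(self) -> dict[tuple[str, int], int]:
        return {(str(c), int(p)): j for j, (c, p) in enumerate(zip(self.chrom, self.pos))}

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.chrom, self.pos,
                              self.ref, self.alt, self.codes[idx])

    def to_vcf(self, path: str | Path) -> None:
        write_vcf(path, self.samples, self.chrom, self.pos, self.ref, self.alt, self.codes)


# ---------------------------------------------------------------------------
# VCF

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_AF_STRINGS = {HOM_REF: "0", HET: "0.5", HOM_ALT: "1", MISSING: "."}


def write_vcf(path: str | Path,
              samples: Sequence[str],
              chrom: Iterable[str],
              pos: Iterable[int],
              ref: Iterable[str],
              alt: Iterable[str],
              codes: np.ndarray,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal multi-sample VCF 4.2 file (GT:AF per call)."""
    chrom = list(chrom)
    pos = list(pos)
    ref = list(ref)
    alt = list(alt)
    codes = np.asarray(codes, dtype=np.int8)
    if contig_lengths is None:
        contig_lengths = {}
        for c, p in zip(chrom, pos):
            contig_lengths[str(c)] = max(contig_lengths.get(str(c), 0), int(p))
    lines = ["##fileformat=VCFv4.2"]
    for c in sorted(contig_lengths, key=str):
        lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for j in range(len(pos)):
        calls = "\t".join(
            f"{_GT_STRINGS[int(codes[i, j])]}:{_AF_STRINGS[int(codes[i, j])]}"
            for i in range(len(samples))
        )
        lines.append(
            f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT:AF\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a VCF into a per-sample variant table and a genotype matrix.

    Returns
    -------
    variant_table : pandas.DataFrame
        One row per sample per biallelic variant row (multi-allelic
        records split), columns :data:`VARIANT_TABLE_COLUMNS`.
    genotypes : GenotypeMatrix
        Biallelic SNV sites only.
    """
    from cyvcf2 import VCF  # deferred: htslib import is slow

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib message passthrough
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    if "ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")

    rows: list[tuple] = []
    snv_sites: list[tuple[str, int, str, str]] = []
    snv_codes: list[np.ndarray] = []
    for line_no, v in enumerate(vcf, start=1):
        gts = v.genotypes
        if gts is None or len(gts) != len(samples):
            raise VcfFormatError(f"{path}: record {v.CHROM}:{v.POS} lacks genotypes")
        af_fmt = None
        try:
            af_fmt = v.format("AF")
        except KeyError:
            af_fmt = None
        ad_fmt = None
        try:
            ad_fmt = v.format("AD")
        except KeyError:
            ad_fmt = None
        alleles = [v.REF] + list(v.ALT)
        for k, alt_allele in enumerate(v.ALT, start=1):
            try:
                vclass = classify_variant(v.REF, alt_allele)
            except ValueError:
                vclass = "other"
            col = np.empty(len(samples), dtype=np.int8)
            for i in range(len(samples)):
                a, b = gts[i][0], gts[i][1]
                if a < 0 or b < 0:
                    col[i] = MISSING
                    rows.append((samples[i], v.CHROM, v.POS, v.REF, alt_allele,
                                 vclass, None, None, False, False, np.nan))
                    continue
                pair = tuple(sorted((a, b)))
                al1, al2 = alleles[pair[0]], alleles[pair[1]]
                has_alt = k in pair
                if pair == (0, 0):
                    col[i] = HOM_REF
                elif pair == (0, k):
                    col[i] = HET
                elif pair == (k, k):
                    col[i] = HOM_ALT
                else:
                    # involves a third allele: excluded from matrix analyses
                    col[i] = MISSING
                af = np.nan
                if af_fmt is not None:
                    row_af = np.atleast_1d(af_fmt[i]).astype(float)
                    af = float(row_af[min(k - 1, len(row_af) - 1)])
                elif ad_fmt is not None:
                    depths = np.atleast_1d(ad_fmt[i]).astype(float)
                    total = np.nansum(depths)
                    if total > 0 and len(depths) > k:
                        af = float(depths[k] / total)
                rows.append((samples[i], v.CHROM, v.POS, v.REF, alt_allele,
                             vclass, al1, al2, True, has_alt, af))
            if vclass == "SNV":
                snv_sites.append((v.CHROM, v.POS, v.REF, alt_allele))
                snv_codes.append(col)

    table = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    if snv_sites:
        chrom_arr = np.array([s[0] for s in snv_sites], dtype=object)
        pos_arr = np.array([s[1] for s in snv_sites], dtype=np.int64)
        ref_arr = np.array([s[2] for s in snv_sites], dtype=object)
        alt_arr = np.array([s[3] for s in snv_sites], dtype=object)
        codes = np.column_stack(snv_codes).astype(np.int8)
    else:
        chrom_arr = np.array([], dtype=object)
        pos_arr = np.array([], dtype=np.int64)
        ref_arr = np.array([], dtype=object)
        alt_arr = np.array([], dtype=object)
        codes = np.empty((len(samples), 0), dtype=np.int8)
    gm = GenotypeMatrix(samples, chrom_arr, pos_arr, ref_arr, alt_arr, codes)
    return table, gm


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}``; uppercased, U -> T."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# metadata TSV

_METADATA_COLUMNS = ["sample_id", "latitude", "longitude", "year", "taxon_label"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read and validate the sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    records = [
        SampleMetadata(
            sample_id=row.sample_id,
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            collection_year=int(row.year),
            taxon_label=str(row.taxon_label),
        )
        for row in df.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample_id values")
    return records


def write_metadata(path: str | Path, records: Sequence[SampleMetadata]) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.latitude, r.longitude, r.collection_year, r.taxon_label)
         for r in records],
        columns=_METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.latitude, r.longitude, r.collection_year, r.taxon_label)
         for r in records],
        columns=_METADATA_COLUMNS,
    ).set_index("sample_id")


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
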