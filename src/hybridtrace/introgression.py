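"""ABBA-BABA four-taxon test with block-jackknife significance.

For a rooted topology (((P1, P2), P3), O) the outgroup O polarizes each
biallelic column into ancestral ("A") and derived ("B") states.  The two
discordant patterns ABBA (P2 and P3 share the derived allele) and BABA
(P1 and P3 share it) are equally likely under incomplete lineage sorting,
so Patterson's D = (nABBA - nBABA) / (nABBA + nBABA) has expectation 0;
an excess of one pattern indicates introgression.  Significance comes
from a delete-one block jackknife over contiguous alignment blocks:
SE^2 = ((m-1)/m) * sum_j (D_(-j) - mean)^2, Z = D/SE, with a two-sided
normal p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FourTaxonAlignment:
    """Equal-length aligned sequences in the fixed order P1, P2, P3, outgroup."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        lengths = {len(self.p1), len(self.p2), len(self.p3), len(self.outgroup)}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self._arr = np.frombuffer(
            (self.p1 + self.p2 + self.p3 + self.outgroup).upper().encode(), dtype="S1"
        ).reshape(4, len(self.p1))

    @property
    def length(self) -> int:
        return len(self.p1)

    def arrays(self) -> np.ndarray:
        """4 x L byte array (rows P1, P2, P3, outgroup)."""
        return self._arr

    @classmethod
    def from_fasta(cls, seqs: dict[str, str],
                   order: tuple[str, str, str, str] | None = None) -> "FourTaxonAlignment":
        if order is None:
            if len(seqs) != 4:
                raise ValueError("expected exactly four sequences")
            order = tuple(seqs)  # input order P1, P2, P3, outgroup
        return cls(*(seqs[name] for name in order))


@dataclass
class DStatResult:
    n_abba: int
    n_baba: int
    d: float                      # NaN when no informative sites
    se: float
    z: float
    p_value: float
    n_blocks: int                 # blocks with informative sites (jackknifed)
    block_boundaries: list[tuple[int, int]]
    block_counts: list[tuple[int, int]]
    direction: str                # P2_P3 / P1_P3 / none
    d_defined: bool
    z_defined: bool


def count_site_patterns(
    aln: FourTaxonAlignment, region: tuple[int, int] | None = None
) -> tuple[int, int, int]:
    """Count ABBA and BABA columns in a region (1-based inclusive).

    A column is eligible iff it has no gap/N, exactly two distinct
    nucleotides across the four sequences, and the outgroup carries one
    of them (the ancestral state).  Returns (n_ABBA, n_BABA,
    n_informative) where informative = ABBA + BABA.
    """
    arr = aln.arrays()
    if region is not None:
        start, end = region
        if not (1 <= start <= end <= aln.length):
            raise ValueError(f"region {region} outside [1, {aln.length}]")
        arr = arr[:, start - 1:end]
    p1, p2, p3, og = arr
    valid = np.ones(arr.shape[1], dtype=bool)
    for row in arr:
        valid &= np.isin(row, _VALID)
    abba = valid & (p1 == og) & (p2 == p3) & (p2 != og)
    baba = valid & (p2 == og) & (p1 == p3) & (p1 != og)
    n_abba = int(abba.sum())
    n_baba = int(baba.sum())
    return n_abba, n_baba, n_abba + n_baba


def patterson_d(n_abba: int, n_baba: int) -> float:
    """D = (nABBA - nBABA)/(nABBA + nBABA); NaN if no informative sites."""
    if n_abba < 0 or n_baba < 0:
        raise ValueError("counts must be non-negative")
    total = n_abba + n_baba
    if total == 0:
        return math.nan
    return (n_abba - n_baba) / total


def partition_blocks(
    aln_length: int, mode: str, value: int
) -> list[tuple[int, int]]:
    """Tile [1, L] with contiguous 1-based inclusive blocks.

    ``mode="n_blocks"``: the first n-1 blocks have length floor(L/n) and
    the last absorbs the remainder.  ``mode="block_len"``: consecutive
    blocks of the given length, the last possibly shorter.  A value
    exceeding L yields a single block with a warning.
    """
    if value < 1:
        raise ValueError("value must be >= 1")
    if aln_length < 1:
        raise ValueError("alignment length must be >= 1")
    if mode == "n_blocks":
        n = value
        if n > aln_length:
            warnings.warn("more blocks than sites; using a single block")
            return [(1, aln_length)]
        size = aln_length // n
        bounds = [(i * size + 1, (i + 1) * size) for i in range(n - 1)]
        bounds.append(((n - 1) * size + 1, aln_length))
        return bounds
    if mode == "block_len":
        if value > aln_length:
            warnings.warn("block length exceeds alignment; using a single block")
            return [(1, aln_length)]
        bounds = []
        start = 1
        while start <= aln_length:
            bounds.append((start, min(start + value - 1, aln_length)))
            start += value
        return bounds
    raise ValueError(f"unknown mode {mode!r}")


def jackknife_from_block_counts(
    block_counts: list[tuple[int, int]]
) -> tuple[float, float, float, float, int]:
    """Delete-one jackknife for D from per-block (ABBA, BABA) counts.

    Blocks with zero informative sites are dropped.  Returns
    (D, SE, Z, p, m) where m is the number of jackknifed blocks; SE/Z/p
    are NaN when fewer than two informative blocks exist, and Z is +/-inf
    when the delete-one estimates are degenerate (SE = 0).
    """
    counts = np.asarray(block_counts, dtype=float)
    tot_abba, tot_baba = counts.sum(axis=0)
    d = patterson_d(int(tot_abba), int(tot_baba))
    informative = counts.sum(axis=1) > 0
    m = int(informative.sum())
    if m < len(block_counts):
        warnings.warn(f"{len(block_counts) - m} block(s) without informative sites "
                      "dropped from the jackknife")
    if m < 2 or math.isnan(d):
        return d, math.nan, math.nan, math.nan, m
    kept = counts[informative]
    loo_abba = tot_abba - kept[:, 0]
    loo_baba = tot_baba - kept[:, 1]
    loo_d = (loo_abba - loo_baba) / (loo_abba + loo_baba)
    se = math.sqrt((m - 1) / m * float(np.sum((loo_d - loo_d.mean()) ** 2)))
    if se == 0.0:
        z = math.copysign(math.inf, d) if d != 0 else math.nan
        return d, 0.0, z, math.nan, m
    z = d / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return d, se, z, p, m


def infer_direction(d: float, significant: bool) -> str:
    """Geneflow direction label from D and its significance.

    Not significant -> "none" (consistent with lineage sorting);
    D > 0 -> introgression between P2 and P3; D < 0 -> between P1 and P3.
    """
    if math.isnan(d):
        raise ValueError("D is undefined")
    if not significant or d == 0:
        return "none"
    return "P2_P3" if d > 0 else "P1_P3"


def block_jackknife_d(
    aln: FourTaxonAlignment,
    boundaries: list[tuple[int, int]],
    alpha: float = 0.05,
) -> DStatResult:
    """Patterson's D with block-jackknife Z/p over the given blocks."""
    block_counts = []
    for (start, end) in boundaries:
        a, b, _ = count_site_patterns(aln, (start, end))
        block_counts.append((a, b))
    d, se, z, p, m = jackknife_from_block_counts(block_counts)
    n_abba = sum(c[0] for c in block_counts)
    n_baba = sum(c[1] for c in block_counts)
    d_defined = not math.isnan(d)
    z_defined = math.isfinite(z)
    significant = z_defined and not math.isnan(p) and p < alpha
    direction = infer_direction(d, significant) if d_defined else "none"
    return DStatResult(
        n_abba=n_abba, n_baba=n_baba, d=d, se=se, z=z, p_value=p,
        n_blocks=m, block_boundaries=list(boundaries),
        block_counts=block_counts, direction=direction,
        d_defined=d_defined, z_defined=z_defined,
    )


def dstat_test(
    aln: FourTaxonAlignment,
    n_blocks: int | None = None,
    block_len: int | None = None,
    alpha: float = 0.05,
) -> DStatResult:
    """Convenience wrapper: partition the alignment, then jackknife D.

    Exactly one of ``n_blocks`` / ``block_len`` must be given (both
    partition conventions are in use for these alignments: equal-count
    blocks and fixed ~1 kb blocks).
    """
    if (n_blocks is None) == (block_len is None):
        raise ValueError("give exactly one of n_blocks or block_len")
    if n_blocks is not None:
        bounds = partition_blocks(aln.length, "n_blocks", n_blocks)
    else:
        bounds = partition_blocks(aln.length, "block_len", block_len)
    return block_jackknife_d(aln, bounds, alpha=alpha)
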