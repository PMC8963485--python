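"""Population structure and isolation-by-distance analyses.

Operates on an alternate-allele dosage matrix (samples x biallelic SNVs,
entries 0/1/2 or NaN): sliding-window LD pruning (50 kb window, step of
10 retained sites, r^2 <= 0.2 by default), PCA of mean-imputed centred
dosages, Nei's standard genetic distance between individual genotypes
(within-individual allele frequencies 0/0.5/1), haversine geographic
distance, and a seeded one-sided Mantel permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

EARTH_RADIUS_KM = 6371.0


@dataclass
class PCAResult:
    coordinates: np.ndarray       # samples x k
    percent_variance: np.ndarray  # length k, non-increasing


@dataclass
class MantelResult:
    r_observed: float
    p_value: float
    n_permutations: int
    seed: int
    n_pairs: int


# ---------------------------------------------------------------------------
# LD pruning

def pairwise_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls.

    Sites with zero variance: r^2 is 1 if the two vectors are identical
    over the shared calls, otherwise NaN (undefined).  An all-missing
    overlap is NaN.
    """
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return math.nan
    x, y = x[ok], y[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 1.0 if np.array_equal(x, y) else math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def _r2_one_vs_many(dosage: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """r^2 of site i against each of sites js, with pairwise_r2 semantics."""
    x = dosage[:, i]
    ys = dosage[:, js]
    if np.isnan(x).any() or np.isnan(ys).any():
        return np.array([pairwise_r2(x, dosage[:, j]) for j in js])
    xc = x - x.mean()
    yc = ys - ys.mean(axis=0)
    sx = math.sqrt(float(xc @ xc))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    out = np.full(len(js), math.nan)
    ok = (sx > 0) & (sy > 0)
    if sx > 0 and ok.any():
        out[ok] = ((xc @ yc[:, ok]) / (sx * sy[ok])) ** 2
    degenerate = ~ok
    if degenerate.any():
        same = np.all(ys[:, degenerate] == x[:, None], axis=0)
        out[np.flatnonzero(degenerate)[same]] = 1.0
    return out


def ld_prune(
    dosage: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    window_bp: int = 50_000,
    step: int = 10,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained site indices.

    Within each window (span <= window_bp on one chromosome) every
    retained pair is checked and the *later* site of a pair with
    r^2 > r2_max is removed; the window start then advances by ``step``
    retained sites.  Passes repeat until no removal occurs, so the
    result is idempotent and deterministic.  Sites must be sorted by
    (chrom, pos).
    """
    dosage = np.asarray(dosage, dtype=float)
    pos = np.asarray(pos, dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    n_sites = dosage.shape[1]
    if n_sites != len(pos):
        raise ValueError("dosage/site shapes disagree")
    for c in np.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("sites must be sorted by (chrom, pos)")
    keep = np.ones(n_sites, dtype=bool)
    changed = True
    while changed:
        changed = False
        for c in np.unique(chrom):
            cidx = np.flatnonzero(chrom == c)
            w = 0
            while True:
                ridx = cidx[keep[cidx]]
                if w >= len(ridx):
                    break
                start_pos = pos[ridx[w]]
                window = ridx[(pos[ridx] >= start_pos)
                              & (pos[ridx] <= start_pos + window_bp)]
                for a_i in range(len(window)):
                    i = window[a_i]
                    if not keep[i]:
                        continue
                    later = window[a_i + 1:]
                    later = later[keep[later]]
                    if len(later) == 0:
                        continue
                    r2 = _r2_one_vs_many(dosage, i, later)
                    hits = later[~np.isnan(r2) & (r2 > r2_max)]
                    if len(hits):
                        keep[hits] = False
                        changed = True
                w += step
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# PCA

def pca_genotypes(dosage: np.ndarray, k: int) -> PCAResult:
    """PCA of the mean-imputed, per-site centred dosage matrix.

    Percent variance per axis is relative to the total variance of the
    imputed matrix.  Component signs are fixed so the loading of largest
    magnitude is positive (deterministic output).
    """
    x = np.asarray(dosage, dtype=float).copy()
    n, s = x.shape
    if k > min(n, s):
        raise ValueError(f"k={k} exceeds min(samples, sites)={min(n, s)}")
    if np.any(np.all(np.isnan(x), axis=1)):
        raise ValueError("matrix contains an all-missing sample")
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(x)
    for axis in range(k):
        comp = model.components_[axis]
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, axis] *= -1.0
    if x.var(axis=0).sum() == 0.0:   # constant matrix: no variance to explain
        pct = np.zeros(k)
    else:
        pct = 100.0 * model.explained_variance_ratio_
    return PCAResult(coordinates=coords, percent_variance=pct)


# ---------------------------------------------------------------------------
# Nei distance

def nei_distance(freqs_x: np.ndarray, freqs_y: np.ndarray) -> float:
    """Nei's standard genetic distance from per-locus allele frequencies.

    ``freqs_x`` / ``freqs_y`` are alternate-allele frequencies per shared
    biallelic locus (for an individual genotype: 0, 0.5 or 1; NaN =
    missing).  D = -ln(Jxy / sqrt(Jx * Jy)) with J the mean probability
    of allele identity; no shared alleles anywhere -> +inf.
    """
    x = np.asarray(freqs_x, dtype=float)
    y = np.asarray(freqs_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError("no shared loci")
    x, y = x[ok], y[ok]
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    jx = float(np.mean(x ** 2 + (1 - x) ** 2))
    jy = float(np.mean(y ** 2 + (1 - y) ** 2))
    if jxy == 0.0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def nei_distance_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise Nei distance between individuals from a dosage matrix."""
    freqs = np.asarray(dosage, dtype=float) / 2.0
    n = freqs.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = nei_distance(freqs[i], freqs[j])
    return out


# ---------------------------------------------------------------------------
# geography

def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in kilometres (Earth radius 6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distance_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    n = len(lat)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = great_circle_km(lat[i], lon[i], lat[j], lon[j])
    return out


# ---------------------------------------------------------------------------
# Mantel test

def _check_square_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError(f"{name} has a non-zero diagonal")
    return m


def mantel_test(
    genetic_dist: np.ndarray,
    geographic_dist: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-sided (greater) Mantel permutation test for matrix correlation.

    r is the Pearson correlation of the upper off-diagonal triangles;
    the null distribution comes from ``n_perm`` seeded simultaneous
    row/column permutations of one matrix, and
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    gd = _check_square_symmetric(genetic_dist, "genetic matrix")
    geo = _check_square_symmetric(geographic_dist, "geographic matrix")
    if gd.shape != geo.shape:
        raise ValueError("matrices have different shapes")
    n = gd.shape[0]
    iu = np.triu_indices(n, k=1)
    x = gd[iu]
    y = geo[iu]
    xc = x - x.mean()
    yc = y - y.mean()
    denom_y = math.sqrt(float(yc @ yc))
    denom_x = math.sqrt(float(xc @ xc))
    if denom_x == 0.0 or denom_y == 0.0:
        raise ValueError("distance matrix with zero variance")
    r_obs = float(xc @ yc) / (denom_x * denom_y)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = gd[np.ix_(perm, perm)][iu]
        xpc = xp - xp.mean()
        r_perm = float(xpc @ yc) / (math.sqrt(float(xpc @ xpc)) * denom_y)
        if r_perm >= r_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return MantelResult(r_observed=r_obs, p_value=p, n_permutations=n_perm,
                        seed=seed, n_pairs=len(x))
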