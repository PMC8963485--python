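import math

import numpy as np
import pytest

from hybridtrace.structure import (geographic_distance_matrix, great_circle_km,
                                   ld_prune, mantel_test, nei_distance,
                                   nei_distance_matrix, pairwise_r2,
                                   pca_genotypes)


# --- pairwise r^2 -----------------------------------------------------------

@pytest.mark.parametrize("x, y, expected", [
    ([0, 1, 2, 1], [0, 1, 2, 1], 1.0),
    ([0, 1, 2, 1], [2, 1, 0, 1], 1.0),        # perfect negative correlation
    ([0, 0, 1, 1], [0, 1, 0, 1], 0.0),
])
def test_pairwise_r2_examples(x, y, expected):
    assert pairwise_r2(np.array(x, float), np.array(y, float)) == pytest.approx(expected)


def test_pairwise_r2_degenerate_cases():
    const = np.array([1.0, 1.0, 1.0])
    assert pairwise_r2(const, const) == 1.0                  # identical constants
    assert math.isnan(pairwise_r2(const, np.array([0.0, 1.0, 2.0])))
    assert math.isnan(pairwise_r2(np.array([np.nan, np.nan]), np.array([1.0, 2.0])))


# --- LD pruning -------------------------------------------------------------

def test_prune_keeps_first_of_duplicated_pair(rng):
    base = rng.integers(0, 3, size=40).astype(float)
    indep = rng.binomial(2, 0.5, size=40).astype(float)
    dosage = np.column_stack([base, base, indep])
    retained = ld_prune(dosage, np.array(["6"] * 3, dtype=object),
                        np.array([1_000, 2_000, 3_000]))
    assert 0 in retained and 1 not in retained


def test_prune_retains_independent_sites(rng):
    # n=400 samples: chance r^2 > 0.2 between independent sites is negligible
    dosage = rng.binomial(2, 0.5, size=(400, 30)).astype(float)
    pos = np.arange(30) * 1_000 + 1
    chrom = np.array(["6"] * 30, dtype=object)
    r2 = np.corrcoef(dosage.T) ** 2
    assert np.max(r2[~np.eye(30, dtype=bool)]) < 0.2  # precondition
    retained = ld_prune(dosage, chrom, pos)
    assert len(retained) == 30


def test_prune_correlated_block_plus_independents(rng):
    """Five copies of one site and five independent sites -> six retained."""
    v = rng.integers(0, 3, size=300).astype(float)
    indep = rng.binomial(2, 0.5, size=(300, 5)).astype(float)
    dosage = np.column_stack([np.tile(v[:, None], 5), indep])
    pos = np.arange(10) * 500 + 1
    chrom = np.array(["6"] * 10, dtype=object)
    retained = ld_prune(dosage, chrom, pos)
    assert list(retained) == [0, 5, 6, 7, 8, 9]


def test_prune_is_idempotent(fixture_set):
    gm = fixture_set.scenario.genotype_matrix(
        fixture_set.sample_ids, fixture_set.codes)
    dosage = gm.dosage()
    first = ld_prune(dosage, gm.chrom, gm.pos)
    again = ld_prune(dosage[:, first], gm.chrom[first], gm.pos[first])
    assert np.array_equal(again, np.arange(len(first)))


def test_prune_with_unit_step_leaves_no_close_correlated_pair(fixture_set):
    """With a window start at every retained site, no retained pair closer
    than the window span exceeds the r^2 threshold."""
    gm = fixture_set.scenario.genotype_matrix(
        fixture_set.sample_ids, fixture_set.codes)
    dosage = gm.dosage()
    kept = ld_prune(dosage, gm.chrom, gm.pos, step=1)
    for c in np.unique(gm.chrom[kept]):
        idx = kept[gm.chrom[kept] == c]
        for ai in range(len(idx)):
            for bi in range(ai + 1, len(idx)):
                if gm.pos[idx[bi]] - gm.pos[idx[ai]] > 50_000:
                    break
                r2 = pairwise_r2(dosage[:, idx[ai]], dosage[:, idx[bi]])
                assert math.isnan(r2) or r2 <= 0.2


def test_prune_rejects_unsorted_positions(rng):
    dosage = rng.binomial(2, 0.5, size=(10, 3)).astype(float)
    with pytest.raises(ValueError, match="sorted"):
        ld_prune(dosage, np.array(["6"] * 3, dtype=object),
                 np.array([300, 100, 200]))


# --- PCA --------------------------------------------------------------------

def test_pca_identical_rows_have_zero_variance():
    dosage = np.tile(np.array([0.0, 1.0, 2.0, 1.0]), (6, 1))
    res = pca_genotypes(dosage, k=2)
    assert np.allclose(res.percent_variance, 0.0)
    assert np.allclose(res.coordinates, 0.0)


def test_pca_two_clusters_on_pc1(rng):
    group_a = np.tile(np.array([0.0] * 20), (5, 1))
    group_b = np.tile(np.array([2.0] * 20), (5, 1))
    res = pca_genotypes(np.vstack([group_a, group_b]), k=2)
    pc1 = res.coordinates[:, 0]
    assert (pc1[:5].max() < pc1[5:].min()) or (pc1[:5].min() > pc1[5:].max())
    assert res.percent_variance[0] == pytest.approx(100.0)


def test_pca_axes_are_orthogonal_and_ordered(fixture_set):
    gm = fixture_set.scenario.genotype_matrix(
        fixture_set.sample_ids, fixture_set.codes)
    res = pca_genotypes(gm.dosage(), k=4)
    gram = res.coordinates.T @ res.coordinates
    assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
    assert np.all(np.diff(res.percent_variance) <= 1e-12)
    assert res.percent_variance.sum() <= 100.0 + 1e-9


def test_pca_validates_k():
    with pytest.raises(ValueError):
        pca_genotypes(np.zeros((3, 5)), k=4)


# --- Nei distance -----------------------------------------------------------

def test_nei_distance_worked_examples():
    assert nei_distance(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0
    # single locus, x fixed for the alternate allele, y at 0.5
    d = nei_distance(np.array([1.0]), np.array([0.5]))
    assert d == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-4)
    assert d == pytest.approx(0.3466, abs=1e-4)
    assert math.isinf(nei_distance(np.array([1.0, 1.0]), np.array([0.0, 0.0])))


def test_nei_distance_symmetric_and_monotone(rng):
    x = rng.random(50)
    y = rng.random(50)
    assert nei_distance(x, y) == pytest.approx(nei_distance(y, x))
    # replacing a shared-allele locus by a fixed difference increases distance
    x2, y2 = x.copy(), y.copy()
    x2[0], y2[0] = 1.0, 1.0
    x3, y3 = x2.copy(), y2.copy()
    x3[0], y3[0] = 1.0, 0.0
    assert nei_distance(x3, y3) > nei_distance(x2, y2)


def test_nei_distance_requires_shared_loci():
    with pytest.raises(ValueError):
        nei_distance(np.array([np.nan]), np.array([0.5]))


# --- geography --------------------------------------------------------------

def test_great_circle_examples():
    assert great_circle_km(10.0, 20.0, 10.0, 20.0) == 0.0
    assert great_circle_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.19, abs=0.01)
    assert great_circle_km(-12.0, 143.0, -15.0, 145.0) == pytest.approx(
        great_circle_km(-15.0, 145.0, -12.0, 143.0))


# --- Mantel -----------------------------------------------------------------

def _ibd_matrices(n=10):
    x = np.arange(n, dtype=float)
    g = np.abs(np.subtract.outer(x, x))
    return g, 2.0 * g


def test_mantel_perfect_correlation():
    g, geo = _ibd_matrices()
    res = mantel_test(g, geo, n_perm=999, seed=3)
    assert res.r_observed == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 1000)


def test_mantel_anticorrelated_matrices():
    g, _ = _ibd_matrices()
    geo = g.max() - g
    np.fill_diagonal(geo, 0.0)
    res = mantel_test(g, geo, n_perm=99, seed=3)
    assert res.r_observed < -0.9


def test_mantel_seeded_reproducibility(rng):
    n = 12
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    b = rng.random((n, n))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    r1 = mantel_test(a, b, n_perm=499, seed=17)
    r2 = mantel_test(a, b, n_perm=499, seed=17)
    assert (r1.r_observed, r1.p_value) == (r2.r_observed, r2.p_value)


def test_mantel_r_matches_scikit_bio(rng):
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel
    n = 15
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    b = rng.random((n, n))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    ours = mantel_test(a, b, n_perm=9, seed=1)
    theirs = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                          method="pearson", permutations=0)
    assert ours.r_observed == pytest.approx(float(theirs[0]), abs=1e-10)


def test_mantel_validates_inputs():
    g, geo = _ibd_matrices()
    with pytest.raises(ValueError, match="symmetric"):
        bad = g.copy()
        bad[0, 1] += 1
        mantel_test(bad, geo)
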