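import hashlib
import math
from dataclasses import replace

import numpy as np
import pytest

from hybridtrace.introgression import count_site_patterns, patterson_d
from hybridtrace.synthetic_data import (CrossSpec, TaxonModel, child_seed,
                                        default_scenario,
                                        simulate_four_taxon_alignment,
                                        simulate_hybrid,
                                        simulate_parental_individuals,
                                        write_fixture_set)


def toy_model(rate: float, n_diag: int = 50, n_bg: int = 1_000,
              taxon: str = "A") -> TaxonModel:
    diag = np.arange(n_diag)
    bg = np.arange(n_diag, n_diag + n_bg)
    return TaxonModel(
        name=taxon, n_sites=n_diag + n_bg,
        diagnostic_site_indices=diag, fixed_site_indices=diag,
        background_site_indices=bg,
        allele_A_per_site=np.array(["A"] * n_diag, dtype=object),
        allele_B_per_site=np.array(["G"] * n_diag, dtype=object),
        fixed_code=0 if taxon == "A" else 2,
        background_het_rate=rate,
        cp_haplotype="cpA" if taxon == "A" else "cpB",
        cp_sequence="ACGT" * 100,
    )


def test_parental_extremes_of_background_rate():
    codes, _ = simulate_parental_individuals(toy_model(0.0), 5, seed=1)
    assert np.all(codes != 1)
    codes, _ = simulate_parental_individuals(toy_model(1.0), 5, seed=1)
    bg = toy_model(1.0).background_site_indices
    assert np.all(codes[:, bg] == 1)


def test_parental_heterozygosity_within_binomial_bounds():
    rate = 0.003
    model = toy_model(rate, n_bg=10_000)
    codes, _ = simulate_parental_individuals(model, 200, seed=2)
    realized = (codes[:, model.background_site_indices] == 1).mean()
    sd = math.sqrt(rate * (1 - rate) / (200 * 10_000))
    assert abs(realized - rate) < 3 * sd


def test_f1_heterozygous_at_every_diagnostic_site():
    a, b = toy_model(0.0, taxon="A"), toy_model(0.0, taxon="B")
    codes, _, label = simulate_hybrid(a, b, CrossSpec(kind="F1", seed=5))
    assert label == "F1"
    assert np.all(codes[a.diagnostic_site_indices] == 1)


def test_backcross_heterozygosity_decays_binomially():
    """BC3 to parent B leaves (1/2)^3 of diagnostic sites heterozygous."""
    a = toy_model(0.0, n_diag=1_000, taxon="A")
    b = toy_model(0.0, n_diag=1_000, taxon="B")
    p = 0.125
    fracs = []
    for k in range(20):
        codes, _, _ = simulate_hybrid(
            a, b, CrossSpec(kind="BC", n_backcrosses=3,
                            recurrent_parent="B", seed=child_seed(6, k)))
        fracs.append((codes[a.diagnostic_site_indices] == 1).mean())
    sd = math.sqrt(p * (1 - p) / (20 * 1_000))
    assert abs(np.mean(fracs) - p) < 3 * sd
    # every non-het diagnostic site is fixed for the recurrent parent
    assert np.all(np.isin(codes[a.diagnostic_site_indices], [1, 2]))


def test_backcross_decay_is_geometric():
    """log heterozygous fraction declines by ln 2 per backcross (within 10%)."""
    a = toy_model(0.0, n_diag=2_000, taxon="A")
    b = toy_model(0.0, n_diag=2_000, taxon="B")
    ns = np.arange(1, 6)
    means = []
    for n in ns:
        fr = [
            (simulate_hybrid(a, b, CrossSpec(kind="BC", n_backcrosses=int(n),
                                             seed=child_seed(30 + n, k)))[0]
             [a.diagnostic_site_indices] == 1).mean()
            for k in range(50)
        ]
        means.append(np.mean(fr))
    slope = np.polyfit(ns, np.log(means), 1)[0]
    assert abs(slope - (-math.log(2))) < 0.1 * math.log(2)


def test_chloroplast_follows_maternal_parent_only():
    a, b = toy_model(0.0, taxon="A"), toy_model(0.0, taxon="B")
    for kind, n_bc in (("F1", 0), ("BC", 4)):
        spec = CrossSpec(kind=kind, n_backcrosses=n_bc, recurrent_parent="B",
                         maternal_parent="A", seed=9)
        _, cp, _ = simulate_hybrid(a, b, spec)
        # cp differs from the maternal haplotype only by private mutations
        diff_a = sum(x != y for x, y in zip(cp, a.cp_sequence))
        assert diff_a <= 2


def test_cross_spec_validation():
    with pytest.raises(ValueError):
        CrossSpec(kind="BC", n_backcrosses=0)
    with pytest.raises(ValueError):
        CrossSpec(kind="F1", n_backcrosses=2)
    with pytest.raises(ValueError):
        CrossSpec(kind="F3")


def test_selfing_halves_heterozygosity_in_expectation():
    a = toy_model(0.0, n_diag=2_000, taxon="A")
    b = toy_model(0.0, n_diag=2_000, taxon="B")
    fr = [
        (simulate_hybrid(a, b, CrossSpec(kind="F2", seed=child_seed(44, k)))[0]
         [a.diagnostic_site_indices] == 1).mean()
        for k in range(20)
    ]
    sd = math.sqrt(0.5 * 0.5 / (20 * 2_000))
    assert abs(np.mean(fr) - 0.5) < 3 * sd


# --- four-taxon simulator ---------------------------------------------------

def test_null_alignment_has_unbiased_d():
    """f = 0: mean D over replicates within 3 SE of zero."""
    ds = []
    for k in range(10):
        aln = simulate_four_taxon_alignment(50_000, 0.05, 0.0, "P2",
                                            seed=child_seed(50, k))
        a, b, _ = count_site_patterns(aln)
        ds.append(patterson_d(a, b))
    se = np.std(ds, ddof=1) / math.sqrt(len(ds))
    assert abs(np.mean(ds)) < 3 * se


def test_null_d_sign_is_balanced():
    """Under exchangeable ABBA/BABA counts, sign(D) is positive ~50% of runs."""
    pos = 0
    for k in range(200):
        aln = simulate_four_taxon_alignment(20_000, 0.05, 0.0, "P2",
                                            seed=child_seed(51, k))
        a, b, _ = count_site_patterns(aln)
        if patterson_d(a, b) > 0:
            pos += 1
    assert abs(pos / 200 - 0.5) <= 0.10


def test_introgression_shifts_d_positive():
    hits = 0
    for k in range(10):
        aln = simulate_four_taxon_alignment(50_000, 0.05, 0.3, "P2",
                                            seed=child_seed(52, k))
        a, b, _ = count_site_patterns(aln)
        if patterson_d(a, b) > 0:
            hits += 1
    assert hits >= 9


def test_zero_substitution_probability_gives_no_informative_sites():
    aln = simulate_four_taxon_alignment(1_000, 0.0, 0.0, "P2", seed=1)
    a, b, n = count_site_patterns(aln)
    assert (a, b, n) == (0, 0, 0)
    assert math.isnan(patterson_d(a, b))


def test_outgroup_always_carries_ancestral_state():
    aln = simulate_four_taxon_alignment(5_000, 0.3, 0.5, "P1", seed=2)
    arr = aln.arrays()
    # every biallelic column's outgroup allele appears in >= 1 other row or
    # stands alone; by construction it is never the single derived allele
    # shared by exactly P2 and P3 AND P1 (all-derived columns keep ancestral O)
    assert set(np.unique(arr[3])) <= set(np.frombuffer(b"ACGT", dtype="S1"))


# --- fixture sets -----------------------------------------------------------

def _digest(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


def test_fixture_set_is_deterministic(tmp_path):
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    write_fixture_set(d1, seed=3)
    write_fixture_set(d2, seed=3)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert _digest(d1 / name) == _digest(d2 / name), name
    d3 = tmp_path / "c"
    write_fixture_set(d3, seed=4)
    assert _digest(d1 / "genotypes.vcf") != _digest(d3 / "genotypes.vcf")


def test_default_scenario_composition(fixture_set):
    fx = fixture_set
    assert len(fx.sample_ids) == 26
    assert len(fx.truth) == 26
    labels = fx.truth["true_taxon"].value_counts()
    assert labels["parental_B"] == 20 and labels["parental_A"] == 1
    assert labels["hybrid"] == 5
    # chloroplast haplotype is set by the maternal lineage alone
    hyb = fx.truth[fx.truth.true_taxon == "hybrid"]
    for r in hyb.itertuples():
        assert r.cp_haplotype == ("cpA" if r.maternal_parent == "A" else "cpB")


def test_scenario_site_map_is_consistent(scenario):
    assert scenario.n_sites == 5_680
    assert (scenario.category == "diag").sum() == 1_400
    assert (scenario.category == "sv").sum() == 280
    # panel sites sit inside their gene interval and alleles differ
    for g in scenario.panel.genes:
        sub = scenario.panel.sites_for(g.name)
        assert len(sub) == 25
        assert ((sub.pos >= g.start) & (sub.pos <= g.end)).all()
        assert (sub.allele_A != sub.allele_B).all()
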