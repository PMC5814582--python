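"""LD statistics, tag-SNP pruning and saturation curves."""

import numpy as np
import pandas as pd
import pytest

from svmosaic.ld import (
    LDUndefinedError,
    compute_r2_dprime,
    ld_decay,
    ld_pairs,
    saturation_analysis,
    window_prune,
)
from svmosaic.matrix import GenotypeMatrix
from svmosaic.synth import SyntheticSpec, generate_cohort


def _matrix_from_geno(geno, chrom="c1", spacing=1000):
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": np.arange(1, n_sites + 1) * spacing,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(sites=sites, samples=[f"S{j}" for j in range(n_samples)], geno=geno)


def _geno_from_hap_counts(n_AB, n_Ab, n_aB, n_ab):
    """Two genotype vectors realizing the given inbred haplotype counts
    (A/B = reference alleles)."""
    gi = [0] * n_AB + [0] * n_Ab + [2] * n_aB + [2] * n_ab
    gj = [0] * n_AB + [2] * n_Ab + [0] * n_aB + [2] * n_ab
    return np.array(gi), np.array(gj)


# ----------------------------------------------------------------------
# r2 / D'
# ----------------------------------------------------------------------
def test_identical_vectors_give_perfect_ld():
    g = np.array([0, 0, 2, 2, 0, 2])
    r2, dp = compute_r2_dprime(g, g)
    assert r2 == pytest.approx(1.0)
    assert dp == pytest.approx(1.0)


def test_equifrequent_independent_sites_give_zero():
    gi, gj = _geno_from_hap_counts(1, 1, 1, 1)
    r2, dp = compute_r2_dprime(gi, gj)
    assert r2 == pytest.approx(0.0)
    assert dp == pytest.approx(0.0)


def test_hand_computed_two_by_two_table():
    """AB=3, Ab=1, aB=1, ab=3: D = 3/8 - 1/4 = 0.125, r2 = 0.25, D' = 0.5."""
    gi, gj = _geno_from_hap_counts(3, 1, 1, 3)
    r2, dp = compute_r2_dprime(gi, gj)
    assert r2 == pytest.approx(0.25)
    assert dp == pytest.approx(0.5)


def test_monomorphic_pair_is_undefined():
    with pytest.raises(LDUndefinedError):
        compute_r2_dprime(np.zeros(10), np.array([0, 2] * 5))


def test_hets_and_missing_are_excluded_pairwise():
    gi, gj = _geno_from_hap_counts(3, 1, 1, 3)
    gi = np.concatenate([gi, [1, -1, 2]])
    gj = np.concatenate([gj, [0, 2, 1]])
    r2, dp = compute_r2_dprime(gi, gj)
    assert r2 == pytest.approx(0.25)
    assert dp == pytest.approx(0.5)


def test_vectorized_pairs_agree_with_scalar_on_toy_set():
    rng = np.random.default_rng(5)
    geno = rng.choice([0, 1, 2, -1], size=(20, 40), p=[0.45, 0.05, 0.45, 0.05]).astype(np.int8)
    m = _matrix_from_geno(geno)
    pairs = ld_pairs(m, max_lag=19)
    got = {(r.pos_i, r.pos_j): (r.r2, r.dprime) for r in pairs.itertuples()}
    n_defined = 0
    for i in range(20):
        for j in range(i + 1, 20):
            try:
                r2, dp = compute_r2_dprime(geno[i], geno[j])
            except LDUndefinedError:
                assert (1000 * (i + 1), 1000 * (j + 1)) not in got
                continue
            n_defined += 1
            key = (1000 * (i + 1), 1000 * (j + 1))
            assert got[key][0] == pytest.approx(r2)
            assert got[key][1] == pytest.approx(dp)
    assert n_defined > 100


def test_r2_bounded_by_dprime(small_truth):
    pairs = ld_pairs(small_truth.genotypes, max_lag=30)
    assert ((pairs["r2"] >= -1e-12) & (pairs["r2"] <= pairs["dprime"] + 1e-9)).all()
    assert (pairs["dprime"] <= 1 + 1e-9).all()


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
def test_no_perfect_ld_keeps_every_site():
    rng = np.random.default_rng(6)
    geno = rng.choice([0, 2], size=(30, 50)).astype(np.int8)
    m = _matrix_from_geno(geno)
    tags = window_prune(m)
    # random independent sites: perfect LD is possible but vanishingly rare
    assert tags.n_tags == 30
    assert tags.tag_of == {}


def test_three_identical_adjacent_sites_collapse_to_one_tag():
    rng = np.random.default_rng(7)
    base = rng.choice([0, 2], size=40).astype(np.int8)
    other = rng.choice([0, 2], size=(3, 40)).astype(np.int8)
    geno = np.vstack([base, base, base, other])
    tags = window_prune(_matrix_from_geno(geno))
    assert 0 in tags.retained
    assert tags.tag_of.get(1) == 0 and tags.tag_of.get(2) == 0


def _prune_oracle(matrix, window=50):
    """Windowed transitive closure via networkx (independent of the
    union-find implementation)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(matrix.n_sites))
    chroms = matrix.sites["chrom"].to_numpy()
    for i in range(matrix.n_sites):
        for j in range(i + 1, min(i + window, matrix.n_sites)):
            if chroms[i] != chroms[j]:
                continue
            try:
                r2, _ = compute_r2_dprime(matrix.geno[i], matrix.geno[j])
            except LDUndefinedError:
                continue
            if abs(r2 - 1.0) <= 1e-9:
                g.add_edge(i, j)
    return sorted(min(c) for c in nx.connected_components(g))


def test_pruning_matches_windowed_transitive_closure_oracle():
    """100-site chromosome with planted duplicate groups."""
    rng = np.random.default_rng(8)
    geno = rng.choice([0, 2, 1, -1], size=(100, 60), p=[0.46, 0.46, 0.04, 0.04]).astype(np.int8)
    for src, dsts in ((0, [1, 2]), (10, [15, 49]), (50, [97]), (60, [61])):
        for d in dsts:
            geno[d] = geno[src]
    m = _matrix_from_geno(geno)
    tags = window_prune(m, window=50)
    assert sorted(tags.retained.tolist()) == _prune_oracle(m, window=50)


def test_pruned_sites_have_a_perfect_ld_partner_in_their_group(small_truth):
    """Every pruned site joined its group through at least one co-windowed
    perfect-LD edge (the chain may pass through different pairwise-complete
    sample subsets, so the *direct* pruned-tag r2 can be below 1)."""
    tags = window_prune(small_truth.genotypes)
    assert tags.n_tags + len(tags.tag_of) == tags.n_input
    groups: dict = {}
    for pruned, tag in tags.tag_of.items():
        groups.setdefault(tag, [tag]).append(pruned)
    geno = small_truth.genotypes.geno
    for pruned, tag in sorted(tags.tag_of.items())[:40]:
        partners = [q for q in groups[tag] if q != pruned and abs(q - pruned) < 50]
        found = False
        for q in partners:
            try:
                r2, _ = compute_r2_dprime(geno[pruned], geno[q])
            except LDUndefinedError:
                continue
            if abs(r2 - 1.0) <= 1e-9:
                found = True
                break
        assert found, f"pruned site {pruned} has no perfect-LD partner"


# ----------------------------------------------------------------------
# decay
# ----------------------------------------------------------------------
def test_all_zero_r2_decays_in_first_bin():
    pairs = pd.DataFrame({"dist": [500, 1500, 2500], "r2": [0.0, 0.0, 0.0]})
    res = ld_decay(pairs, bin_width=1000)
    assert res.distance == 500.0 and not res.open_ended


def test_all_perfect_r2_never_decays():
    pairs = pd.DataFrame({"dist": [500, 1500], "r2": [1.0, 1.0]})
    res = ld_decay(pairs, bin_width=1000)
    assert res.open_ended and res.distance is None


def test_decay_requires_persistence_below_threshold():
    pairs = pd.DataFrame({"dist": [500, 1500, 2500], "r2": [0.1, 0.9, 0.05]})
    res = ld_decay(pairs, bin_width=1000)
    assert res.distance == 2500.0


def test_planted_block_length_recovered_within_one_bin():
    """Two-haplotype blocks of length L: mean r2(d) ~ fraction of pairs
    within one block, crossing 0.2 near 0.8 L."""
    L = 100_000
    spacing = 1000
    spec = SyntheticSpec(
        seed=21,
        n_samples=60,
        n_chromosomes=2,
        chrom_length=500_000,
        n_snp_sites=1000,
        block_size=L // spacing,
        n_common_haplotypes=2,
        n_rare_haplotypes=0,
        maf_spectrum=(0.0, 0.25, 0.25, 0.25, 0.25),
        background_het_rate=0.0,
        missing_rate=0.0,
        n_duplication_segments=0,
        sv_truth_counts={},
        n_genes=2,
        n_array_sites=10,
    )
    truth = generate_cohort(spec)
    pairs = ld_pairs(truth.genotypes, max_lag=150)
    res = ld_decay(pairs, bin_width=L // 5, threshold=0.2)
    assert not res.open_ended
    assert abs(res.distance - 0.8 * L) <= L // 5


# ----------------------------------------------------------------------
# saturation
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def sat_truth():
    spec = SyntheticSpec(
        seed=22,
        n_samples=102,
        n_chromosomes=2,
        chrom_length=800_000,
        n_snp_sites=1600,
        block_size=80,
        background_het_rate=0.0,
        missing_rate=0.0,
        n_duplication_segments=0,
        sv_truth_counts={},
        n_genes=2,
        n_array_sites=10,
    )
    return generate_cohort(spec)


def test_full_cohort_size_counts_all_segregating_sites(sat_truth):
    m = sat_truth.genotypes
    curve = saturation_analysis(m, sizes=(m.n_samples,), replicates=2, seed=0)
    assert curve.mean_variants[0] == int(m.segregating_mask().sum())


def test_single_inbred_sample_has_no_segregating_variants(sat_truth):
    curve = saturation_analysis(sat_truth.genotypes, sizes=(1,), replicates=2, seed=0)
    assert curve.mean_variants[0] == 0


def test_oversized_subset_rejected(sat_truth):
    with pytest.raises(ValueError, match="exceeds"):
        saturation_analysis(sat_truth.genotypes, sizes=(1000,), replicates=1, seed=0)


def test_saturation_monotone_and_tag_curve_plateaus_first(sat_truth):
    curve = saturation_analysis(
        sat_truth.genotypes, sizes=(12, 24, 44, 64, 84, 102), replicates=10, seed=3
    )
    assert (np.diff(curve.mean_variants) >= 0).all()
    assert (np.diff(curve.mean_tags) >= 0).all()
    # rare haplotypes carry many private variants but only one tag each, so
    # the tag curve saturates earlier than the variant curve
    i44 = curve.sizes.index(44)
    tag_frac = curve.mean_tags[i44] / curve.mean_tags[-1]
    var_frac = curve.mean_variants[i44] / curve.mean_variants[-1]
    assert tag_frac > var_frac
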