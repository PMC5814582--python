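"""Platform concordance and the leave-one-out imputation protocol."""

import numpy as np
import pandas as pd
import pytest

from svmosaic.concordance import (
    align_loci,
    compute_concordance,
    evaluate_untyped_imputation,
    impute_missing_simple,
)
from svmosaic.matrix import ABSENT, GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from svmosaic.synth import typed_subset


def _matrix(geno, samples=None, chrom="c1", ref="A", alt="G", pos0=100, provenance="wgs"):
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    samples = samples or [f"S{j}" for j in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": np.arange(pos0, pos0 + n_sites),
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
        }
    )
    return GenotypeMatrix(sites=sites, samples=samples, geno=geno, provenance=provenance)


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------
def test_disjoint_sites_give_empty_pairing_with_warning():
    a = _matrix(np.zeros((3, 2)), pos0=100)
    b = _matrix(np.zeros((3, 2)), pos0=900)
    with pytest.warns(UserWarning, match="empty pairing"):
        pair = align_loci(a, b)
    assert pair.n_sites == 0


def test_identical_matrices_pair_fully():
    g = np.array([[0, 1], [2, 0], [1, 1]])
    pair = align_loci(_matrix(g), _matrix(g))
    assert pair.n_sites == 3
    np.testing.assert_array_equal(pair.a, pair.b)


def test_swapped_ref_alt_sites_are_flipped_and_logged():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(100, 4)).astype(np.int8)
    a = _matrix(g)
    b = _matrix(g.copy())
    # plant 10 ref/alt swaps in b with mirrored codes
    swap = rng.choice(100, size=10, replace=False)
    sites = b.sites.copy()
    sites.loc[swap, ["ref", "alt"]] = ["G", "A"]
    b.sites = sites
    sub = b.geno[swap]
    sub[sub == HOM_REF] = 9
    sub[sub == HOM_ALT] = HOM_REF
    sub[sub == 9] = HOM_ALT
    b.geno[swap] = sub
    pair = align_loci(a, b)
    assert pair.n_sites == 100
    assert pair.n_flipped == 10
    np.testing.assert_array_equal(pair.a, pair.b)  # flips fully reconciled


def test_unresolvable_alleles_are_dropped(caplog):
    a = _matrix(np.zeros((2, 2)))
    b = _matrix(np.zeros((2, 2)), ref="C", alt="T")
    with caplog.at_level("WARNING"):
        pair = align_loci(a, b)
    assert pair.n_sites == 0 and len(pair.dropped) == 2
    assert "site dropped" in caplog.text


# ----------------------------------------------------------------------
# concordance
# ----------------------------------------------------------------------
def test_identical_matrices_score_perfectly():
    g = np.array([[0, 1, 2], [2, 2, 0], [1, 0, 0]])
    rep = compute_concordance(align_loci(_matrix(g), _matrix(g)))
    assert rep.overall == 1.0
    assert rep.homozygous.concordance == 1.0
    assert rep.heterozygous.concordance == 1.0


def test_planted_discordances_give_expected_rate():
    """1000 comparisons with exactly 14 planted discordances: 98.6%."""
    rng = np.random.default_rng(1)
    g = rng.integers(0, 3, size=(100, 10)).astype(np.int8)
    a = _matrix(g)
    gb = g.copy()
    flat = rng.choice(1000, size=14, replace=False)
    gb.flat[flat] = (gb.flat[flat] + 1) % 3
    b = _matrix(gb)
    rep = compute_concordance(align_loci(a, b))
    assert rep.shared == 1000
    assert rep.overall == pytest.approx(0.986)


def test_all_missing_platform_flags_no_comparable_calls():
    a = _matrix(np.zeros((5, 3)))
    b = _matrix(np.full((5, 3), MISSING))
    rep = compute_concordance(align_loci(a, b))
    assert rep.no_comparable_calls
    assert np.isnan(rep.overall)


def test_absent_code_routes_to_indel_class():
    # site 0 is an indel locus, site 1 a SNP; platform b declares both absent
    a = _matrix(np.array([[0, 2], [0, 2]]))
    sites = a.sites.copy()
    sites.loc[0, ["ref", "alt"]] = ["AT", "A"]
    a.sites = sites
    b = _matrix(np.full((2, 2), ABSENT))
    b.sites = sites.copy()
    rep = compute_concordance(align_loci(a, b))
    assert rep.indel.n == 4
    # only the true indel row counts as concordant under the surrogate rule
    assert rep.indel.concordant == 2


def test_missing_excluded_and_conserved():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
    gb = g.copy()
    gb[rng.random(gb.shape) < 0.2] = MISSING
    rep = compute_concordance(align_loci(_matrix(g), _matrix(gb)))
    assert rep.shared + rep.excluded_missing == 50 * 8
    assert rep.homozygous.n + rep.heterozygous.n + rep.indel.n == rep.shared


def test_role_swap_leaves_overall_concordance_unchanged():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(80, 6)).astype(np.int8)
    gb = g.copy()
    gb[rng.random(gb.shape) < 0.05] = rng.integers(0, 3)
    a, b = _matrix(g), _matrix(gb)
    r1 = compute_concordance(align_loci(a, b))
    r2 = compute_concordance(align_loci(b, a))
    assert r1.overall == pytest.approx(r2.overall)


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------
def _block_cohort(seed=0, n_samples=30, n_blocks=6, sites_per_block=50, n_haps=4, noise=0.0):
    """Inbred block-haplotype cohort, one block per chromosome.

    Typed 'barcode' sites at indices 0 and 10 (both kept by a stride-10
    typed subset) uniquely identify the four haplotypes of each block.
    """
    rng = np.random.default_rng(seed)
    geno = []
    chroms = []
    hap_of = np.zeros((n_blocks, n_samples), dtype=int)
    for b in range(n_blocks):
        haps = rng.integers(0, 2, size=(n_haps, sites_per_block))
        haps[:, 0] = [0, 0, 1, 1]
        if sites_per_block > 10:
            haps[:, 10] = [0, 1, 0, 1]
        else:
            haps[:, min(1, sites_per_block - 1)] = [0, 1, 0, 1]
        hap_of[b] = rng.integers(0, n_haps, size=n_samples)
        geno.append(2 * haps[hap_of[b]].T)
        chroms.extend([f"c{b:02d}"] * sites_per_block)
    geno = np.vstack(geno).astype(np.int8)
    if noise > 0:
        flip = rng.random(geno.shape) < noise
        geno[flip] = np.where(geno[flip] == 0, 2, 0)
    samples = [f"S{j}" for j in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.tile(np.arange(100, 100 + sites_per_block * 37, 37)[:sites_per_block], n_blocks),
            "ref": "A",
            "alt": "G",
        }
    )
    m = GenotypeMatrix(sites=sites, samples=samples, geno=geno, provenance="wgs")
    return m, hap_of, n_blocks, sites_per_block


def test_target_identical_to_panel_sample_is_reproduced_exactly():
    m, *_ = _block_cohort(seed=4)
    target = typed_subset(m.subset_samples([m.samples[0]]), 5)
    out = impute_missing_simple(m, target, k=3, w=20)
    np.testing.assert_array_equal(out.geno[:, 0], m.geno[:, 0])


def test_monomorphic_site_imputes_the_single_allele():
    g = np.zeros((40, 6), dtype=np.int8)
    g[:, 0] = 2  # panel sample 0 is alt everywhere; site set monomorphic otherwise
    panel = _matrix(g[:, 1:], samples=[f"P{j}" for j in range(5)])
    target = typed_subset(_matrix(g[:, :1], samples=["T0"]), 4)
    out = impute_missing_simple(panel, target, k=3, w=10)
    untyped = np.setdiff1d(np.arange(40), np.arange(0, 40, 4))
    assert (out.geno[untyped, 0] == 0).all()


def test_masking_recovery_on_block_cohort():
    m, *_ = _block_cohort(seed=5, n_samples=40)
    rng = np.random.default_rng(6)
    masked = m.copy()
    holes = rng.random(masked.geno.shape) < 0.05
    masked.geno[holes] = MISSING
    out = impute_missing_simple(m, masked, k=5, w=50)
    acc = (out.geno[holes] == m.geno[holes]).mean()
    assert acc > 0.95


def test_lowdensity_equal_to_panel_reports_undefined():
    m, *_ = _block_cohort(seed=7)
    rep = evaluate_untyped_imputation(m, m, n_permutations=2, seed=0)
    assert rep.undefined and "no untyped loci" in rep.reason


def test_too_many_permutations_rejected():
    m, *_ = _block_cohort(seed=8, n_samples=10)
    with pytest.raises(ValueError, match="permutations"):
        evaluate_untyped_imputation(m, typed_subset(m, 10), n_permutations=11, seed=0)


def test_noiseless_block_cohort_imputes_perfectly():
    m, *_ = _block_cohort(seed=9, n_samples=40)
    low = typed_subset(m, 10)  # includes each block's barcode region
    rep = evaluate_untyped_imputation(m, low, n_permutations=5, seed=1, k=5, w=10)
    assert rep.mean_accuracy == 1.0


def test_noisy_cohort_tracks_haplotype_oracle_within_two_percent():
    m, hap_of, n_blocks, spb = _block_cohort(seed=10, n_samples=60, noise=0.02)
    low = typed_subset(m, 10)
    rep = evaluate_untyped_imputation(m, low, n_permutations=5, seed=2, k=5, w=10)
    # oracle: impute from the true haplotype label; majority genotype of the
    # same-haplotype panel members at each untyped site
    rng = np.random.default_rng(2)
    chosen = rng.choice(m.samples, size=5, replace=False)
    untyped = np.setdiff1d(np.arange(m.n_sites), np.arange(0, m.n_sites, 10))
    accs = []
    for s in chosen:
        j = m.samples.index(s)
        ok = 0
        tot = 0
        for site in untyped:
            b = site // spb
            same = [jj for jj in range(m.n_samples) if jj != j and hap_of[b, jj] == hap_of[b, j]]
            if not same:
                continue
            votes = np.bincount(m.geno[site, same], minlength=3)
            pred = votes.argmax()
            ok += pred == m.geno[site, j]
            tot += 1
        accs.append(ok / tot)
    oracle = float(np.mean(accs))
    assert abs(rep.mean_accuracy - oracle) <= 0.02


def test_accuracy_degrades_with_shorter_haplotype_blocks():
    """Masking-recovery accuracy is non-increasing as block length shrinks."""
    accs = []
    for spb in (50, 10, 4):
        m, *_ = _block_cohort(seed=11, n_samples=40, sites_per_block=spb, n_blocks=300 // spb)
        low = typed_subset(m, 10)
        rep = evaluate_untyped_imputation(m, low, n_permutations=3, seed=3, k=5, w=10)
        accs.append(rep.mean_accuracy)
    assert accs[0] >= accs[1] >= accs[2] - 0.02
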