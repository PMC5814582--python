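"""Pairwise linkage disequilibrium, tag-SNP pruning and saturation curves.

Haplotype frequencies are estimated directly from homozygous genotypes —
in an essentially fully inbred cohort each homozygote is two copies of one
haplotype, so heterozygous and missing calls are simply excluded pairwise
and no EM phasing is needed.

With alleles A/a at site 1 and B/b at site 2::

    D  = p_AB - p_A * p_B
    r2 = D^2 / (p_A p_a p_B p_b)
    D' = |D| / D_max,   D_max = min(p_A p_b, p_a p_B)  if D > 0
                        D_max = min(p_A p_B, p_a p_b)  if D < 0
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, HOM_REF, HOM_ALT

#: two r2 values within this tolerance of 1 count as perfect LD
PERFECT_LD_TOL = 1e-9


class LDUndefinedError(ValueError):
    """A site is monomorphic after pairwise exclusions: LD undefined."""


def compute_r2_dprime(geno_i, geno_j):
    """(r2, D') for two genotype-code vectors (homozygotes only, pairwise)."""
    gi = np.asarray(geno_i)
    gj = np.asarray(geno_j)
    mask = ((gi == HOM_REF) | (gi == HOM_ALT)) & ((gj == HOM_REF) | (gj == HOM_ALT))
    n = int(mask.sum())
    if n == 0:
        raise LDUndefinedError("no jointly homozygous samples")
    a = gi[mask] == HOM_ALT
    b = gj[mask] == HOM_ALT
    pA = a.mean()
    pB = b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise LDUndefinedError("monomorphic site after exclusions")
    pAB = (a & b).mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return float(r2), 0.0
    return float(r2), float(abs(D) / dmax)


# ----------------------------------------------------------------------
# vectorized banded pair statistics
# ----------------------------------------------------------------------
def _banded_pair_stats(geno: np.ndarray, max_lag: int):
    """Yield (lag, r2, dprime) arrays for site pairs (i, i+lag).

    r2/dprime are NaN where LD is undefined (monomorphic after pairwise
    exclusion of non-homozygous samples).
    """
    alt = geno == HOM_ALT
    hom = (geno == HOM_REF) | alt
    n_sites = geno.shape[0]
    for lag in range(1, min(max_lag, n_sites - 1) + 1):
        v = hom[:-lag] & hom[lag:]
        n = v.sum(axis=1).astype(float)
        a = (alt[:-lag] & v).sum(axis=1)
        b = (alt[lag:] & v).sum(axis=1)
        ab = (alt[:-lag] & alt[lag:] & v).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pA = a / n
            pB = b / n
            pAB = ab / n
            D = pAB - pA * pB
            denom = pA * (1 - pA) * pB * (1 - pB)
            r2 = np.where(denom > 0, D * D / denom, np.nan)
            dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
            dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
            dmax = np.where(D > 0, dmax_pos, dmax_neg)
            dp = np.where(D == 0, 0.0, np.abs(D) / np.where(dmax > 0, dmax, np.nan))
            dp = np.where(denom > 0, dp, np.nan)
        yield lag, r2, dp


def ld_pairs(matrix: GenotypeMatrix, max_lag: int = 50, max_dist_bp: int | None = None) -> pd.DataFrame:
    """All defined LD pairs within ``max_lag`` site indices per chromosome
    (optionally also within ``max_dist_bp``)."""
    rows = []
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        g = matrix.geno[idx]
        p = pos[idx]
        for lag, r2, dp in _banded_pair_stats(g, max_lag):
            dist = p[lag:] - p[:-lag]
            ok = ~np.isnan(r2)
            if max_dist_bp is not None:
                ok &= dist <= max_dist_bp
            for i in np.flatnonzero(ok):
                rows.append(
                    (chrom, int(p[i]), int(p[i + lag]), int(dist[i]), float(r2[i]), float(dp[i]))
                )
    return pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "dist", "r2", "dprime"])


# ----------------------------------------------------------------------
# tag-SNP pruning
# ----------------------------------------------------------------------
@dataclass
class TagSNPSet:
    """Pruning result: retained site indices and pruned-site -> tag mapping."""

    retained: np.ndarray  # indices into the input matrix, sorted
    tag_of: dict  # pruned index -> retained index
    n_input: int

    @property
    def n_tags(self) -> int:
        return len(self.retained)


def window_prune(matrix: GenotypeMatrix, window: int = 50) -> TagSNPSet:
    """Sliding-window perfect-LD pruning.

    Within every window of ``window`` consecutive sites (sliding by one, so
    any pair at index distance < ``window`` is co-windowed), sites in
    perfect LD (r2 = 1 within a 1e-9 tolerance) are grouped transitively;
    the left-most site of each group is kept as its tag SNP.  Deterministic
    for a fixed input.
    """
    n = matrix.n_sites
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    chroms = matrix.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        g = matrix.geno[idx]
        for lag, r2, _dp in _banded_pair_stats(g, window - 1):
            hit = np.flatnonzero(np.abs(r2 - 1.0) <= PERFECT_LD_TOL)
            for i in hit:
                ri, rj = find(idx[i]), find(idx[i + lag])
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)  # keep left-most

    roots = np.array([find(i) for i in range(n)])
    retained = np.unique(roots)
    tag_of = {i: int(roots[i]) for i in range(n) if roots[i] != i}
    return TagSNPSet(retained=retained, tag_of=tag_of, n_input=n)


# ----------------------------------------------------------------------
# LD decay
# ----------------------------------------------------------------------
@dataclass
class LDDecayResult:
    distance: float | None  # midpoint of the first persistently-below bin
    open_ended: bool  # LD never decayed below the threshold in range
    bin_means: pd.DataFrame


def ld_decay(pairs: pd.DataFrame, bin_width: int, threshold: float = 0.2) -> LDDecayResult:
    """Distance at which binned mean r2 drops (and stays) below ``threshold``."""
    if len(pairs) == 0:
        raise ValueError("no LD pairs supplied")
    b = (pairs["dist"] // bin_width).astype(int)
    means = pairs.groupby(b)["r2"].mean().sort_index()
    frame = pd.DataFrame(
        {
            "bin_start": means.index * bin_width,
            "bin_mid": means.index * bin_width + bin_width / 2,
            "mean_r2": means.to_numpy(),
        }
    )
    below = frame["mean_r2"].to_numpy() < threshold
    # first bin below threshold with every later occupied bin also below
    ok = np.flatnonzero(below & (np.cumsum(~below[::-1])[::-1] == 0))
    if len(ok) == 0:
        return LDDecayResult(distance=None, open_ended=True, bin_means=frame)
    return LDDecayResult(distance=float(frame["bin_mid"].iloc[ok[0]]), open_ended=False, bin_means=frame)


# ----------------------------------------------------------------------
# saturation curves
# ----------------------------------------------------------------------
@dataclass
class SaturationCurve:
    sizes: list
    mean_variants: np.ndarray
    mean_tags: np.ndarray
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subset_size": self.sizes, "mean_variants": self.mean_variants, "mean_tag_snps": self.mean_tags}
        )


def saturation_analysis(
    matrix: GenotypeMatrix,
    sizes=(12, 24, 44, 64, 84, 102),
    replicates: int = 10,
    seed: int = 0,
    window: int = 50,
) -> SaturationCurve:
    """Mean segregating-variant and tag-SNP counts in random sample subsets
    of increasing size (sampling without replacement per replicate)."""
    sizes = list(sizes)
    if max(sizes) > matrix.n_samples:
        raise ValueError(f"subset size {max(sizes)} exceeds {matrix.n_samples} samples")
    rng = np.random.default_rng(seed)
    mv = np.zeros(len(sizes))
    mt = np.zeros(len(sizes))
    for si, size in enumerate(sizes):
        for _ in range(replicates):
            pick = rng.choice(matrix.samples, size=size, replace=False)
            sub = matrix.subset_samples(list(pick))
            seg = sub.segregating_mask()
            mv[si] += int(seg.sum())
            if seg.any():
                mt[si] += window_prune(sub.subset_sites(seg), window=window).n_tags
        mv[si] /= replicates
        mt[si] /= replicates
    return SaturationCurve(sizes=sizes, mean_variants=mv, mean_tags=mt, replicates=replicates, seed=seed)
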