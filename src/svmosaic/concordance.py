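"""Cross-platform genotype concordance and the leave-one-out untyped-locus
imputation-accuracy protocol.

Concordance compares genotype calls from two platforms (e.g. WGS vs array)
at shared loci, split into homozygous / heterozygous / indel classes.  The
imputation protocol removes one accession from a dense reference panel,
imputes its untyped loci from its low-density genotypes with a k-nearest-
neighbour haplotype-matching imputer, and scores the imputed calls against
the withheld dense truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING, ABSENT

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# locus alignment
# ----------------------------------------------------------------------
@dataclass
class PairedMatrix:
    """Two platforms aligned on intersected sites and samples."""

    sites: pd.DataFrame  # chrom,pos,ref,alt (platform-a alleles) + is_indel
    samples: list
    a: np.ndarray
    b: np.ndarray
    n_flipped: int
    dropped: list  # unresolvable allele mismatches

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def align_loci(a: GenotypeMatrix, b: GenotypeMatrix) -> PairedMatrix:
    """Intersect two matrices on (chrom, pos) with allele-identity checks.

    Sites with swapped ref/alt in ``b`` are reconciled by mirroring its
    codes; sites whose alleles cannot be reconciled are dropped and logged.
    """
    ka = a.sites.reset_index().set_index(["chrom", "pos"])
    kb = b.sites.reset_index().set_index(["chrom", "pos"])
    common = ka.index.intersection(kb.index)
    samples = [s for s in a.samples if s in set(b.samples)]
    if len(common) == 0 or not samples:
        warnings.warn("no shared sites/samples between platforms: empty pairing")
        return PairedMatrix(
            sites=a.sites.iloc[:0].assign(is_indel=pd.Series(dtype=bool)),
            samples=samples,
            a=np.empty((0, len(samples)), dtype=np.int8),
            b=np.empty((0, len(samples)), dtype=np.int8),
            n_flipped=0,
            dropped=[],
        )
    ia = ka.loc[common, "index"].to_numpy()
    ib = kb.loc[common, "index"].to_numpy()
    ra = a.sites["ref"].to_numpy()[ia]
    aa = a.sites["alt"].to_numpy()[ia]
    rb = b.sites["ref"].to_numpy()[ib]
    ab = b.sites["alt"].to_numpy()[ib]

    same = (ra == rb) & (aa == ab)
    swapped = (ra == ab) & (aa == rb) & ~same
    keep = same | swapped
    dropped = [
        (c, p) for (c, p), k in zip(common, keep) if not k
    ]
    for c, p in dropped:
        log.warning("unresolvable allele mismatch at %s:%s: site dropped", c, p)

    ia, ib = ia[keep], ib[keep]
    ja = [a.samples.index(s) for s in samples]
    jb = [b.samples.index(s) for s in samples]
    ga = a.geno[np.ix_(ia, ja)].copy()
    gb = b.geno[np.ix_(ib, jb)].copy()

    flip_rows = np.flatnonzero(swapped[keep])
    for r in flip_rows:
        row = gb[r]
        hr = row == HOM_REF
        ha = row == HOM_ALT
        row[hr] = HOM_ALT
        row[ha] = HOM_REF
        gb[r] = row

    sites = a.sites.iloc[ia].reset_index(drop=True).copy()
    sites["is_indel"] = [len(r) != len(x) for r, x in zip(sites["ref"], sites["alt"])]
    return PairedMatrix(
        sites=sites,
        samples=samples,
        a=ga,
        b=gb,
        n_flipped=len(flip_rows),
        dropped=dropped,
    )


# ----------------------------------------------------------------------
# concordance
# ----------------------------------------------------------------------
@dataclass
class ClassStats:
    n: int
    concordant: int

    @property
    def concordance(self) -> float:
        return self.concordant / self.n if self.n else float("nan")


@dataclass
class ConcordanceReport:
    """Shared-genotype counts and per-class concordance fractions.

    Classes follow the platform-a call (homozygous / heterozygous) with
    indel sites — and absent-on-one-platform indel surrogates — routed to
    the ``indel`` class.  ``het_either`` is the alternative heterozygous
    denominator counting comparisons heterozygous on *either* platform.
    """

    shared: int
    homozygous: ClassStats
    heterozygous: ClassStats
    indel: ClassStats
    het_either: ClassStats
    excluded_missing: int
    no_comparable_calls: bool = False

    @property
    def overall(self) -> float:
        n = self.homozygous.n + self.heterozygous.n + self.indel.n
        c = self.homozygous.concordant + self.heterozygous.concordant + self.indel.concordant
        return c / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, st in (
            ("homozygous", self.homozygous),
            ("heterozygous", self.heterozygous),
            ("indel", self.indel),
            ("het_either_platform", self.het_either),
        ):
            rows.append(
                {"class": name, "n": st.n, "concordance_pct": round(100 * st.concordance, 1) if st.n else float("nan")}
            )
        rows.append({"class": "overall", "n": self.shared, "concordance_pct": round(100 * self.overall, 1) if self.shared else float("nan")})
        return pd.DataFrame(rows)


def compute_concordance(paired: PairedMatrix) -> ConcordanceReport:
    """Score a paired matrix; missing-in-either comparisons are excluded
    from every denominator and counted separately."""
    a, b = paired.a, paired.b
    is_indel = paired.sites["is_indel"].to_numpy()[:, None] if len(paired.sites) else np.empty((0, 1), bool)
    is_indel = np.broadcast_to(is_indel, a.shape) if a.size else np.empty(a.shape, bool)

    missing = (a == MISSING) | (b == MISSING) | ((a == ABSENT) & (b == ABSENT))
    absent_one = ((a == ABSENT) ^ (b == ABSENT)) & ~missing
    comparable = ~missing

    # indel class: indel site, or an absent-on-one-platform surrogate
    indel_cls = comparable & (is_indel | absent_one)
    het_cls = comparable & ~indel_cls & ((a == HET))
    hom_cls = comparable & ~indel_cls & ~het_cls

    match = (a == b) & comparable
    # absent surrogate: concordant iff the site is an indel locus
    match = np.where(absent_one, is_indel, match)

    het_either = comparable & ~indel_cls & ((a == HET) | (b == HET))

    def _stats(mask):
        return ClassStats(n=int(mask.sum()), concordant=int((match & mask).sum()))

    shared = int(comparable.sum())
    report = ConcordanceReport(
        shared=shared,
        homozygous=_stats(hom_cls),
        heterozygous=_stats(het_cls),
        indel=_stats(indel_cls),
        het_either=_stats(het_either),
        excluded_missing=int(missing.sum()),
        no_comparable_calls=shared == 0,
    )
    return report


# ----------------------------------------------------------------------
# simple k-NN haplotype-matching imputer (documented stand-in for model-based
# imputation engines)
# ----------------------------------------------------------------------
def impute_missing_simple(
    panel: GenotypeMatrix,
    target: GenotypeMatrix,
    k: int = 5,
    w: int = 50,
) -> GenotypeMatrix:
    """Impute missing/untyped genotypes of ``target`` samples from ``panel``.

    For each genotype to impute, the ``w`` typed sites nearest to the locus
    (same chromosome) anchor a Hamming-distance ranking of panel samples;
    the ``k`` nearest panel samples vote; ties break toward the panel's
    major genotype at the locus.  Panel samples at Hamming distance zero
    (an exact local-haplotype match) take precedence over the fixed-k vote,
    so a target identical to a panel sample reproduces that sample.  Output
    covers the panel's site set with provenance ``imputed``; loci with no
    typed flanking sites stay missing.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    pk = panel.sites.reset_index().set_index(key_cols)["index"]
    tk = target.sites.reset_index().set_index(key_cols)["index"]
    common = pk.index.intersection(tk.index)
    p_idx_of_typed = pk.loc[common].to_numpy()
    t_idx_of_typed = tk.loc[common].to_numpy()

    n_sites = panel.n_sites
    out = np.full((n_sites, target.n_samples), MISSING, dtype=np.int8)
    # seed with the target's own typed calls
    out[p_idx_of_typed] = target.geno[t_idx_of_typed]

    # panel major genotype per site (tie-break)
    major = np.zeros(n_sites, dtype=np.int8)
    for code in (HOM_REF, HET, HOM_ALT):
        pass
    counts = np.stack([(panel.geno == c).sum(axis=1) for c in (HOM_REF, HET, HOM_ALT)])
    major = np.argmax(counts, axis=0).astype(np.int8)

    chroms = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy()

    for j_t in range(target.n_samples):
        typed_mask = out[:, j_t] >= 0
        for chrom in pd.unique(chroms):
            on_chrom = chroms == chrom
            typed_here = np.flatnonzero(on_chrom & typed_mask)
            to_fill = np.flatnonzero(on_chrom & ~typed_mask)
            if len(to_fill) == 0:
                continue
            if len(typed_here) == 0:
                continue  # left missing, no typed flanks on this chromosome
            t_pos = pos[typed_here]
            # window of w typed sites centred on the locus
            centre = np.searchsorted(t_pos, pos[to_fill])
            half = w // 2
            w_start = np.clip(centre - half, 0, max(0, len(typed_here) - w))
            # group loci sharing a window to vectorize distance computation
            order = np.argsort(w_start, kind="stable")
            for s in np.split(order, np.flatnonzero(np.diff(w_start[order])) + 1):
                ws = w_start[s[0]]
                win = typed_here[ws : ws + w]
                tg = out[win, j_t]
                pg = panel.geno[win]
                valid = (pg >= 0) & (tg >= 0)[:, None]
                mism = (pg != tg[:, None]) & valid
                denom = valid.sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    dist = np.where(denom > 0, mism.sum(axis=0) / denom, np.inf)
                exact = np.flatnonzero(dist == 0.0)
                nn = exact if len(exact) else np.argsort(dist, kind="stable")[:k]
                votes = panel.geno[np.ix_(to_fill[s], nn)]
                for r, site in zip(range(len(s)), to_fill[s]):
                    vv = votes[r][votes[r] >= 0]
                    if len(vv) == 0:
                        out[site, j_t] = major[site]
                        continue
                    binc = np.bincount(vv, minlength=3)
                    best = np.flatnonzero(binc == binc.max())
                    if len(best) == 1:
                        out[site, j_t] = best[0]
                    else:
                        out[site, j_t] = major[site] if major[site] in best else best[0]

    return GenotypeMatrix(
        sites=panel.sites.copy(),
        samples=list(target.samples),
        geno=out,
        provenance="imputed",
    )


# ----------------------------------------------------------------------
# leave-one-out untyped-locus protocol
# ----------------------------------------------------------------------
@dataclass
class PermutationResult:
    sample: str
    n_untyped_scored: int
    accuracy: float
    hom_stats: ClassStats
    het_stats: ClassStats


@dataclass
class ImputationReport:
    permutations: list
    undefined: bool = False
    reason: str = ""

    @property
    def mean_accuracy(self) -> float:
        if self.undefined or not self.permutations:
            return float("nan")
        return float(np.mean([p.accuracy for p in self.permutations]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": p.sample,
                "n_scored": p.n_untyped_scored,
                "accuracy_pct": round(100 * p.accuracy, 2),
                "hom_accuracy_pct": round(100 * p.hom_stats.concordance, 2) if p.hom_stats.n else float("nan"),
                "het_accuracy_pct": round(100 * p.het_stats.concordance, 2) if p.het_stats.n else float("nan"),
            }
            for p in self.permutations
        ]
        return pd.DataFrame(rows)


def evaluate_untyped_imputation(
    wgs_panel: GenotypeMatrix,
    lowdensity: GenotypeMatrix,
    n_permutations: int = 5,
    seed: int = 0,
    k: int = 5,
    w: int = 50,
) -> ImputationReport:
    """Leave-one-out accuracy at untyped loci.

    Per permutation one random accession is withheld from the dense panel;
    its untyped loci (present in the panel, absent from the low-density set)
    are imputed from its low-density genotypes and compared with the
    withheld dense truth.  Homozygous/heterozygous classing follows the
    withheld truth genotype.  Permutations sample accessions without
    replacement.
    """
    if n_permutations > wgs_panel.n_samples:
        raise ValueError("more permutations than samples")
    for s in lowdensity.samples:
        if s not in wgs_panel.samples:
            raise ValueError(f"low-density sample {s!r} absent from the dense panel")

    key_cols = ["chrom", "pos", "ref", "alt"]
    panel_keys = pd.MultiIndex.from_frame(wgs_panel.sites[key_cols])
    low_keys = pd.MultiIndex.from_frame(lowdensity.sites[key_cols])
    untyped = ~panel_keys.isin(low_keys)
    if not untyped.any():
        return ImputationReport(
            permutations=[], undefined=True, reason="no untyped loci: low-density set covers the panel"
        )

    rng = np.random.default_rng(seed)
    chosen = rng.choice(wgs_panel.samples, size=n_permutations, replace=False)

    results = []
    for s in chosen:
        keep = [x for x in wgs_panel.samples if x != s]
        panel_minus = wgs_panel.subset_samples(keep)
        target = lowdensity.subset_samples([s])
        imputed = impute_missing_simple(panel_minus, target, k=k, w=w)
        truth_col = wgs_panel.geno[:, wgs_panel.samples.index(s)]
        imp_col = imputed.geno[:, 0]
        scored = untyped & (truth_col >= 0) & (imp_col >= 0)
        ok = imp_col[scored] == truth_col[scored]
        th = truth_col[scored]
        hom = (th == HOM_REF) | (th == HOM_ALT)
        het = th == HET
        results.append(
            PermutationResult(
                sample=str(s),
                n_untyped_scored=int(scored.sum()),
                accuracy=float(ok.mean()) if scored.sum() else float("nan"),
                hom_stats=ClassStats(n=int(hom.sum()), concordant=int(ok[hom].sum())),
                het_stats=ClassStats(n=int(het.sum()), concordant=int(ok[het].sum())),
            )
        )
    return ImputationReport(permutations=results)
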