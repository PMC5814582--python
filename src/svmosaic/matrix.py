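"""Genotype matrix container shared by the concordance, LD and heterozygosity stages.

Genotypes are unphased diploid codes for an inbred cohort:

====  =========================
code  meaning
====  =========================
0     homozygous reference
1     heterozygous
2     homozygous alternative
-1    missing (``./.``)
-2    declared absent on the platform (indel surrogate on array data)
====  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1
ABSENT = -2

#: columns every ``sites`` frame must carry
SITE_COLUMNS = ("chrom", "pos", "ref", "alt")

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype codes with site metadata.

    Parameters
    ----------
    sites
        DataFrame with at least ``chrom, pos, ref, alt`` columns, one row per
        site, sorted by (chrom, pos).  ``pos`` is 1-based (VCF convention).
    samples
        Ordered sample identifiers.
    geno
        ``int8`` array of shape ``(n_sites, n_samples)`` holding the codes
        above.
    provenance
        Where the calls come from: ``wgs``, ``array``, ``gbs`` or ``imputed``.
    """

    sites: pd.DataFrame
    samples: list[str]
    geno: np.ndarray
    provenance: str = "wgs"

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype array shape {self.geno.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"sites frame lacks required column {col!r}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> pd.MultiIndex:
        """(chrom, pos, ref, alt) keys, unique per site."""
        return pd.MultiIndex.from_frame(self.sites[list(SITE_COLUMNS)])

    def copy(self) -> "GenotypeMatrix":
        return replace(self, sites=self.sites.copy(), samples=list(self.samples), geno=self.geno.copy())

    def subset_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            geno=self.geno[idx],
        )

    def subset_samples(self, names) -> "GenotypeMatrix":
        pos = [self.samples.index(n) for n in names]
        return replace(
            self,
            sites=self.sites.copy(),
            samples=list(names),
            geno=self.geno[:, pos],
        )

    # ------------------------------------------------------------------
    def het_fraction(self) -> float:
        """Genome-wide fraction of non-missing genotype calls that are heterozygous."""
        called = self.geno >= 0
        if not called.any():
            return float("nan")
        return float((self.geno == HET).sum() / called.sum())

    def alt_allele_counts(self) -> np.ndarray:
        """Per-site ALT allele count over non-missing diploid genotypes."""
        g = self.geno
        ac = np.where(g == HET, 1, 0) + np.where(g == HOM_ALT, 2, 0)
        return ac.sum(axis=1)

    def called_allele_totals(self) -> np.ndarray:
        return 2 * (self.geno >= 0).sum(axis=1)

    def maf(self) -> np.ndarray:
        """Per-site minor-allele frequency; NaN where no genotype is called."""
        ac = self.alt_allele_counts().astype(float)
        an = self.called_allele_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ac / an
            return np.where(an > 0, np.minimum(p, 1.0 - p), np.nan)

    def segregating_mask(self) -> np.ndarray:
        """True where both alleles are observed among non-missing genotypes."""
        ac = self.alt_allele_counts()
        an = self.called_allele_totals()
        return (ac > 0) & (ac < an)

    # ------------------------------------------------------------------
    def to_table(self, path) -> None:
        """Write the tab-delimited array-genotype dialect (id, chrom, pos, one column per sample)."""
        out = pd.DataFrame(
            {
                "site_id": [f"{c}_{p}" for c, p in zip(self.sites["chrom"], self.sites["pos"])],
                "chrom": self.sites["chrom"],
                "pos": self.sites["pos"],
                "ref": self.sites["ref"],
                "alt": self.sites["alt"],
            }
        )
        for j, s in enumerate(self.samples):
            out[s] = [_GT_STRINGS.get(int(g), "--") for g in self.geno[:, j]]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path, provenance: str = "array") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = ["site_id", "chrom", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta]
        rev = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT, "./.": MISSING, "--": ABSENT}
        geno = np.full((len(df), len(samples)), MISSING, dtype=np.int8)
        for j, s in enumerate(samples):
            geno[:, j] = [rev.get(v, MISSING) for v in df[s]]
        sites = df[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
        return cls(sites=sites, samples=samples, geno=geno, provenance=provenance)

    @classmethod
    def from_vcf(cls, path, provenance: str = "wgs") -> "GenotypeMatrix":
        """Load a multi-sample VCF (first ALT allele only) into a matrix."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows = []
        codes = []
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        remap = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)
        for v in vcf:
            alt = v.ALT[0] if v.ALT else "."
            rows.append((v.CHROM, v.POS, v.REF, alt))
            codes.append(remap[v.gt_types])
        vcf.close()
        sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
        geno = (
            np.vstack(codes) if codes else np.empty((0, len(samples)), dtype=np.int8)
        )
        return cls(sites=sites, samples=samples, geno=geno, provenance=provenance)
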