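"""Hard site filters for nucleotide variants and per-site allele statistics.

The six removal rules (applied in this order for the removal tally):

1. more than two alleles,
2. an allele without read support on both strands,
3. site quality (QUAL) below 32,
4. mapping quality (MQ) below 20,
5. read depth below 2,
6. minor allele frequency below 0.02.

Removal conditions are strict (< threshold), so retention thresholds are
inclusive: a site at QUAL exactly 32 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MAFUndefinedError(ValueError):
    """All genotypes missing: MAF has no denominator."""


class MissingQCFieldError(ValueError):
    """A record lacks a QC field required by the filters."""


@dataclass
class VariantRecord:
    """One nucleotide-variant site with per-sample genotypes and QC fields.

    ``genotypes`` holds per-sample allele-index pairs (``(0, 1)`` etc.) or
    ``None`` for missing.  ``allele_strand`` holds one (forward, reverse)
    support flag pair per allele (ref first), aggregated over samples.
    ``sample_depth`` is optional per-sample read depth for the per-sample
    depth mode; ``depth`` is the site-level mean (minNR basis).
    """

    chrom: str
    pos: int
    ref: str
    alts: list
    qual: float | None = None
    mq: float | None = None
    depth: float | None = None
    genotypes: list = field(default_factory=list)
    allele_strand: list = field(default_factory=list)
    sample_depth: np.ndarray | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF convention)")

    @property
    def alleles(self):
        return [self.ref] + list(self.alts)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def variant_class(self) -> str:
        """SNP (both length 1), MNP (equal lengths > 1) or indel (unequal lengths)."""
        if any(len(a) != len(self.ref) for a in self.alts):
            return "indel"
        return "SNP" if len(self.ref) == 1 else "MNP"

    def allele_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_alleles, dtype=np.int64)
        for gt in self.genotypes:
            if gt is None:
                continue
            for a in gt:
                counts[a] += 1
        return counts

    def called_alleles(self) -> set:
        out = set()
        for gt in self.genotypes:
            if gt is not None:
                out.update(gt)
        return out


def compute_maf(record: VariantRecord) -> float:
    """Minor-allele count / total called allele count (missing excluded)."""
    counts = record.allele_counts()
    total = int(counts.sum())
    if total == 0:
        raise MAFUndefinedError(f"{record.chrom}:{record.pos}: all genotypes missing")
    return float((total - counts.max()) / total)


def maf_bin(maf: float) -> int:
    """Five MAF bins, 1-based: [0,0.1), [0.1,0.2), [0.2,0.3), [0.3,0.4), [0.4,0.5]."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if maf == 0.5:
        return 5
    return int(maf * 10) + 1


@dataclass
class FilterConfig:
    """Inclusive retention thresholds for the six site filters."""

    max_alleles: int = 2
    require_both_strands: bool = True
    min_qual: float = 32.0
    min_mq: float = 20.0
    min_depth: float = 2.0
    min_maf: float = 0.02
    #: 'site' removes sites whose mean depth fails; 'sample' first masks
    #: low-depth genotypes to missing, removing the site only if nothing
    #: callable remains
    depth_mode: str = "site"

    def __post_init__(self):
        for name in ("min_qual", "min_mq", "min_depth", "min_maf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.depth_mode not in ("site", "sample"):
            raise ValueError("depth_mode must be 'site' or 'sample'")


RULE_ORDER = ("max_alleles", "strand", "qual", "mq", "depth", "maf")


def _require(record: VariantRecord, name: str):
    v = getattr(record, name)
    if v is None:
        raise MissingQCFieldError(f"{record.chrom}:{record.pos}: missing QC field {name!r}")
    return v


def _first_failing_rule(record: VariantRecord, cfg: FilterConfig):
    if record.n_alleles > cfg.max_alleles:
        return "max_alleles"
    if cfg.require_both_strands:
        if len(record.allele_strand) < record.n_alleles:
            raise MissingQCFieldError(
                f"{record.chrom}:{record.pos}: missing QC field 'allele_strand'"
            )
        for a in sorted(record.called_alleles()):
            fwd, rev = record.allele_strand[a]
            if not (fwd and rev):
                return "strand"
    if _require(record, "qual") < cfg.min_qual:
        return "qual"
    if _require(record, "mq") < cfg.min_mq:
        return "mq"
    if cfg.depth_mode == "site":
        if _require(record, "depth") < cfg.min_depth:
            return "depth"
        masked = record
    else:
        if record.sample_depth is None:
            raise MissingQCFieldError(
                f"{record.chrom}:{record.pos}: missing QC field 'sample_depth'"
            )
        gts = [
            gt if gt is not None and record.sample_depth[i] >= cfg.min_depth else None
            for i, gt in enumerate(record.genotypes)
        ]
        if all(g is None for g in gts):
            return "depth"
        masked = VariantRecord(
            chrom=record.chrom, pos=record.pos, ref=record.ref, alts=record.alts,
            qual=record.qual, mq=record.mq, depth=record.depth,
            genotypes=gts, allele_strand=record.allele_strand,
        )
    try:
        if compute_maf(masked) < cfg.min_maf:
            return "maf"
    except MAFUndefinedError:
        return "maf"
    return None


def apply_site_filters(records, cfg: FilterConfig | None = None):
    """Apply the six site filters; return (retained, per-rule removal tally).

    A removed record is tallied once, at its first failing rule in
    :data:`RULE_ORDER`.  ``retained + sum(tally.values()) == len(records)``.
    """
    cfg = cfg or FilterConfig()
    retained = []
    tally = {rule: 0 for rule in RULE_ORDER}
    for rec in records:
        rule = _first_failing_rule(rec, cfg)
        if rule is None:
            retained.append(rec)
        else:
            tally[rule] += 1
    return retained, tally


def tally_to_frame(tally: dict, n_input: int) -> pd.DataFrame:
    rows = [{"rule": r, "removed": tally.get(r, 0)} for r in RULE_ORDER]
    rows.append({"rule": "retained", "removed": n_input - sum(tally.values())})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# VCF boundary
# ----------------------------------------------------------------------
def read_vcf_records(path, saf_field: str = "SAF", sar_field: str = "SAR"):
    """Read a VCF into VariantRecords.

    Strand support is taken from per-allele INFO count fields (Number=R,
    ref first); configurable names default to a SAF/SAR-style convention.
    """
    from cyvcf2 import VCF

    def _per_allele(v, key):
        raw = v.INFO.get(key)
        if raw is None:
            return None
        if isinstance(raw, (int, float)):
            raw = (raw,)
        return [int(x) for x in raw]

    records = []
    vcf = VCF(str(path))
    for v in vcf:
        saf = _per_allele(v, saf_field)
        sar = _per_allele(v, sar_field)
        n_all = 1 + len(v.ALT)
        strand = None
        if saf is not None and sar is not None:
            strand = [(saf[i] > 0, sar[i] > 0) for i in range(min(n_all, len(saf)))]
        gts = []
        for g in v.genotypes:
            a = tuple(int(x) for x in g[:-1])
            gts.append(None if any(x < 0 for x in a) else a)
        mq = v.INFO.get("MQ")
        dp = v.INFO.get("DP")
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=list(v.ALT),
                qual=v.QUAL,
                mq=float(mq) if mq is not None else None,
                depth=float(dp) if dp is not None else None,
                genotypes=gts,
                allele_strand=strand if strand is not None else [],
            )
        )
    vcf.close()
    return records


def write_filtered_vcf(in_path, out_path, retained_records, provenance: str = "") -> None:
    """Copy the input VCF keeping only retained sites; header is preserved
    and a provenance line appended."""
    keep = {(r.chrom, r.pos) for r in retained_records}
    with open(in_path) as src, open(out_path, "w") as dst:
        for line in src:
            if line.startswith("##"):
                dst.write(line)
            elif line.startswith("#"):
                dst.write(f"##svmosaic_filter={provenance or 'site filters applied'}\n")
                dst.write(line)
            else:
                chrom, pos = line.split("\t", 2)[:2]
                if (chrom, int(pos)) in keep:
                    dst.write(line)
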