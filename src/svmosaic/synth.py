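"""Self-contained synthetic cohort with known ground truth.

The generator emulates an elite, essentially fully inbred crop cohort
resequenced at moderate depth:

* a toy reference genome with protein-coding gene models whose CDS carries a
  proper ORF (ATG ... stop), so codon-level impact classification is exact;
* a sites x samples genotype matrix with subpopulation structure, a
  block-haplotype LD architecture, a target minor-allele-frequency spectrum
  and a very low background heterozygosity;
* planted duplicated segments whose carriers show clustered artefactual
  heterozygous calls plus elevated read depth (the collapsed-duplication
  artefact);
* a structural-variant truth set and three mock caller outputs derived from
  it with per-tool false-negative rates, breakpoint jitter and false
  positives;
* an array-genotype subset of the WGS loci with planted per-class
  discordance rates.

Haplotype architecture: each chromosome is partitioned into blocks of
``block_size`` consecutive sites.  Every block has a pool of common
haplotypes plus a few low-frequency haplotypes; rare variants (MAF < 0.1)
are private to one low-frequency haplotype, so a newly sampled rare
haplotype contributes *many* new variants but only *one* new tag SNP —
the mechanism behind the tag-SNP saturation curve plateauing before the
variant curve.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genes import GeneModel, write_gff3
from .matrix import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING, ABSENT
from .svmerge import SVCall, write_bedpe

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}
#: canonical MAF bins, left-closed right-open except the last
MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


# ----------------------------------------------------------------------
# spec
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DuplicationSegment:
    """A planted duplicated segment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    carriers: tuple
    depth_multiplier: float = 2.0
    artefact_het_rate: float = 0.35
    sv_type: str = "DUP"  # DUP or CNV

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty duplication segment")
        if self.depth_multiplier < 1.5:
            raise ValueError("depth multiplier must be >= 1.5")
        if self.sv_type not in ("DUP", "CNV"):
            raise ValueError("duplication segment type must be DUP or CNV")


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one mock SV caller."""

    name: str
    fn_rate: float = 0.1
    fp_count: int = 10
    jitter_sd: float = 30.0
    cannot_call: frozenset = frozenset()
    min_size: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValueError(f"fn_rate must be in [0, 1], got {self.fn_rate}")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")

    def emits(self, sv_type: str, size: int) -> bool:
        if sv_type in self.cannot_call:
            return False
        return size >= self.min_size.get(sv_type, 0)


def default_caller_profiles():
    """Three mock callers patterned on split-read/paired-end/read-depth tools."""
    return (
        CallerProfile("splitpair", fn_rate=0.05, fp_count=8, jitter_sd=3.0,
                      cannot_call=frozenset({"TRA_inter"})),
        CallerProfile("pairedend", fn_rate=0.12, fp_count=12, jitter_sd=8.0,
                      cannot_call=frozenset({"CNV"}), min_size={"INV": 500}),
        CallerProfile("readdepth", fn_rate=0.15, fp_count=10, jitter_sd=15.0,
                      cannot_call=frozenset({"INV", "TRA_intra", "TRA_inter"})),
    )


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design at toy scale: 102 inbred samples in 5
    subpopulations, <1% background heterozygosity, ~9% missing WGS
    genotypes, a 35/20/17/14/14% MAF spectrum over the five canonical bins,
    and 20 planted duplicated segments of which 18 produce a heterozygosity
    artefact in their carriers.
    """

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_samples: int = 102
    n_subpopulations: int = 5
    n_snp_sites: int = 4000
    maf_spectrum: tuple = (0.35, 0.20, 0.17, 0.14, 0.14)
    background_het_rate: float = 0.005
    missing_rate: float = 0.09
    n_genes: int = 30
    variant_class_fractions: tuple = (0.815, 0.057, 0.128)  # SNP, MNP, indel
    # block-haplotype architecture
    block_size: int = 150
    n_common_haplotypes: int = 5
    n_rare_haplotypes: int = 1
    structure_alpha: float = 30.0
    # duplications: explicit list, or auto-generated from the knobs below
    duplication_segments: list | None = None
    n_duplication_segments: int = 20
    duplication_length: int = 30_000
    n_duplications_without_artefact: int = 2
    artefact_het_rate: float = 0.35
    depth_multiplier: float = 2.0
    # SV truth (DUP/CNV counts come from the duplication segments)
    sv_truth_counts: dict = field(
        default_factory=lambda: {"DEL": 64, "INS": 16, "INV": 8, "TRA_intra": 4, "TRA_inter": 2}
    )
    caller_profiles: tuple = field(default_factory=default_caller_profiles)
    # array subset
    n_array_sites: int = 300
    array_indel_fraction: float = 0.05
    array_error_rates: dict = field(
        default_factory=lambda: {"hom": 0.003, "het": 0.014, "indel": 0.039}
    )
    array_missing_rate: float = 0.01
    array_swap_fraction: float = 0.02
    # depth track
    depth_bin: int = 5000
    median_depth: float = 11.0

    def chrom_names(self):
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        if abs(sum(self.maf_spectrum) - 1.0) > 1e-9:
            raise ValueError("maf_spectrum weights must sum to 1")
        if not 0.0 <= self.background_het_rate < 1.0:
            raise ValueError("background_het_rate must be in [0, 1)")
        if self.duplication_segments is not None:
            segs = sorted(self.duplication_segments, key=lambda s: (s.chrom, s.start))
            for a, b in zip(segs, segs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(
                        f"overlapping duplication segments: {a.chrom}:{a.start}-{a.end} "
                        f"and {b.chrom}:{b.start}-{b.end}"
                    )
            names = set(self.chrom_names())
            for s in segs:
                if s.chrom not in names or s.start < 0 or s.end > self.chrom_length:
                    raise ValueError(f"duplication segment outside chromosome bounds: {s}")
                if s.artefact_het_rate != 0.0 and self.background_het_rate > 0 and not (
                    s.artefact_het_rate > 10 * self.background_het_rate
                ):
                    raise ValueError(
                        "artefact het rate must be 0 or exceed 10x the background rate"
                    )


# ----------------------------------------------------------------------
# truth container
# ----------------------------------------------------------------------
@dataclass
class DepthTrack:
    """Fixed-step windowed mean coverage per sample (0-based half-open bins)."""

    bin_size: int
    chrom_lengths: dict
    samples: list
    values: dict  # chrom -> array (n_bins, n_samples)

    def sample_median(self, sample: str) -> float:
        j = self.samples.index(sample)
        return float(np.median(np.concatenate([v[:, j] for v in self.values.values()])))

    def write_bedgraph_dir(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for j, s in enumerate(self.samples):
            with open(os.path.join(outdir, f"{s}.bedgraph"), "w") as fh:
                for chrom in sorted(self.values):
                    v = self.values[chrom]
                    L = self.chrom_lengths[chrom]
                    for b in range(v.shape[0]):
                        start = b * self.bin_size
                        end = min(L, start + self.bin_size)
                        fh.write(f"{chrom}\t{start}\t{end}\t{v[b, j]:.2f}\n")

    @classmethod
    def from_bedgraph_dir(cls, indir):
        samples = sorted(f[: -len(".bedgraph")] for f in os.listdir(indir) if f.endswith(".bedgraph"))
        per_chrom: dict = {}
        chrom_lengths: dict = {}
        bin_size = None
        for j, s in enumerate(samples):
            df = pd.read_csv(
                os.path.join(indir, f"{s}.bedgraph"),
                sep="\t",
                names=["chrom", "start", "end", "depth"],
            )
            if bin_size is None:
                bin_size = int((df["end"] - df["start"]).max())
            for chrom, sub in df.groupby("chrom"):
                chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), int(sub["end"].max()))
                per_chrom.setdefault(chrom, {})[s] = sub["depth"].to_numpy()
        values = {
            chrom: np.column_stack([per_chrom[chrom][s] for s in samples])
            for chrom in per_chrom
        }
        return cls(bin_size=bin_size, chrom_lengths=chrom_lengths, samples=samples, values=values)


@dataclass
class TruthSet:
    """Everything the generator knows; the ground truth for all assertions."""

    spec: SyntheticSpec
    reference: dict
    genes: list
    genotypes: GenotypeMatrix
    array: GenotypeMatrix
    duplications: list
    svs: list  # truth SVCalls, caller == 'truth'
    caller_calls: dict  # caller name -> list[SVCall]
    depth: DepthTrack
    subpop: np.ndarray  # sample -> subpopulation index
    hap_assign: dict  # block id -> array of per-sample haplotype indices
    site_block: np.ndarray  # site -> block id
    site_ld_class: np.ndarray  # site -> LD class id (perfect-LD group)
    site_hap_subset: list  # site -> tuple of ALT-carrying haplotype ids

    @property
    def samples(self):
        return self.genotypes.samples


# ----------------------------------------------------------------------
# generation helpers
# ----------------------------------------------------------------------
def _random_sequence(rng, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _coding_sequence(rng, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(BASES[rng.integers(0, 4, size=3)])
        if c not in STOP_CODONS and c != "ATG" or len(codons) == 0:
            if c not in STOP_CODONS:
                codons.append(c)
    codons.append(sorted(STOP_CODONS)[rng.integers(0, 3)])
    return "".join(codons)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _place_genes(rng, spec: SyntheticSpec, reference: dict):
    """Non-overlapping genes with exon/CDS structure; CDS written into the reference."""
    genes = []
    chroms = spec.chrom_names()
    per_chrom = [spec.n_genes // len(chroms)] * len(chroms)
    for i in range(spec.n_genes % len(chroms)):
        per_chrom[i] += 1
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        occupied = []
        tries = 0
        while n_here > 0 and tries < 2000:
            tries += 1
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(120, 400, size=n_exons)
            # trim so the CDS length is a multiple of 3
            total = int(exon_lens.sum())
            exon_lens[-1] -= total % 3
            intron_lens = rng.integers(80, 600, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            start = int(rng.integers(10_000, spec.chrom_length - span - 10_000))
            end = start + span - 1
            if any(not (end + 500 < s or start - 500 > e) for s, e in occupied):
                continue
            occupied.append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gid += 1
            g = GeneModel(
                gene_id=f"gene{gid:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                cds=list(exons),
            )
            genes.append(g)
            # write a real ORF into the reference under the CDS spans
            cds_seq = _coding_sequence(rng, g.cds_length // 3)
            if strand == "-":
                cds_seq = cds_seq[::-1].translate(_COMPLEMENT)
            off = 0
            arr = reference[chrom]
            for s, e in g.cds:
                arr[s - 1 : e] = np.array(list(cds_seq[off : off + e - s + 1]))
                off += e - s + 1
            n_here -= 1
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _bin_subset_dictionary(freqs, n_per_bin: int = 2):
    """Canonical subsets of the common haplotypes per MAF bin.

    For each non-rare bin, the ``n_per_bin`` subsets whose frequency sums are
    closest to the bin centre.  Keeping this dictionary small means sites of
    a block fall into few, well-separated perfect-LD classes, which is what
    gives tag-SNP counts their early saturation.
    """
    from itertools import combinations

    n = len(freqs)
    subsets = []
    for size in range(1, n):
        subsets.extend(combinations(range(n), size))
    sums = np.array([sum(freqs[list(s)]) for s in subsets])
    folded = np.minimum(sums, 1.0 - sums)
    out = {}
    for b, centre in enumerate((0.15, 0.25, 0.35, 0.45), start=1):
        order = np.argsort(np.abs(folded - centre), kind="stable")[:n_per_bin]
        out[b] = [tuple(subsets[i]) for i in order]
    return out


def _draw_alleles(rng, refarr, pos0: int, vclass: str):
    """(ref, alt) strings for a site at 0-based position pos0."""
    base = str(refarr[pos0])
    others = [b for b in "ACGT" if b != base]
    if vclass == "SNP":
        return base, others[rng.integers(0, 3)]
    if vclass == "MNP":
        n = int(rng.integers(2, 4))
        ref = "".join(refarr[pos0 : pos0 + n])
        alt = "".join(
            [b for b in "ACGT" if b != r][rng.integers(0, 3)] for r in ref
        )
        return ref, alt
    # indel
    n = int(rng.integers(1, 7))
    if rng.random() < 0.5:  # deletion
        ref = "".join(refarr[pos0 : pos0 + n + 1])
        return ref, ref[0]
    ins = "".join(BASES[rng.integers(0, 4, size=n)])
    return base, base + ins


# ----------------------------------------------------------------------
# main generator
# ----------------------------------------------------------------------
def generate_cohort(spec: SyntheticSpec, outdir=None) -> TruthSet:
    """Generate the full synthetic cohort; optionally emit all files under ``outdir``.

    Deterministic: the same spec (same seed) yields byte-identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chroms = spec.chrom_names()
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    subpop = np.arange(spec.n_samples) % spec.n_subpopulations

    # reference + genes
    reference = {c: _random_sequence(rng, spec.chrom_length) for c in chroms}
    genes = _place_genes(rng, spec, reference)

    # site positions (even spacing with jitter keeps them unique and sorted)
    per_chrom = [spec.n_snp_sites // len(chroms)] * len(chroms)
    for i in range(spec.n_snp_sites % len(chroms)):
        per_chrom[i] += 1
    site_chrom, site_pos = [], []
    for c, n_here in zip(chroms, per_chrom):
        spacing = (spec.chrom_length - 200) // (n_here + 1)
        base = np.arange(1, n_here + 1) * spacing + 100
        jitter = rng.integers(-spacing // 3, spacing // 3 + 1, size=n_here)
        pos = np.sort(base + jitter)
        site_chrom.extend([c] * n_here)
        site_pos.append(pos)
    site_pos = np.concatenate(site_pos)
    n_sites = len(site_pos)

    # alleles and QC fields
    classes = np.array(["SNP", "MNP", "indel"])[
        rng.choice(3, size=n_sites, p=spec.variant_class_fractions)
    ]
    refs, alts = [], []
    for i in range(n_sites):
        r, a = _draw_alleles(rng, reference[site_chrom[i]], int(site_pos[i]) - 1, classes[i])
        refs.append(r)
        alts.append(a)
    qual = np.round(np.clip(rng.normal(60, 12, n_sites), 33, None), 1)
    mq = np.round(np.clip(rng.normal(50, 4, n_sites), 20.5, None), 1)
    depth = np.clip(np.round(rng.normal(spec.median_depth, 1.5, n_sites)), 2, None).astype(np.int64)
    saf_ref = rng.poisson(depth / 4) + 1
    sar_ref = rng.poisson(depth / 4) + 1
    saf_alt = rng.poisson(depth / 4) + 1
    sar_alt = rng.poisson(depth / 4) + 1

    # block-haplotype genotypes
    geno = np.zeros((n_sites, spec.n_samples), dtype=np.int8)
    site_block = np.zeros(n_sites, dtype=np.int64)
    site_ld_class = np.zeros(n_sites, dtype=np.int64)
    site_hap_subset: list = [()] * n_sites
    hap_assign: dict = {}
    ld_class_ids: dict = {}
    n_haps = spec.n_common_haplotypes + spec.n_rare_haplotypes
    block_id = -1
    i = 0
    while i < n_sites:
        block_id += 1
        j = i
        while (
            j < n_sites
            and j - i < spec.block_size
            and site_chrom[j] == site_chrom[i]
        ):
            j += 1
        block_sites = np.arange(i, j)
        # haplotype pool frequencies
        rare = rng.uniform(0.01, 0.05, size=spec.n_rare_haplotypes)
        common = rng.dirichlet(np.full(spec.n_common_haplotypes, 3.0))
        common = common * (1.0 - rare.sum())
        subset_dict = _bin_subset_dictionary(common)
        freqs = np.concatenate([common, rare])
        # per-subpopulation perturbation (mean-preserving)
        sub_freqs = np.vstack(
            [rng.dirichlet(spec.structure_alpha * freqs) for _ in range(spec.n_subpopulations)]
        )
        hap_of = np.zeros(spec.n_samples, dtype=np.int64)
        for q in range(spec.n_subpopulations):
            members = np.flatnonzero(subpop == q)
            hap_of[members] = rng.choice(n_haps, size=len(members), p=sub_freqs[q])
        hap_assign[block_id] = hap_of
        # allele assignment per site
        for s in block_sites:
            site_block[s] = block_id
            b = int(rng.choice(5, p=spec.maf_spectrum))
            if b == 0:
                hap = spec.n_common_haplotypes + int(
                    rng.integers(0, spec.n_rare_haplotypes)
                )
                subset = (hap,)
            else:
                cands = subset_dict[b]
                subset = cands[int(rng.integers(0, len(cands)))]
            site_hap_subset[s] = subset
            key = (block_id, subset)
            if key not in ld_class_ids:
                ld_class_ids[key] = len(ld_class_ids)
            site_ld_class[s] = ld_class_ids[key]
            carrier = np.isin(hap_of, subset)
            geno[s, carrier] = HOM_ALT
        i = j

    # background heterozygosity, duplication artefacts, missingness
    if spec.background_het_rate > 0:
        geno[rng.random(geno.shape) < spec.background_het_rate] = HET

    duplications = spec.duplication_segments
    if duplications is None:
        duplications = _auto_duplications(rng, spec, samples)
    sample_index = {s: k for k, s in enumerate(samples)}
    for seg in duplications:
        if seg.artefact_het_rate <= 0:
            continue
        in_seg = np.flatnonzero(
            (np.asarray(site_chrom) == seg.chrom)
            & (site_pos - 1 >= seg.start)
            & (site_pos - 1 < seg.end)
        )
        cols = [sample_index[s] for s in seg.carriers]
        sub = geno[np.ix_(in_seg, cols)]
        sub[rng.random(sub.shape) < seg.artefact_het_rate] = HET
        geno[np.ix_(in_seg, cols)] = sub

    if spec.missing_rate > 0:
        geno[rng.random(geno.shape) < spec.missing_rate] = MISSING

    sites = pd.DataFrame(
        {
            "chrom": site_chrom,
            "pos": site_pos,
            "ref": refs,
            "alt": alts,
            "variant_class": classes,
            "qual": qual,
            "mq": mq,
            "depth": depth,
            "saf": [f"{a},{b}" for a, b in zip(saf_ref, saf_alt)],
            "sar": [f"{a},{b}" for a, b in zip(sar_ref, sar_alt)],
        }
    )
    matrix = GenotypeMatrix(sites=sites, samples=samples, geno=geno, provenance="wgs")

    # SV truth + mock callers
    svs = _truth_svs(rng, spec, duplications, samples)
    caller_calls = simulate_caller_outputs(svs, spec.caller_profiles, rng, spec)

    # depth track
    depth_track = _depth_track(rng, spec, samples, duplications, sample_index)

    # array subset with planted per-class errors
    array = _array_subset(rng, spec, matrix)

    truth = TruthSet(
        spec=spec,
        reference={c: "".join(reference[c]) for c in chroms},
        genes=genes,
        genotypes=matrix,
        array=array,
        duplications=list(duplications),
        svs=svs,
        caller_calls=caller_calls,
        depth=depth_track,
        subpop=subpop,
        hap_assign=hap_assign,
        site_block=site_block,
        site_ld_class=site_ld_class,
        site_hap_subset=site_hap_subset,
    )
    if outdir is not None:
        write_cohort(truth, outdir)
    return truth


def _auto_duplications(rng, spec: SyntheticSpec, samples):
    segs = []
    chroms = spec.chrom_names()
    occupied: dict = {c: [] for c in chroms}
    n = spec.n_duplication_segments
    for k in range(n):
        for _ in range(500):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(20_000, spec.chrom_length - spec.duplication_length - 20_000))
            end = start + spec.duplication_length
            if all(e + 50_000 < start or s - 50_000 > end for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                break
        else:  # pragma: no cover - generous genome, should not happen
            raise RuntimeError("could not place duplication segments without overlap")
        n_car = int(rng.integers(8, 21))
        carriers = tuple(sorted(rng.choice(samples, size=n_car, replace=False)))
        rate = 0.0 if k < spec.n_duplications_without_artefact else spec.artefact_het_rate
        segs.append(
            DuplicationSegment(
                chrom=chrom,
                start=start,
                end=end,
                carriers=carriers,
                depth_multiplier=spec.depth_multiplier,
                artefact_het_rate=rate,
                sv_type="DUP" if k % 2 == 0 else "CNV",
            )
        )
    return segs


_SIZE_RANGES = {
    "DEL": (100, 10_000),
    "INS": (50, 2_000),
    "INV": (200, 10_000),
    "TRA_intra": (10_000, 200_000),
    "TRA_inter": (100, 3_000),
}
#: same-type truth events are kept this far apart so that zero-noise mock
#: calls from different truth events can never satisfy the merge criteria
_TRUTH_MARGIN = 2_000


def _truth_svs(rng, spec: SyntheticSpec, duplications, samples):
    svs = []
    chroms = spec.chrom_names()
    placed: dict = {}
    tid = 0

    def _carriers():
        n_car = int(rng.integers(1, max(2, spec.n_samples // 3)))
        return frozenset(rng.choice(samples, size=n_car, replace=False))

    for seg in duplications:
        tid += 1
        svs.append(
            SVCall(
                caller="truth",
                sv_type=seg.sv_type,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                carriers=frozenset(seg.carriers),
                rd_ratio=float(np.round(rng.uniform(1.6, 2.8), 2)),
                gq=float(np.round(rng.uniform(35, 99), 1)),
                spanning_pairs=int(rng.poisson(25) + 11),
                truth_id=f"T{tid:04d}",
                call_id=f"T{tid:04d}",
            )
        )
        placed.setdefault((seg.sv_type, seg.chrom), []).append((seg.start, seg.end))

    for svt in sorted(spec.sv_truth_counts):
        count = spec.sv_truth_counts[svt]
        lo, hi = _SIZE_RANGES.get(svt, (100, 10_000))
        for _ in range(count):
            for _try in range(1000):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                if svt == "TRA_inter":
                    others = [c for c in chroms if c != chrom]
                    chrom2 = others[int(rng.integers(0, len(others)))]
                    start = int(rng.integers(10_000, spec.chrom_length - 10_000))
                    end = int(rng.integers(10_000, spec.chrom_length - 10_000))
                    key, span = (svt, chrom), (start, start + 1)
                elif svt in ("INS", "TRA_intra"):
                    start = int(rng.integers(10_000, spec.chrom_length - size - 10_000))
                    end = start + 1 if svt == "INS" else start + size
                    chrom2 = None
                    key, span = (svt, chrom), (start, end)
                else:
                    start = int(rng.integers(10_000, spec.chrom_length - size - 10_000))
                    end = start + size
                    chrom2 = None
                    key, span = (svt, chrom), (start, end)
                clear = all(
                    span[1] + _TRUTH_MARGIN < s or span[0] - _TRUTH_MARGIN > e
                    for s, e in placed.get(key, [])
                )
                if clear:
                    placed.setdefault(key, []).append(span)
                    break
            else:  # pragma: no cover
                raise RuntimeError(f"could not place {svt} truth events")
            tid += 1
            kwargs = {}
            if svt == "DEL":
                kwargs["rd_ratio"] = float(np.round(rng.uniform(0.2, 0.6), 2))
            if svt == "INV":
                kwargs["n_genotyped"] = int(0.8 * spec.n_samples)
                kwargs["n_samples_total"] = spec.n_samples
                kwargs["carrier_pair_fraction"] = float(np.round(rng.uniform(0.5, 0.9), 2))
            svs.append(
                SVCall(
                    caller="truth",
                    sv_type=svt,
                    chrom=chrom,
                    start=start,
                    end=end if svt != "INS" else start + 1,
                    chrom2=chrom2,
                    length=size if svt in ("INS", "TRA_intra", "TRA_inter") else None,
                    carriers=_carriers(),
                    gq=float(np.round(rng.uniform(35, 99), 1)),
                    spanning_pairs=int(rng.poisson(25) + 11),
                    truth_id=f"T{tid:04d}",
                    call_id=f"T{tid:04d}",
                    **kwargs,
                )
            )
    return svs


def simulate_caller_outputs(truth_svs, profiles, rng, spec: SyntheticSpec | None = None):
    """Derive per-caller call sets from the truth set.

    Each caller misses a truth event with probability ``fn_rate``, jitters
    retained breakpoints with N(0, jitter_sd) noise (type and chromosome are
    preserved), and adds ``fp_count`` false-positive calls at random
    positions.  A caller configured with ``cannot_call``/``min_size`` never
    emits those events.
    """
    out: dict = {}
    chrom_length = spec.chrom_length if spec is not None else None
    chroms = spec.chrom_names() if spec is not None else sorted({t.chrom for t in truth_svs})
    for prof in profiles:
        if not isinstance(prof, CallerProfile):
            raise TypeError("profiles must be CallerProfile instances")
        calls = []
        k = 0
        for t in truth_svs:
            if not prof.emits(t.sv_type, t.size):
                continue
            if rng.random() < prof.fn_rate:
                continue
            k += 1
            ds = int(np.round(rng.normal(0, prof.jitter_sd))) if prof.jitter_sd > 0 else 0
            de = int(np.round(rng.normal(0, prof.jitter_sd))) if prof.jitter_sd > 0 else 0
            start, end = t.start + ds, t.end + de
            if t.sv_type == "INS":
                start = max(0, start)
                end = start + 1
            elif t.sv_type in ("DEL", "DUP", "CNV", "INV"):
                start = max(0, start)
                if end <= start:
                    end = start + max(1, t.size // 2)
            calls.append(
                replace(
                    t,
                    caller=prof.name,
                    start=start,
                    end=end,
                    call_id=f"{prof.name}_{k:04d}",
                )
            )
        # false positives
        if prof.fp_count and chrom_length is not None:
            fp_types = [s for s in ("DEL", "INS", "DUP", "INV") if prof.emits(s, 10**9)]
            for _ in range(prof.fp_count):
                k += 1
                svt = fp_types[int(rng.integers(0, len(fp_types)))]
                lo, hi = _SIZE_RANGES.get(svt, (100, 10_000))
                size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(1_000, chrom_length - size - 1_000))
                calls.append(
                    SVCall(
                        caller=prof.name,
                        sv_type=svt,
                        chrom=chrom,
                        start=start,
                        end=start + 1 if svt == "INS" else start + size,
                        length=size if svt == "INS" else None,
                        gq=float(np.round(rng.uniform(35, 99), 1)),
                        spanning_pairs=int(rng.poisson(25) + 11),
                        rd_ratio=(
                            float(np.round(rng.uniform(0.2, 0.6), 2))
                            if svt == "DEL"
                            else float(np.round(rng.uniform(1.6, 2.8), 2))
                            if svt in ("DUP", "CNV")
                            else None
                        ),
                        n_genotyped=int(0.8 * (spec.n_samples if spec else 100)) if svt == "INV" else None,
                        n_samples_total=(spec.n_samples if spec else 100) if svt == "INV" else None,
                        carrier_pair_fraction=0.6 if svt == "INV" else None,
                        call_id=f"{prof.name}_fp{k:04d}",
                    )
                )
        out[prof.name] = calls
    return out


def simulate_agreement_callsets(truth_svs, agreement_rates: dict, rng):
    """Plant exact two-tool agreement rates per SV type.

    For each truth event of type ``t``: with probability ``agreement_rates[t]``
    the event is emitted by two (of three) callers, otherwise by exactly one.
    The fraction of consensus sites with support >= 2 therefore estimates the
    planted rate directly.
    """
    names = ("toolA", "toolB", "toolC")
    out = {n: [] for n in names}
    counters = {n: 0 for n in names}
    for t in truth_svs:
        p = agreement_rates.get(t.sv_type)
        if p is None:
            continue
        if rng.random() < p:
            chosen = rng.choice(3, size=2, replace=False)
        else:
            chosen = [rng.integers(0, 3)]
        for c in chosen:
            n = names[int(c)]
            counters[n] += 1
            out[n].append(replace(t, caller=n, call_id=f"{n}_{counters[n]:05d}"))
    return out


def _depth_track(rng, spec: SyntheticSpec, samples, duplications, sample_index):
    values = {}
    sample_base = np.clip(rng.normal(spec.median_depth, 1.2, size=len(samples)), 4, None)
    for chrom in spec.chrom_names():
        n_bins = int(np.ceil(spec.chrom_length / spec.depth_bin))
        v = rng.normal(sample_base, 1.0, size=(n_bins, len(samples)))
        values[chrom] = np.clip(v, 0.5, None)
    for seg in duplications:
        b0 = seg.start // spec.depth_bin
        b1 = int(np.ceil(seg.end / spec.depth_bin))
        cols = [sample_index[s] for s in seg.carriers]
        values[seg.chrom][np.ix_(range(b0, b1), cols)] *= seg.depth_multiplier
    return DepthTrack(
        bin_size=spec.depth_bin,
        chrom_lengths={c: spec.chrom_length for c in spec.chrom_names()},
        samples=list(samples),
        values={c: np.round(values[c], 2) for c in values},
    )


def _array_subset(rng, spec: SyntheticSpec, matrix: GenotypeMatrix) -> GenotypeMatrix:
    is_indel = (matrix.sites["variant_class"] == "indel").to_numpy()
    n_ind = int(round(spec.n_array_sites * spec.array_indel_fraction))
    n_snp = spec.n_array_sites - n_ind
    snp_idx = np.flatnonzero(~is_indel)
    ind_idx = np.flatnonzero(is_indel)
    pick = np.sort(
        np.concatenate(
            [
                rng.choice(snp_idx, size=min(n_snp, len(snp_idx)), replace=False),
                rng.choice(ind_idx, size=min(n_ind, len(ind_idx)), replace=False),
            ]
        )
    )
    arr = matrix.subset_sites(pick)
    arr.provenance = "array"
    g = arr.geno.copy()
    classes = arr.sites["variant_class"].to_numpy()
    err = np.empty(len(pick))
    err[:] = spec.array_error_rates["hom"]
    err[classes == "indel"] = spec.array_error_rates["indel"]
    u = rng.random(g.shape)
    # per-genotype error rate: heterozygous truth calls get the het rate
    rate = np.broadcast_to(err[:, None], g.shape).copy()
    rate[(g == HET) & (classes != "indel")[:, None]] = spec.array_error_rates["het"]
    flip = (u < rate) & (g >= 0)
    if flip.any():
        cur = g[flip]
        offs = rng.integers(1, 3, size=flip.sum())
        g[flip] = (cur + offs) % 3
    g[rng.random(g.shape) < spec.array_missing_rate] = MISSING
    # planted ref/alt swaps: allele roles flipped, codes mirrored
    swap = rng.random(len(pick)) < spec.array_swap_fraction
    if swap.any():
        s = arr.sites.copy()
        r = s.loc[swap, "ref"].copy()
        s.loc[swap, "ref"] = s.loc[swap, "alt"].to_numpy()
        s.loc[swap, "alt"] = r.to_numpy()
        arr.sites = s
        rows = np.flatnonzero(swap)
        sub = g[rows]
        sub[sub == HOM_REF] = 3
        sub[sub == HOM_ALT] = HOM_REF
        sub[sub == 3] = HOM_ALT
        g[rows] = sub
    arr.geno = g
    return arr


# ----------------------------------------------------------------------
# emission
# ----------------------------------------------------------------------
_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, extra_header_lines=()) -> None:
    """Write the cohort matrix as a VCF 4.2 with site QC INFO fields."""
    sites = matrix.sites
    has_qc = "qual" in sites.columns
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svmosaic-synth\n")
        for chrom in sorted(sites["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean read depth">\n')
        fh.write('##INFO=<ID=SAF,Number=R,Type=Integer,Description="Forward-strand allele support">\n')
        fh.write('##INFO=<ID=SAR,Number=R,Type=Integer,Description="Reverse-strand allele support">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples) + "\n")
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        ref_arr = sites["ref"].to_numpy()
        alt_arr = sites["alt"].to_numpy()
        for i in range(matrix.n_sites):
            if has_qc:
                row = sites.iloc[i]
                info = f"MQ={row['mq']};DP={row['depth']};SAF={row['saf']};SAR={row['sar']}"
                q = f"{row['qual']}"
            else:
                info, q = ".", "."
            gts = "\t".join(_GT.get(int(g), "./.") for g in matrix.geno[i])
            fh.write(
                f"{chrom_arr[i]}\t{pos_arr[i]}\t{chrom_arr[i]}_{pos_arr[i]}\t{ref_arr[i]}\t{alt_arr[i]}\t{q}\t.\t{info}\tGT\t{gts}\n"
            )


def write_fasta(reference: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cohort(truth: TruthSet, outdir) -> dict:
    """Emit every cohort file; returns {relative path: sha256}."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta(truth.reference, os.path.join(outdir, "reference.fa"))
    write_gff3(truth.genes, os.path.join(outdir, "genes.gff3"))
    write_vcf(truth.genotypes, os.path.join(outdir, "variants.vcf"))
    truth.array.to_table(os.path.join(outdir, "array.tsv"))
    calldir = os.path.join(outdir, "callers")
    os.makedirs(calldir, exist_ok=True)
    write_bedpe(truth.svs, os.path.join(outdir, "truth_svs.bedpe"))
    for name in sorted(truth.caller_calls):
        write_bedpe(truth.caller_calls[name], os.path.join(calldir, f"{name}.bedpe"))
    truth.depth.write_bedgraph_dir(os.path.join(outdir, "depth"))

    checksums = {}
    for root, _dirs, files in os.walk(outdir):
        for f in sorted(files):
            p = os.path.join(root, f)
            rel = os.path.relpath(p, outdir)
            with open(p, "rb") as fh:
                checksums[rel] = hashlib.sha256(fh.read()).hexdigest()
    return checksums


def typed_subset(matrix: GenotypeMatrix, stride: int, provenance: str = "gbs") -> GenotypeMatrix:
    """Every ``stride``-th site: a mock reduced-representation (GBS-like) marker set."""
    out = matrix.subset_sites(np.arange(0, matrix.n_sites, stride))
    out.provenance = provenance
    return out
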