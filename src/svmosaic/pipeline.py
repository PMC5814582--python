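"""End-to-end orchestration: config, staged runs, manifest and report.

A run is driven by a single declarative YAML config (every key optional
except ``outdir``); unknown keys are rejected by name.  The manifest records
parameters, stage outputs and file checksums so a run is reproducible
byte-for-byte given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_variants, summarize_spectra
from .concordance import align_loci, compute_concordance, evaluate_untyped_imputation
from .filtering import FilterConfig, apply_site_filters, read_vcf_records, tally_to_frame, write_filtered_vcf
from .hetdup import detect_het_clusters, duplication_het_concordance, window_profiles
from .ld import ld_decay, ld_pairs, saturation_analysis, window_prune
from .matrix import GenotypeMatrix
from .svgenes import annotate_catalogue
from .svmerge import SVFilterConfig, apply_raw_filters, cluster_calls, unify_and_score, write_catalogue_vcf
from .synth import SyntheticSpec, generate_cohort, typed_subset, write_vcf

log = logging.getLogger("svmosaic")

ALL_STAGES = (
    "simulate",
    "filter",
    "annotate",
    "concordance",
    "impute",
    "ld",
    "sv",
    "sv_annotate",
    "hetdup",
    "report",
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: str
    seed: int = 1
    log_level: str = "INFO"
    stages: tuple = ALL_STAGES
    synthetic: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    sv: dict = field(default_factory=dict)
    ld: dict = field(default_factory=lambda: {"max_lag": 100, "bin_width": 25_000, "threshold": 0.2, "window": 50})
    saturation: dict = field(default_factory=lambda: {"sizes": None, "replicates": 10})
    imputation: dict = field(default_factory=lambda: {"stride": 10, "n_permutations": 5, "k": 5, "w": 50})
    hetdup: dict = field(default_factory=lambda: {"window": 10_000, "step": 10_000, "min_sites": 3, "min_windows": 3, "het_threshold": 0.15, "merge_gap": 10_000})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
        sub_schemas = {
            "synthetic": {f.name for f in dataclasses.fields(SyntheticSpec)},
            "filter": {f.name for f in dataclasses.fields(FilterConfig)},
            "sv": {f.name for f in dataclasses.fields(SVFilterConfig)},
            "ld": {"max_lag", "bin_width", "threshold", "window"},
            "saturation": {"sizes", "replicates"},
            "imputation": {"stride", "n_permutations", "k", "w"},
            "hetdup": {"window", "step", "min_sites", "min_windows", "het_threshold", "merge_gap", "background_rate"},
        }
        for section, allowed in sub_schemas.items():
            for key in raw.get(section, {}) or {}:
                if key not in allowed:
                    raise ValueError(f"unknown config key: {section}.{key!r}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if isinstance(cfg.stages, str):
            cfg.stages = (cfg.stages,)
        unknown_stages = set(cfg.stages) - set(ALL_STAGES)
        if unknown_stages:
            raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest.

    The manifest (also written to ``<outdir>/manifest.json``) lists every
    output file with its checksum, the effective parameters and package
    version; a stage failure leaves a partial manifest on disk and
    re-raises.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }

    def _done(stage, files, started, **extra):
        manifest["stages"][stage] = {
            "status": "ok",
            "elapsed_s": round(time.time() - started, 2),
            "outputs": files,
            **extra,
        }
        for f in files:
            manifest["files"][f] = _sha256(os.path.join(out, f))
        _write_manifest(manifest, out)

    try:
        ctx: dict = {}
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            started = time.time()
            log.info("stage %s", stage)
            files, extra = _STAGE_FUNCS[stage](config, ctx, out)
            _done(stage, files, started, **extra)
    except Exception as exc:  # record partial state before propagating
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(manifest, out)
        raise
    return manifest


def _write_manifest(manifest, out):
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------
def _stage_simulate(config, ctx, out):
    spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
    cohort_dir = os.path.join(out, "cohort")
    truth = generate_cohort(spec, outdir=cohort_dir)
    ctx["truth"] = truth
    files = [
        os.path.join("cohort", os.path.relpath(os.path.join(r, f), cohort_dir))
        for r, _d, fs in os.walk(cohort_dir)
        for f in sorted(fs)
    ]
    return sorted(files), {"n_sites": truth.genotypes.n_sites, "n_samples": truth.genotypes.n_samples}


def _stage_filter(config, ctx, out):
    truth = ctx["truth"]
    vcf_in = os.path.join(out, "cohort", "variants.vcf")
    records = read_vcf_records(vcf_in)
    fcfg = FilterConfig(**config.filter)
    retained, tally = apply_site_filters(records, fcfg)
    ctx["retained_records"] = retained
    write_filtered_vcf(vcf_in, os.path.join(out, "filtered.vcf"), retained, provenance=f"svmosaic {__version__}")
    tally_to_frame(tally, len(records)).to_csv(os.path.join(out, "filter_tally.tsv"), sep="\t", index=False)
    return ["filtered.vcf", "filter_tally.tsv"], {"n_input": len(records), "n_retained": len(retained)}


def _stage_annotate(config, ctx, out):
    truth = ctx["truth"]
    ann = annotate_variants(
        truth.genotypes.sites, truth.genes, truth.reference,
        chrom_lengths={c: len(s) for c, s in truth.reference.items()},
    )
    ann.to_csv(os.path.join(out, "annotation.tsv"), sep="\t", index=False)
    ac = truth.genotypes.alt_allele_counts() / np.maximum(truth.genotypes.called_allele_totals(), 1)
    spectra = summarize_spectra(ann, alt_freqs=ac)
    with open(os.path.join(out, "annotation_summary.json"), "w") as fh:
        json.dump(
            {
                "context_proportions": spectra["context"].round(4).to_dict(),
                "impact_counts": spectra["impact_counts"].to_dict(),
                "n_high_impact_genes": len(spectra["high_impact_genes"]),
            },
            fh,
            indent=2,
        )
    ctx["annotation"] = ann
    return ["annotation.tsv", "annotation_summary.json"], {}


def _stage_concordance(config, ctx, out):
    truth = ctx["truth"]
    pair = align_loci(truth.genotypes, truth.array)
    report = compute_concordance(pair)
    report.to_frame().to_csv(os.path.join(out, "concordance.tsv"), sep="\t", index=False)
    ctx["concordance"] = report
    return ["concordance.tsv"], {"overall_pct": round(100 * report.overall, 2)}


def _stage_impute(config, ctx, out):
    truth = ctx["truth"]
    p = config.imputation
    low = typed_subset(truth.genotypes, int(p["stride"]))
    rep = evaluate_untyped_imputation(
        truth.genotypes, low, n_permutations=int(p["n_permutations"]),
        seed=config.seed, k=int(p["k"]), w=int(p["w"]),
    )
    rep.to_frame().to_csv(os.path.join(out, "imputation.tsv"), sep="\t", index=False)
    ctx["imputation"] = rep
    return ["imputation.tsv"], {"mean_accuracy_pct": round(100 * rep.mean_accuracy, 2)}


def _stage_ld(config, ctx, out):
    truth = ctx["truth"]
    p = config.ld
    pairs = ld_pairs(truth.genotypes, max_lag=int(p["max_lag"]))
    pairs.to_csv(os.path.join(out, "ld_pairs.tsv"), sep="\t", index=False)
    decay = ld_decay(pairs, bin_width=int(p["bin_width"]), threshold=float(p["threshold"]))
    tags = window_prune(truth.genotypes, window=int(p["window"]))
    pd.DataFrame(
        {
            "site": tags.retained,
            "chrom": truth.genotypes.sites["chrom"].to_numpy()[tags.retained],
            "pos": truth.genotypes.sites["pos"].to_numpy()[tags.retained],
        }
    ).to_csv(os.path.join(out, "tag_snps.tsv"), sep="\t", index=False)
    sizes = config.saturation.get("sizes") or _default_sizes(truth.genotypes.n_samples)
    sat = saturation_analysis(
        truth.genotypes, sizes=sizes, replicates=int(config.saturation["replicates"]),
        seed=config.seed, window=int(p["window"]),
    )
    sat.to_frame().to_csv(os.path.join(out, "saturation.tsv"), sep="\t", index=False)
    ctx["ld_decay"] = decay
    ctx["tags"] = tags
    ctx["saturation"] = sat
    return ["ld_pairs.tsv", "tag_snps.tsv", "saturation.tsv"], {
        "decay_bp": decay.distance,
        "n_tag_snps": tags.n_tags,
    }


def _default_sizes(n_samples: int):
    template = (12, 24, 44, 64, 84, 102)
    sizes = sorted({min(s, n_samples) for s in template})
    return sizes


def _stage_sv(config, ctx, out):
    truth = ctx["truth"]
    svcfg = SVFilterConfig(**config.sv)
    calls = [c for calls in truth.caller_calls.values() for c in calls]
    retained, tally = apply_raw_filters(calls, svcfg)
    sites = cluster_calls(retained, svcfg)
    catalogue, stats, summary = unify_and_score(sites)
    write_catalogue_vcf(catalogue, os.path.join(out, "sv_catalogue.vcf"))
    summary.to_csv(os.path.join(out, "sv_summary.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "sv_concordance.json"), "w") as fh:
        json.dump(
            {
                "per_type_site_rate": {k: round(v, 4) for k, v in stats.per_type_site_rate.items()},
                "per_type_call_rate": {k: round(v, 4) for k, v in stats.per_type_call_rate.items()},
                "weighted_site_rate": round(stats.weighted_site_rate, 4),
                "weighted_call_rate": round(stats.weighted_call_rate, 4),
                "raw_filter_tally": tally,
            },
            fh,
            indent=2,
        )
    ctx["catalogue"] = catalogue
    ctx["sv_stats"] = stats
    return ["sv_catalogue.vcf", "sv_summary.tsv", "sv_concordance.json"], {
        "n_unified_sites": len(catalogue)
    }


def _stage_sv_annotate(config, ctx, out):
    truth = ctx["truth"]
    table, summary = annotate_catalogue(
        ctx["catalogue"], truth.genes, chroms=list(truth.reference)
    )
    table.to_csv(os.path.join(out, "sv_gene_annotation.tsv"), sep="\t", index=False)
    summary.to_frame().to_csv(os.path.join(out, "sv_gene_summary.tsv"), sep="\t")
    ctx["sv_gene_summary"] = summary
    return ["sv_gene_annotation.tsv", "sv_gene_summary.tsv"], {}


def _stage_hetdup(config, ctx, out):
    truth = ctx["truth"]
    p = dict(config.hetdup)
    profiles = window_profiles(
        truth.genotypes, truth.depth, window=int(p["window"]), step=int(p["step"]),
        min_sites=int(p["min_sites"]),
    )
    profiles.to_csv(os.path.join(out, "window_profiles.tsv"), sep="\t", index=False)
    clusters = detect_het_clusters(
        profiles,
        het_threshold=p.get("het_threshold"),
        background_rate=p.get("background_rate", truth.spec.background_het_rate),
        min_windows=int(p["min_windows"]),
        merge_gap=int(p["merge_gap"]),
    )
    with open(os.path.join(out, "het_clusters.bed"), "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample}\t{c.mean_het:.3f}\t{c.n_windows}\n")
    dups = [s for s in ctx.get("catalogue", []) if s.sv_type in ("DUP", "CNV")]
    report = duplication_het_concordance(clusters, dups)
    report.per_call.to_csv(os.path.join(out, "hetdup_concordance.tsv"), sep="\t", index=False)
    ctx["hetdup"] = report
    return ["window_profiles.tsv", "het_clusters.bed", "hetdup_concordance.tsv"], {
        "concordance": report.fraction
    }


def _stage_report(config, ctx, out):
    make_report(out, os.path.join(out, "report.md"))
    files = ["report.md"]
    for png in ("saturation.png", "hetdup_profile.png"):
        if os.path.exists(os.path.join(out, png)):
            files.append(png)
    return files, {}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "annotate": _stage_annotate,
    "concordance": _stage_concordance,
    "impute": _stage_impute,
    "ld": _stage_ld,
    "sv": _stage_sv,
    "sv_annotate": _stage_sv_annotate,
    "hetdup": _stage_hetdup,
    "report": _stage_report,
}


# ----------------------------------------------------------------------
# report
# ----------------------------------------------------------------------
def make_report(outdir, path=None, plots: bool = True) -> str:
    """Render a Markdown summary from a run directory; idempotent.

    Every table is backed by a machine-readable TSV in the run directory;
    sections whose stage outputs are absent are marked as such.  With
    ``plots=True`` a saturation curve and a heterozygosity/depth window
    profile are rendered as PNGs next to the report.
    """
    path = path or os.path.join(outdir, "report.md")
    if plots:
        _render_plots(outdir)
    parts = ["# svmosaic run report\n"]
    manifest_path = os.path.join(outdir, "manifest.json")
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        parts.append(f"Package version {manifest.get('version')}, seed {manifest.get('seed')}.\n")

    def _table(title, fname):
        p = os.path.join(outdir, fname)
        parts.append(f"## {title}\n")
        if not os.path.exists(p):
            parts.append("_section absent: stage did not run_\n")
            return
        df = pd.read_csv(p, sep="\t")
        parts.append(df.to_markdown(index=False) + "\n")

    _table("Site-filter removal tally", "filter_tally.tsv")
    _table("Platform genotype concordance", "concordance.tsv")
    _table("Untyped-locus imputation accuracy", "imputation.tsv")
    _table("Saturation of variants and tag SNPs", "saturation.tsv")
    _table("Unified SV catalogue", "sv_summary.tsv")
    _table("SV gene-overlap summary", "sv_gene_summary.tsv")
    _table("Duplication vs heterozygosity concordance", "hetdup_concordance.tsv")
    for png, caption in (
        ("saturation.png", "Variant and tag-SNP saturation"),
        ("hetdup_profile.png", "Windowed heterozygosity and depth ratio"),
    ):
        if os.path.exists(os.path.join(outdir, png)):
            parts.append(f"## {caption}\n\n![{caption}]({png})\n")
    text = "\n".join(parts)
    with open(path, "w") as fh:
        fh.write(text)
    return text


def _render_plots(outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sat_path = os.path.join(outdir, "saturation.tsv")
    if os.path.exists(sat_path):
        sat = pd.read_csv(sat_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(sat["subset_size"], sat["mean_variants"], "o-", color="tab:blue", label="variants")
        ax.plot(sat["subset_size"], sat["mean_tag_snps"], "s-", color="tab:green", label="tag SNPs")
        ax.set_xlabel("number of samples")
        ax.set_ylabel("mean count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "saturation.png"), dpi=110)
        plt.close(fig)

    prof_path = os.path.join(outdir, "window_profiles.tsv")
    if os.path.exists(prof_path):
        prof = pd.read_csv(prof_path, sep="\t")
        informative = prof[prof["informative"].fillna(False)]
        if len(informative):
            # show the sample/chromosome with the strongest het cluster
            key = informative.groupby(["sample", "chrom"])["het_rate"].max().idxmax()
            mine = prof[(prof["sample"] == key[0]) & (prof["chrom"] == key[1])]
            fig, ax = plt.subplots(figsize=(6, 3.2))
            ax.plot(mine["start"] / 1e3, mine["het_rate"], color="tab:red", label="het rate")
            ax.set_xlabel(f"{key[1]} position (kb), sample {key[0]}")
            ax.set_ylabel("heterozygosity rate")
            if "depth_ratio" in mine.columns and mine["depth_ratio"].notna().any():
                ax2 = ax.twinx()
                ax2.plot(mine["start"] / 1e3, mine["depth_ratio"], color="tab:gray", alpha=0.7)
                ax2.set_ylabel("depth ratio")
            ax.legend(loc="upper right")
            fig.tight_layout()
            fig.savefig(os.path.join(outdir, "hetdup_profile.png"), dpi=110)
            plt.close(fig)
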