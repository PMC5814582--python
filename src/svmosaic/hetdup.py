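"""Clustered residual heterozygosity and its concordance with duplication calls.

In a fully inbred line every locus should be homozygous.  A collapsed
duplication — two diverged copies mapping onto a single-copy reference
segment — produces a *cluster* of apparently heterozygous calls together
with elevated read depth in exactly the samples carrying the extra copy.
This module computes per-sample windowed heterozygosity and depth-ratio
profiles, detects heterozygosity clusters, and scores how often
duplication/CNV calls coincide with a heterozygosity cluster in at least
one of their carrier samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, HET

#: clusters never use a relative threshold below this absolute het-rate floor
ABS_THRESHOLD_FLOOR = 0.05


def het_profile(
    matrix: GenotypeMatrix,
    window: int = 100_000,
    step: int = 50_000,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Per-sample sliding-window heterozygosity rates.

    Returns a long-format frame (sample, chrom, start, end, n_sites,
    n_called, het_rate, informative); windows with fewer than ``min_sites``
    variants are flagged uninformative.  Window coordinates are 0-based
    half-open.
    """
    if not window >= step > 0:
        raise ValueError("require window >= step > 0")
    chroms = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    rows = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos0[idx]
        g = matrix.geno[idx]
        het = np.cumsum(np.vstack([np.zeros((1, g.shape[1]), dtype=np.int64), (g == HET).astype(np.int64)]), axis=0)
        called = np.cumsum(np.vstack([np.zeros((1, g.shape[1]), dtype=np.int64), (g >= 0).astype(np.int64)]), axis=0)
        last = int(p.max()) + 1 if len(p) else 0
        for start in range(0, max(1, last), step):
            end = start + window
            j0, j1 = np.searchsorted(p, [start, end])
            n_sites = j1 - j0
            h = het[j1] - het[j0]
            c = called[j1] - called[j0]
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(c > 0, h / c, np.nan)
            for sj, sample in enumerate(matrix.samples):
                rows.append(
                    (sample, chrom, start, end, int(n_sites), int(c[sj]), float(rate[sj]), n_sites >= min_sites)
                )
            if end >= last:
                break
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_sites", "n_called", "het_rate", "informative"]
    )


def depth_ratio_profile(depth_track, window: int = 100_000, step: int = 50_000) -> pd.DataFrame:
    """Per-sample windowed depth ratio (window mean depth / sample genome-wide median)."""
    rows = []
    bs = depth_track.bin_size
    medians = {s: depth_track.sample_median(s) for s in depth_track.samples}
    for chrom in sorted(depth_track.values):
        v = depth_track.values[chrom]
        L = depth_track.chrom_lengths[chrom]
        for start in range(0, L, step):
            end = min(L, start + window)
            b0, b1 = start // bs, int(np.ceil(end / bs))
            mean_depth = v[b0:b1].mean(axis=0)
            for sj, sample in enumerate(depth_track.samples):
                rows.append(
                    (sample, chrom, start, start + window, float(mean_depth[sj] / medians[sample]))
                )
            if start + window >= L:
                break
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "depth_ratio"])


def window_profiles(matrix, depth_track=None, window=100_000, step=50_000, min_sites=3) -> pd.DataFrame:
    """Joint heterozygosity + depth-ratio window profiles."""
    prof = het_profile(matrix, window=window, step=step, min_sites=min_sites)
    if depth_track is None:
        return prof
    depth = depth_ratio_profile(depth_track, window=window, step=step)
    return prof.merge(depth, on=["sample", "chrom", "start", "end"], how="left")


@dataclass(frozen=True)
class HetCluster:
    sample: str
    chrom: str
    start: int
    end: int
    mean_het: float
    n_windows: int


def detect_het_clusters(
    profiles: pd.DataFrame,
    het_threshold: float | None = None,
    background_rate: float | None = None,
    min_windows: int = 2,
    merge_gap: int = 0,
):
    """Merge above-threshold windows into heterozygosity clusters.

    The threshold defaults to ``max(10 * background_rate, 0.05)``; passing
    ``background_rate=0`` without an absolute ``het_threshold`` is an error
    (a relative threshold of 0 would call everything).  Windows whose gaps
    are <= ``merge_gap`` bp are merged; clusters need >= ``min_windows``
    informative windows.
    """
    if het_threshold is None:
        if not background_rate:
            raise ValueError(
                "background_rate is zero/unset: an absolute het_threshold is required"
            )
        het_threshold = max(10.0 * background_rate, ABS_THRESHOLD_FLOOR)

    clusters = []
    hot = profiles[
        profiles["informative"] & (profiles["het_rate"] >= het_threshold)
    ].sort_values(["sample", "chrom", "start"])
    for (sample, chrom), grp in hot.groupby(["sample", "chrom"], sort=True):
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start"] <= cur["end"] + merge_gap:
                cur["end"] = max(cur["end"], w["end"])
                cur["rates"].append(w["het_rate"])
            else:
                if cur is not None and len(cur["rates"]) >= min_windows:
                    clusters.append(_close(cur, sample, chrom))
                cur = {"start": w["start"], "end": w["end"], "rates": [w["het_rate"]]}
        if cur is not None and len(cur["rates"]) >= min_windows:
            clusters.append(_close(cur, sample, chrom))
    return clusters


def _close(cur, sample, chrom) -> HetCluster:
    return HetCluster(
        sample=sample,
        chrom=chrom,
        start=int(cur["start"]),
        end=int(cur["end"]),
        mean_het=float(np.mean(cur["rates"])),
        n_windows=len(cur["rates"]),
    )


@dataclass
class HetDupReport:
    fraction: float | None
    per_call: pd.DataFrame
    undefined: bool = False


def duplication_het_concordance(
    clusters,
    dup_calls,
    mode: str = "call",
) -> HetDupReport:
    """Fraction of DUP/CNV calls coinciding with a carrier's het cluster.

    A call is concordant iff at least one of its carrier samples has a
    HetCluster overlapping the call interval (any overlap).  ``mode='region'``
    first merges overlapping calls on the same chromosome into regions
    (carrier sets united) and scores regions instead of calls.
    """
    dups = [c for c in dup_calls if c.sv_type in ("DUP", "CNV")]
    if mode == "region":
        dups = _merge_regions(dups)
    if not dups:
        return HetDupReport(fraction=None, per_call=pd.DataFrame(), undefined=True)

    by_sample: dict = {}
    for cl in clusters:
        by_sample.setdefault((cl.sample, cl.chrom), []).append(cl)

    rows = []
    n_conc = 0
    for c in dups:
        evidence = []
        for s in sorted(c.carriers):
            for cl in by_sample.get((s, c.chrom), []):
                if cl.start < c.end and c.start < cl.end:
                    evidence.append(f"{s}:{cl.start}-{cl.end}")
        conc = bool(evidence)
        n_conc += conc
        rows.append(
            {
                "sv_type": c.sv_type,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_carriers": len(c.carriers),
                "concordant": conc,
                "evidence": ";".join(evidence),
            }
        )
    return HetDupReport(fraction=n_conc / len(dups), per_call=pd.DataFrame(rows))


@dataclass
class _Region:
    sv_type: str
    chrom: str
    start: int
    end: int
    carriers: frozenset


def _merge_regions(dups):
    out = []
    for c in sorted(dups, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == c.chrom and c.start < out[-1].end:
            last = out[-1]
            out[-1] = _Region(
                sv_type=last.sv_type,
                chrom=last.chrom,
                start=last.start,
                end=max(last.end, c.end),
                carriers=last.carriers | c.carriers,
            )
        else:
            out.append(_Region(c.sv_type, c.chrom, c.start, c.end, frozenset(c.carriers)))
    return out
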