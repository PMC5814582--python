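"""SV-versus-gene overlap scenarios and the gene-impact summary.

Four scenarios describe how an SV touches a gene (positionally, not
strand-aware):

* ``in_gene`` — the SV lies entirely inside the gene;
* ``upstream_and_gene`` — the SV starts before the gene and ends inside it;
* ``downstream_and_gene`` — the SV starts inside the gene and ends after it;
* ``whole_gene`` — the SV covers the gene completely.

Spanned types (DEL/DUP/CNV) are compared interval-to-interval; breakpoint
types (INV/TRA) count a gene only when a breakpoint falls inside it
(``in_gene``).  Insertions are points by default (``in_gene`` or nothing);
interval semantics for insertions with a reported length are available via
``ins_as_interval``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

SCENARIOS = ("in_gene", "upstream_and_gene", "downstream_and_gene", "whole_gene")
SPANNED_TYPES = frozenset({"DEL", "DUP", "CNV"})


@dataclass(frozen=True)
class OverlapScenario:
    gene_id: str
    scenario: str


class SVGeneIndex:
    """Gene spans (0-based half-open) indexed per chromosome."""

    def __init__(self, genes, chroms=None):
        self.trees: dict = defaultdict(IntervalTree)
        self.chroms = set(chroms) if chroms is not None else set()
        for g in genes:
            self.trees[g.chrom].addi(g.start - 1, g.end, g.gene_id)
            self.chroms.add(g.chrom)

    def overlapping(self, chrom, start, end):
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} absent from the gene annotation")
        return sorted(self.trees[chrom].overlap(start, end), key=lambda iv: (iv.begin, iv.data))

    def at_point(self, chrom, pos):
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} absent from the gene annotation")
        return sorted(self.trees[chrom].at(pos), key=lambda iv: (iv.begin, iv.data))


def spanned_scenario(s0: int, s1: int, g0: int, g1: int) -> str:
    """Scenario of an SV interval [s0, s1) against a gene interval [g0, g1).

    Assumes the intervals overlap; exactly one scenario applies.
    """
    if s0 >= g0 and s1 <= g1:
        return "in_gene"
    if s0 <= g0 and s1 >= g1:
        return "whole_gene"
    if s0 < g0:
        return "upstream_and_gene"
    return "downstream_and_gene"


def classify_sv_gene_overlap(sv, index: SVGeneIndex, ins_as_interval: bool = False):
    """OverlapScenario list for one SV (ConsensusSite or SVCall-like).

    A gene completely inside an inversion without breakpoint contact gets no
    scenario (breakpoint semantics).
    """
    svt = sv.sv_type
    out = []
    if svt in SPANNED_TYPES or (svt == "INS" and ins_as_interval):
        start, end = sv.start, sv.end
        if svt == "INS" and ins_as_interval:
            end = sv.start + max(1, sv.size)
        for iv in index.overlapping(sv.chrom, start, end):
            out.append(OverlapScenario(iv.data, spanned_scenario(start, end, iv.begin, iv.end)))
        return out
    if svt == "INS":
        for iv in index.at_point(sv.chrom, sv.start):
            out.append(OverlapScenario(iv.data, "in_gene"))
        return out
    # INV / TRA: breakpoint semantics
    seen = set()
    for chrom, pos in sv.breakpoints():
        for iv in index.at_point(chrom, pos):
            if iv.data not in seen:
                seen.add(iv.data)
                out.append(OverlapScenario(iv.data, "in_gene"))
    return out


@dataclass
class SVAnnotationSummary:
    counts: pd.DataFrame  # scenario x sv_type counts
    totals: pd.Series  # per-type scenario-count totals
    sites_affecting: pd.Series  # per-type sites with >= 1 scenario
    sites_total: pd.Series
    percent_affecting: pd.Series  # one decimal

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.loc["total_scenarios"] = self.totals
        out.loc["sites_affecting_genes"] = self.sites_affecting
        out.loc["sites_total"] = self.sites_total
        out.loc["percent_affecting_genes"] = self.percent_affecting
        return out


def summarize_gene_impact(scenarios_per_sv: dict, catalogue) -> SVAnnotationSummary:
    """Per-type x per-scenario counts and gene-affecting percentages.

    ``scenarios_per_sv`` maps an index into ``catalogue`` to its scenario
    list.  An SV hitting several genes contributes every scenario to the
    counts but only once to the site-level percentage (so percentages stay
    <= 100).
    """
    types = sorted({s.sv_type for s in catalogue})
    counts = pd.DataFrame(0, index=list(SCENARIOS), columns=types, dtype=int)
    affecting = pd.Series(0, index=types, dtype=int)
    total = pd.Series(0, index=types, dtype=int)
    for i, sv in enumerate(catalogue):
        total[sv.sv_type] += 1
        scen = scenarios_per_sv.get(i, [])
        for s in scen:
            counts.loc[s.scenario, sv.sv_type] += 1
        if scen:
            affecting[sv.sv_type] += 1
    pct = (100.0 * affecting / total.where(total > 0)).round(1)
    return SVAnnotationSummary(
        counts=counts,
        totals=counts.sum(axis=0),
        sites_affecting=affecting,
        sites_total=total,
        percent_affecting=pct,
    )


def annotate_catalogue(catalogue, genes, chroms=None, ins_as_interval: bool = False):
    """Classify every site of a unified catalogue; returns (per-SV table, summary)."""
    index = SVGeneIndex(genes, chroms=chroms)
    per_sv = {}
    rows = []
    for i, sv in enumerate(catalogue):
        scen = classify_sv_gene_overlap(sv, index, ins_as_interval=ins_as_interval)
        per_sv[i] = scen
        for s in scen:
            rows.append(
                {
                    "sv_type": sv.sv_type,
                    "chrom": sv.chrom,
                    "start": sv.start,
                    "end": sv.end,
                    "gene": s.gene_id,
                    "scenario": s.scenario,
                }
            )
    table = pd.DataFrame(rows, columns=["sv_type", "chrom", "start", "end", "gene", "scenario"])
    return table, summarize_gene_impact(per_sv, catalogue)
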