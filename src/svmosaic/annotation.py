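"""Genomic-context and functional-impact classification of nucleotide variants.

A deliberately compact effect model (a small subset of what full-featured
variant annotators provide): splice sites are the canonical 2-bp intron termini;
coding changes are classified by codon translation; everything non-coding is
a ``modifier``.

Effect -> impact mapping::

    frameshift, splice_acceptor, splice_donor,
    stop_gained, start_lost, stop_lost          -> high
    missense, inframe_indel                     -> moderate
    synonymous                                  -> low
    noncoding                                   -> modifier
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genes import GeneModel, FLANK_BP

CONTEXTS = ("splice_site", "exonic", "intronic", "up_downstream", "intergenic")

EFFECT_IMPACT = {
    "frameshift": "high",
    "splice_acceptor": "high",
    "splice_donor": "high",
    "stop_gained": "high",
    "start_lost": "high",
    "stop_lost": "high",
    "missense": "moderate",
    "inframe_indel": "moderate",
    "synonymous": "low",
    "noncoding": "modifier",
}
IMPACT_SEVERITY = {"high": 0, "moderate": 1, "low": 2, "modifier": 3}


class GeneIndex:
    """Interval index over gene models for fast context lookups."""

    def __init__(self, genes, chrom_lengths: dict | None = None):
        self.genes = list(genes)
        self.chrom_lengths = chrom_lengths
        self._gene_tree: dict = defaultdict(IntervalTree)
        self._flank_tree: dict = defaultdict(IntervalTree)
        for g in self.genes:
            self._gene_tree[g.chrom].addi(g.start, g.end + 1, g)
            for lo, hi in (g.upstream_flank(), g.downstream_flank()):
                if hi >= lo:
                    self._flank_tree[g.chrom].addi(lo, hi + 1, g)

    def overlapping_genes(self, chrom: str, pos: int):
        return sorted(
            (iv.data for iv in self._gene_tree[chrom].at(pos)),
            key=lambda g: g.gene_id,
        )

    def in_flank(self, chrom: str, pos: int) -> bool:
        return bool(self._flank_tree[chrom].at(pos))


def _splice_role(gene: GeneModel, pos: int):
    """'splice_donor'/'splice_acceptor' if pos is in a canonical 2-bp intron
    terminus of this gene, else None."""
    for s, e in gene.introns():
        if e - s + 1 < 4:  # intron too short for two distinct 2-bp termini
            continue
        at_left = s <= pos <= s + 1
        at_right = e - 1 <= pos <= e
        if not (at_left or at_right):
            continue
        # donor is the 5' end of the intron in transcript orientation
        if gene.strand == "+":
            return "splice_donor" if at_left else "splice_acceptor"
        return "splice_acceptor" if at_left else "splice_donor"
    return None


def classify_context(chrom: str, pos: int, index: GeneIndex) -> str:
    """One of splice_site > exonic > intronic > up_downstream > intergenic."""
    if pos < 1:
        raise ValueError(f"position {pos} before chromosome start")
    if index.chrom_lengths is not None:
        L = index.chrom_lengths.get(chrom)
        if L is not None and pos > L:
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end {L}")
    genes = index.overlapping_genes(chrom, pos)
    if any(_splice_role(g, pos) for g in genes):
        return "splice_site"
    if any(any(s <= pos <= e for s, e in g.exons) for g in genes):
        return "exonic"
    if genes:
        return "intronic"
    if index.in_flank(chrom, pos):
        return "up_downstream"
    return "intergenic"


# ----------------------------------------------------------------------
# impact
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ImpactCall:
    effect: str
    impact: str
    gene_id: str


def classify_impact(chrom, pos, ref, alt, gene: GeneModel, reference: dict) -> ImpactCall:
    """Predicted functional effect of one variant on one gene.

    Coding substitutions are resolved by mutating the affected codon(s) of
    the spliced CDS and translating; indels in CDS are frameshift unless the
    length change is a multiple of 3; canonical 2-bp intron termini give
    splice effects; everything else is noncoding.
    """
    role = _splice_role(gene, pos)
    if role is not None:
        return ImpactCall(role, EFFECT_IMPACT[role], gene.gene_id)

    is_indel = len(ref) != len(alt)
    ref_positions = range(pos, pos + len(ref))
    offsets = [gene.cds_offset(p) for p in ref_positions]
    in_cds = [o for o in offsets if o is not None]
    if not in_cds:
        return ImpactCall("noncoding", "modifier", gene.gene_id)

    if is_indel:
        if abs(len(ref) - len(alt)) % 3 != 0:
            return ImpactCall("frameshift", "high", gene.gene_id)
        return ImpactCall("inframe_indel", "moderate", gene.gene_id)

    # SNP/MNP: substitute affected CDS offsets and compare translations of
    # the affected codons
    cds = list(gene.cds_sequence(reference))
    n_codons = len(cds) // 3
    mutated = cds.copy()
    for p, off in zip(ref_positions, offsets):
        if off is None:
            continue
        base = alt[p - pos]
        if gene.strand == "-":
            base = str(Seq(base).complement())
        mutated[off] = base
    codon_idx = sorted({o // 3 for o in in_cds if o // 3 < n_codons})
    old_aa = [str(Seq("".join(cds[3 * c : 3 * c + 3])).translate()) for c in codon_idx]
    new_aa = [str(Seq("".join(mutated[3 * c : 3 * c + 3])).translate()) for c in codon_idx]

    effect = "synonymous"
    for c, oa, na in zip(codon_idx, old_aa, new_aa):
        if na == "*" and oa != "*":
            return ImpactCall("stop_gained", "high", gene.gene_id)
    for c, oa, na in zip(codon_idx, old_aa, new_aa):
        if c == 0 and "".join(mutated[0:3]) != "ATG":
            return ImpactCall("start_lost", "high", gene.gene_id)
    for c, oa, na in zip(codon_idx, old_aa, new_aa):
        if c == n_codons - 1 and oa == "*" and na != "*":
            return ImpactCall("stop_lost", "high", gene.gene_id)
    if any(oa != na for oa, na in zip(old_aa, new_aa)):
        effect = "missense"
    return ImpactCall(effect, EFFECT_IMPACT[effect], gene.gene_id)


def annotate_variants(sites: pd.DataFrame, genes, reference: dict, chrom_lengths=None) -> pd.DataFrame:
    """Per-variant context + impact table.

    One row per variant with its single context label, plus the most severe
    impact over all genes the variant touches (all per-gene calls are kept
    in the ``gene_effects`` column).
    """
    index = GeneIndex(genes, chrom_lengths)
    rows = []
    for chrom, pos, ref, alt in zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"]):
        context = classify_context(chrom, int(pos), index)
        touched = {g.gene_id: g for g in index.overlapping_genes(chrom, int(pos))}
        # splice termini lie in introns of their gene; ensure those genes are included
        calls = [
            classify_impact(chrom, int(pos), ref, alt, g, reference)
            for g in touched.values()
        ]
        if calls:
            best = min(calls, key=lambda c: IMPACT_SEVERITY[c.impact])
        else:
            best = ImpactCall("noncoding", "modifier", "")
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "context": context,
                "effect": best.effect,
                "impact": best.impact,
                "gene": best.gene_id,
                "gene_effects": ";".join(f"{c.gene_id}:{c.effect}" for c in calls),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "context", "effect", "impact", "gene", "gene_effects"],
    )


def summarize_spectra(annotations: pd.DataFrame, alt_freqs=None, n_freq_bins: int = 5) -> dict:
    """Context proportions, impact counts, per-impact mutant (ALT) allele
    frequency histograms, and the deduplicated high-impact gene list."""
    out: dict = {}
    if len(annotations) == 0:
        out["context"] = pd.Series(dtype=float)
        out["impact_counts"] = pd.Series(dtype=int)
        out["impact_freq_hist"] = pd.DataFrame()
        out["high_impact_genes"] = []
        return out
    ctx = annotations["context"].value_counts(normalize=True)
    out["context"] = ctx
    out["impact_counts"] = annotations["impact"].value_counts()
    if alt_freqs is not None:
        freqs = np.asarray(alt_freqs, dtype=float)
        edges = np.linspace(0, 1, n_freq_bins + 1)
        hist = {}
        for impact in ("high", "moderate", "low", "modifier"):
            mask = (annotations["impact"] == impact).to_numpy()
            if mask.any():
                counts, _ = np.histogram(np.clip(freqs[mask], 0, 1), bins=edges)
                hist[impact] = counts / counts.sum()
        out["impact_freq_hist"] = pd.DataFrame(
            hist, index=[f"[{a:.1f},{b:.1f})" for a, b in zip(edges[:-1], edges[1:])]
        )
    else:
        out["impact_freq_hist"] = pd.DataFrame()
    high = annotations.loc[annotations["impact"] == "high", "gene"]
    out["high_impact_genes"] = sorted(set(g for g in high if g))
    return out
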