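"""Multi-caller structural-variant consensus: ingestion, raw-call filters,
reciprocal-overlap / breakpoint-offset clustering, and cross-tool concordance.

Internal coordinates are 0-based half-open; VCF (1-based POS, inclusive END)
is converted at the I/O boundary.  Insertions and translocations are
breakpoint events: ``start`` holds the (first) breakpoint, ``end`` the second
breakpoint (translocations) or ``start + 1`` (insertions, with the inserted
length kept in ``length``).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd
from intervaltree import IntervalTree

SV_TYPES = ("DEL", "INS", "DUP", "INV", "CNV", "TRA_intra", "TRA_inter")
#: types whose [start, end) span is a genomic interval
INTERVALLIC = frozenset({"DEL", "DUP", "CNV", "INV"})
#: types scored in the count-weighted cross-tool concordance
WEIGHTED_TYPES = ("DEL", "INS", "INV", "DUP")


@dataclass
class SVCall:
    """One caller's SV call (or a truth-set entry)."""

    caller: str
    sv_type: str
    chrom: str
    start: int
    end: int
    chrom2: str | None = None  # partner chromosome for TRA_inter
    length: int | None = None  # event length when [start, end) is not a span
    gq: float = 99.0
    spanning_pairs: int = 20
    carriers: frozenset = frozenset()
    rd_ratio: float | None = None
    n_genotyped: int | None = None  # inversion genotyping support
    n_samples_total: int | None = None
    carrier_pair_fraction: float | None = None
    truth_id: str | None = None
    call_id: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type in INTERVALLIC and not self.start < self.end:
            raise ValueError(f"{self.sv_type} requires start < end ({self.start}, {self.end})")
        if self.size <= 0:
            raise ValueError("SV length must be positive")

    @property
    def size(self) -> int:
        if self.sv_type == "INS":
            return int(self.length or 1)
        if self.sv_type in INTERVALLIC:
            return self.end - self.start
        return int(self.length or abs(self.end - self.start))

    def breakpoints(self):
        """(chrom, pos) tuples of the call's breakpoints."""
        if self.sv_type == "INS":
            return [(self.chrom, self.start)]
        if self.sv_type == "TRA_inter":
            return [(self.chrom, self.start), (self.chrom2, self.end)]
        return [(self.chrom, self.start), (self.chrom, self.end)]


@dataclass
class SVFilterConfig:
    """Raw-call filter thresholds.

    Deletions must show depleted coverage in carriers (``rd_ratio`` below
    ``rd_ratio_max_del``); duplications/CNVs must show the mirrored excess.
    Spanning-pair and genotype-quality thresholds are strict (>), matching
    the removal conditions being stated as "<=" complements.
    """

    rd_ratio_max_del: float = 0.75
    min_spanning_pairs: int = 10
    centromere_pad: int = 1000
    gap_pad: int = 50
    min_gq: float = 30.0
    ro_threshold: float = 0.80
    max_breakpoint_offset: int = 250
    inv_min_genotyped_ratio: float = 0.4
    inv_min_carrier_pair_fraction: float = 0.3
    #: 'genotyped_to_ungenotyped' (default) or 'genotyped_to_total'
    inv_ratio_mode: str = "genotyped_to_ungenotyped"

    def __post_init__(self) -> None:
        if not 0 < self.ro_threshold <= 1:
            raise ValueError("ro_threshold must be in (0, 1]")
        if self.centromere_pad < 0 or self.gap_pad < 0:
            raise ValueError("pads must be >= 0")

    @property
    def rd_ratio_min_dup(self) -> float:
        return 1.0 / self.rd_ratio_max_del


@dataclass
class ConsensusSite:
    """A merged multi-tool SV site (connected component of matching calls)."""

    sv_type: str
    chrom: str
    start: int
    end: int
    chrom2: str | None
    members: list
    tools: frozenset
    precision: int  # max breakpoint offset of any member from the representative

    @property
    def support(self) -> int:
        return len(self.tools)

    @property
    def size(self) -> int:
        if self.sv_type == "INS":
            lens = sorted(m.size for m in self.members)
            return lens[(len(lens) - 1) // 2]
        return abs(self.end - self.start)

    @property
    def carriers(self) -> frozenset:
        out = frozenset()
        for m in self.members:
            out = out | m.carriers
        return out

    def breakpoints(self):
        if self.sv_type == "INS":
            return [(self.chrom, self.start)]
        if self.sv_type == "TRA_inter":
            return [(self.chrom, self.start), (self.chrom2, self.end)]
        return [(self.chrom, self.start), (self.chrom, self.end)]


# ----------------------------------------------------------------------
# ingestion
# ----------------------------------------------------------------------
_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tstrand1\tstrand2\ttags\n"
)


def write_bedpe(calls, path) -> None:
    """Emit calls as 10-column BEDPE plus a key=value tag column."""
    with open(path, "w") as fh:
        fh.write(_BEDPE_HEADER)
        for c in calls:
            if c.sv_type == "INS":
                b1 = (c.chrom, c.start, c.start + 1)
                b2 = b1
            elif c.sv_type == "TRA_inter":
                b1 = (c.chrom, c.start, c.start + 1)
                b2 = (c.chrom2, c.end, c.end + 1)
            else:
                b1 = (c.chrom, c.start, c.start + 1)
                b2 = (c.chrom, c.end - 1 if c.sv_type in INTERVALLIC else c.end, c.end if c.sv_type in INTERVALLIC else c.end + 1)
            tags = [f"TYPE={c.sv_type}", f"LEN={c.size}", f"GQ={c.gq:g}", f"PE={c.spanning_pairs}"]
            if c.rd_ratio is not None:
                tags.append(f"RD={c.rd_ratio:g}")
            if c.carriers:
                tags.append("CARRIERS=" + ",".join(sorted(c.carriers)))
            if c.truth_id is not None:
                tags.append(f"TRUTH={c.truth_id}")
            fh.write(
                f"{b1[0]}\t{b1[1]}\t{b1[2]}\t{b2[0]}\t{b2[1]}\t{b2[2]}\t"
                f"{c.call_id or '.'}\t{c.gq:g}\t+\t+\t" + ";".join(tags) + "\n"
            )


def _parse_tags(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def ingest_callset(path, caller: str, dialect: str = "bedpe"):
    """Read one caller's output into SVCall objects (internal coordinates).

    ``dialect`` is ``bedpe`` (10+1 columns, TYPE tag) or ``vcf_svtype``
    (SVTYPE/END/SVLEN INFO keys).  Records with an unknown SVTYPE are skipped;
    malformed lines raise with the line number.
    """
    if dialect == "bedpe":
        return _ingest_bedpe(path, caller)
    if dialect == "vcf_svtype":
        return _ingest_vcf(path, caller)
    raise ValueError(f"unknown dialect {dialect!r}")


def _ingest_bedpe(path, caller):
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ValueError(f"{path}:{ln}: expected >= 11 BEDPE columns, got {len(f)}")
            try:
                c1, s1 = f[0], int(f[1])
                c2, s2 = f[3], int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
            tags = _parse_tags(f[10])
            svt = tags.get("TYPE")
            if svt is None and c1 != c2:
                svt = "TRA_inter"
            if svt not in SV_TYPES:
                continue  # unknown type: skip
            length = int(tags["LEN"]) if "LEN" in tags else None
            if svt == "INS":
                start, end = s1, s1 + 1
            elif svt == "TRA_inter":
                start, end = s1, s2
            elif svt == "TRA_intra":
                start, end = s1, s2
            else:
                start, end = s1, int(f[5])
            calls.append(
                SVCall(
                    caller=caller,
                    sv_type=svt,
                    chrom=c1,
                    start=start,
                    end=end,
                    chrom2=c2 if svt == "TRA_inter" else None,
                    length=length,
                    gq=float(tags.get("GQ", f[7] if f[7] != "." else 99)),
                    spanning_pairs=int(tags.get("PE", 20)),
                    carriers=frozenset(tags["CARRIERS"].split(",")) if tags.get("CARRIERS") else frozenset(),
                    rd_ratio=float(tags["RD"]) if "RD" in tags else None,
                    truth_id=tags.get("TRUTH"),
                    call_id=f[6] if f[6] != "." else None,
                )
            )
    return calls


def _ingest_vcf(path, caller):
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{ln}: truncated VCF record")
            info = _parse_tags(f[7].replace(";", ";"))
            svt = info.get("SVTYPE")
            if svt == "TRA":
                svt = "TRA_inter" if info.get("CHR2") not in (None, f[0]) else "TRA_intra"
            if svt not in SV_TYPES:
                continue
            try:
                pos = int(f[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed POS") from exc
            start = pos - 1
            end = int(info["END"]) if "END" in info else start + 1
            length = abs(int(info["SVLEN"])) if "SVLEN" in info else None
            if svt == "INS":
                start, end = start, start + 1
            calls.append(
                SVCall(
                    caller=caller,
                    sv_type=svt,
                    chrom=f[0],
                    start=start,
                    end=end,
                    chrom2=info.get("CHR2") if svt == "TRA_inter" else None,
                    length=length,
                    gq=float(info.get("GQ", 99)),
                    spanning_pairs=int(info.get("PE", 20)),
                    carriers=frozenset(info["CARRIERS"].split(",")) if info.get("CARRIERS") else frozenset(),
                    rd_ratio=float(info["RD"]) if "RD" in info else None,
                    truth_id=info.get("TRUTH"),
                    call_id=f[2] if f[2] != "." else None,
                )
            )
    return calls


def write_callset_vcf(calls, path) -> None:
    """Emit calls in the SVTYPE/END VCF dialect (sites only, no genotypes)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=PE,Number=1,Type=Integer,Description="Spanning read pairs">\n')
        fh.write('##INFO=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">\n')
        fh.write('##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome">\n')
        fh.write('##INFO=<ID=RD,Number=1,Type=Float,Description="Read-depth ratio">\n')
        fh.write('##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Carrier samples">\n')
        fh.write('##INFO=<ID=TRUTH,Number=1,Type=String,Description="Truth id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = [f"SVTYPE={'TRA' if c.sv_type.startswith('TRA') else c.sv_type}"]
            info.append(f"END={c.end}")
            info.append(f"SVLEN={c.size}")
            info.append(f"PE={c.spanning_pairs}")
            info.append(f"GQ={c.gq:g}")
            if c.sv_type == "TRA_inter":
                info.append(f"CHR2={c.chrom2}")
            elif c.sv_type == "TRA_intra":
                info.append(f"CHR2={c.chrom}")
            if c.rd_ratio is not None:
                info.append(f"RD={c.rd_ratio:g}")
            if c.carriers:
                info.append("CARRIERS=" + ",".join(sorted(c.carriers)))
            if c.truth_id is not None:
                info.append(f"TRUTH={c.truth_id}")
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t{c.call_id or '.'}\tN\t<{'TRA' if c.sv_type.startswith('TRA') else c.sv_type}>\t.\t.\t"
                + ";".join(info)
                + "\n"
            )


# ----------------------------------------------------------------------
# raw-call filters
# ----------------------------------------------------------------------
RULE_ORDER = (
    "rd_ratio",
    "spanning_pairs",
    "centromere",
    "gap",
    "gq",
    "inv_genotyped_ratio",
    "inv_carrier_pairs",
    "tra_syntenic",
    "rd_unevaluable",
)


def _mask_tree(regions, pad: int) -> dict:
    trees: dict = defaultdict(IntervalTree)
    for chrom, start, end in regions:
        trees[chrom].addi(max(0, start - pad), end + pad)
    return trees


def _hits_mask(call: SVCall, trees: dict) -> bool:
    for chrom, pos in call.breakpoints():
        t = trees.get(chrom)
        if t is not None and t.overlaps_point(pos):
            return True
    return False


def apply_raw_filters(calls, cfg: SVFilterConfig, centromeres=(), gaps=(), syntenic=()):
    """Apply the raw-call filters; return (retained, per-rule removal tally).

    Mask arguments are iterables of 0-based half-open (chrom, start, end)
    intervals.  A removed call is tallied once, at the first failing rule in
    :data:`RULE_ORDER`.  DEL/DUP/CNV calls without an ``rd_ratio`` cannot be
    evaluated and are tallied under ``rd_unevaluable``.
    """
    cent = _mask_tree(centromeres, cfg.centromere_pad)
    gap = _mask_tree(gaps, cfg.gap_pad)
    syn = _mask_tree(syntenic, 0)

    retained = []
    tally = Counter()
    for c in calls:
        rule = _first_failing_rule(c, cfg, cent, gap, syn)
        if rule is None:
            retained.append(c)
        else:
            tally[rule] += 1
    return retained, dict(tally)


def _first_failing_rule(c: SVCall, cfg: SVFilterConfig, cent, gap, syn):
    if c.sv_type in ("DEL", "DUP", "CNV"):
        if c.rd_ratio is None:
            return "rd_unevaluable"
        if c.sv_type == "DEL" and not c.rd_ratio < cfg.rd_ratio_max_del:
            return "rd_ratio"
        if c.sv_type in ("DUP", "CNV") and not c.rd_ratio > cfg.rd_ratio_min_dup:
            return "rd_ratio"
    if not c.spanning_pairs > cfg.min_spanning_pairs:
        return "spanning_pairs"
    if _hits_mask(c, cent):
        return "centromere"
    if _hits_mask(c, gap):
        return "gap"
    if not c.gq > cfg.min_gq:
        return "gq"
    if c.sv_type == "INV":
        if c.n_genotyped is not None and c.n_samples_total is not None:
            n_un = c.n_samples_total - c.n_genotyped
            if cfg.inv_ratio_mode == "genotyped_to_total":
                ratio = c.n_genotyped / c.n_samples_total if c.n_samples_total else 0.0
            else:
                ratio = c.n_genotyped / n_un if n_un > 0 else math.inf
            if not ratio > cfg.inv_min_genotyped_ratio:
                return "inv_genotyped_ratio"
        if c.carrier_pair_fraction is not None and not c.carrier_pair_fraction > cfg.inv_min_carrier_pair_fraction:
            return "inv_carrier_pairs"
    if c.sv_type.startswith("TRA") and _hits_mask(c, syn):
        return "tra_syntenic"
    return None


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
def reciprocal_overlap(a, b) -> float:
    """RO of two 0-based half-open intervals on the same chromosome.

    RO = overlap length / max(len_a, len_b) = min(overlap/len_a, overlap/len_b).
    """
    (a0, a1), (b0, b1) = a, b
    la, lb = a1 - a0, b1 - b0
    if la <= 0 or lb <= 0:
        raise ValueError("zero-length interval")
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return ov / max(la, lb)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def calls_match(a: SVCall, b: SVCall, cfg: SVFilterConfig) -> bool:
    """True iff two same-type, same-chromosome calls satisfy the merge criteria."""
    if a.sv_type != b.sv_type or a.chrom != b.chrom or a.chrom2 != b.chrom2:
        return False
    off = cfg.max_breakpoint_offset
    if abs(a.start - b.start) > off or abs(a.end - b.end) > off:
        return False
    if a.sv_type in INTERVALLIC:
        return reciprocal_overlap((a.start, a.end), (b.start, b.end)) >= cfg.ro_threshold
    return True


def _lower_median(vals) -> int:
    s = sorted(vals)
    return s[(len(s) - 1) // 2]


def cluster_calls(calls, cfg: SVFilterConfig | None = None):
    """Single-linkage clustering of calls into ConsensusSites.

    Calls are grouped by (type, chromosome [pair]); within a group an edge
    joins two calls iff they satisfy :func:`calls_match`; connected
    components become sites.  Deterministic and invariant to input order.
    """
    cfg = cfg or SVFilterConfig()
    groups: dict = defaultdict(list)
    for c in calls:
        groups[(c.sv_type, c.chrom, c.chrom2 or "")].append(c)

    sites = []
    for key in sorted(groups):
        members = sorted(
            groups[key], key=lambda c: (c.start, c.end, c.caller, c.call_id or "")
        )
        n = len(members)
        uf = _UnionFind(n)
        off = cfg.max_breakpoint_offset
        for i in range(n):
            for j in range(i + 1, n):
                if members[j].start - members[i].start > off:
                    break  # sorted by start: no further j can match
                if calls_match(members[i], members[j], cfg):
                    uf.union(i, j)
        comps: dict = defaultdict(list)
        for i in range(n):
            comps[uf.find(i)].append(members[i])
        for root in sorted(comps):
            ms = comps[root]
            rep_s = _lower_median([m.start for m in ms])
            rep_e = _lower_median([m.end for m in ms])
            prec = max(
                max(abs(m.start - rep_s), abs(m.end - rep_e)) for m in ms
            )
            sites.append(
                ConsensusSite(
                    sv_type=key[0],
                    chrom=key[1],
                    start=rep_s,
                    end=rep_e,
                    chrom2=key[2] or None,
                    members=ms,
                    tools=frozenset(m.caller for m in ms),
                    precision=prec,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.sv_type, s.chrom2 or ""))
    return sites


# ----------------------------------------------------------------------
# unification and concordance scoring
# ----------------------------------------------------------------------
@dataclass
class ConcordanceStats:
    """Cross-tool agreement, per SV type and count-weighted.

    ``call_rate``: fraction of individual calls that ended up in a >= 2-tool
    component.  ``site_rate``: fraction of consensus sites supported by >= 2
    tools — the per-SV statement usually quoted when saying "X% of SVs were
    called by at least two tools".
    """

    per_type_call_rate: dict
    per_type_site_rate: dict
    weighted_call_rate: float
    weighted_site_rate: float
    per_type_call_counts: dict
    per_type_site_counts: dict


def unify_and_score(sites, weight_types=WEIGHTED_TYPES, min_support: int = 2):
    """Build the >= min_support unified catalogue and cross-tool concordance.

    Returns ``(catalogue, stats, summary)`` where ``summary`` is a
    per-type DataFrame (site count, size range, median size, breakpoint
    precision) over the unified catalogue.
    """
    catalogue = [s for s in sites if s.support >= min_support]

    call_counts: Counter = Counter()
    call_hits: Counter = Counter()
    site_counts: Counter = Counter()
    site_hits: Counter = Counter()
    for s in sites:
        site_counts[s.sv_type] += 1
        if s.support >= 2:
            site_hits[s.sv_type] += 1
        call_counts[s.sv_type] += len(s.members)
        if s.support >= 2:
            call_hits[s.sv_type] += len(s.members)

    per_call = {t: call_hits[t] / call_counts[t] for t in call_counts}
    per_site = {t: site_hits[t] / site_counts[t] for t in site_counts}

    def _weighted(rates, weights):
        ts = [t for t in weight_types if t in rates and weights[t] > 0]
        tot = sum(weights[t] for t in ts)
        if tot == 0:
            return float("nan")
        return sum(rates[t] * weights[t] for t in ts) / tot

    stats = ConcordanceStats(
        per_type_call_rate=per_call,
        per_type_site_rate=per_site,
        weighted_call_rate=_weighted(per_call, call_counts),
        weighted_site_rate=_weighted(per_site, site_counts),
        per_type_call_counts=dict(call_counts),
        per_type_site_counts=dict(site_counts),
    )

    rows = []
    for t in SV_TYPES:
        of_type = [s for s in catalogue if s.sv_type == t]
        if not of_type:
            continue  # omitted row, never zero-division
        sizes = sorted(s.size for s in of_type)
        rows.append(
            {
                "sv_type": t,
                "n_sites": len(of_type),
                "min_size": sizes[0],
                "max_size": sizes[-1],
                "median_size": sizes[(len(sizes) - 1) // 2],
                "median_precision": _lower_median([s.precision for s in of_type]),
                "max_precision": max(s.precision for s in of_type),
            }
        )
    summary = pd.DataFrame(rows)
    return catalogue, stats, summary


def write_catalogue_vcf(catalogue, path) -> None:
    """Write the unified catalogue as a symbolic-allele VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, desc in (
            ("SVTYPE", "SV type"),
            ("END", "End position (1-based inclusive)"),
            ("SVLEN", "SV length"),
            ("SUPP", "Number of supporting tools"),
            ("SUPP_SET", "Supporting tools"),
            ("CIPOS", "Start spread among members"),
            ("CIEND", "End spread among members"),
        ):
            num = "2" if key.startswith("CI") else ("." if key == "SUPP_SET" else "1")
            typ = "String" if key in ("SVTYPE", "SUPP_SET") else "Integer"
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, s in enumerate(
            sorted(catalogue, key=lambda x: (x.chrom, x.start, x.sv_type)), 1
        ):
            svt = "TRA" if s.sv_type.startswith("TRA") else s.sv_type
            lo = min(m.start for m in s.members) - s.start
            hi = max(m.start for m in s.members) - s.start
            lo_e = min(m.end for m in s.members) - s.end
            hi_e = max(m.end for m in s.members) - s.end
            info = (
                f"SVTYPE={svt};END={s.end};SVLEN={s.size};SUPP={s.support};"
                f"SUPP_SET={','.join(sorted(s.tools))};CIPOS={lo},{hi};CIEND={lo_e},{hi_e}"
            )
            fh.write(f"{s.chrom}\t{s.start + 1}\tSV{i:05d}\tN\t<{svt}>\t.\tPASS\t{info}\n")
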