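"""SV ingestion, raw-call filters, clustering and cross-tool concordance."""

import numpy as np
import pytest

from svmosaic.svmerge import (
    SVCall,
    SVFilterConfig,
    apply_raw_filters,
    calls_match,
    cluster_calls,
    ingest_callset,
    reciprocal_overlap,
    unify_and_score,
    write_bedpe,
    write_callset_vcf,
)


def _call(**kw):
    base = dict(
        caller="t1", sv_type="DEL", chrom="c1", start=1000, end=2000,
        gq=60.0, spanning_pairs=25, rd_ratio=0.5,
    )
    base.update(kw)
    return SVCall(**base)


# ----------------------------------------------------------------------
# ingestion / coordinates
# ----------------------------------------------------------------------
def test_vcf_del_coordinates_convert_to_half_open(tmp_path):
    p = tmp_path / "c.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "c1\t1001\tx\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=2000;PE=20;GQ=50\n"
    )
    (call,) = ingest_callset(p, "toolx", "vcf_svtype")
    assert (call.start, call.end, call.size) == (1000, 2000, 1000)


def test_bedpe_cross_chromosome_row_is_interchromosomal(tmp_path):
    p = tmp_path / "c.bedpe"
    p.write_text("c1\t100\t101\tc2\t900\t901\tid1\t50\t+\t+\tLEN=200;GQ=50;PE=20\n")
    (call,) = ingest_callset(p, "bd", "bedpe")
    assert call.sv_type == "TRA_inter"
    assert call.chrom == "c1" and call.chrom2 == "c2"


def test_unknown_svtype_skipped_and_malformed_line_raises(tmp_path):
    p = tmp_path / "c.bedpe"
    p.write_text("c1\t100\t101\tc1\t900\t901\tid1\t50\t+\t+\tTYPE=WEIRD;GQ=50\n")
    assert ingest_callset(p, "x", "bedpe") == []
    p.write_text("c1\tnotanumber\t101\tc1\t900\t901\tid1\t50\t+\t+\tTYPE=DEL\n")
    with pytest.raises(ValueError, match=":1:"):
        ingest_callset(p, "x", "bedpe")


def test_bedpe_and_vcf_round_trips(tmp_path, small_truth):
    calls = [c for cl in small_truth.caller_calls.values() for c in cl]
    assert len(calls) > 80

    def key(c):
        return (c.caller, c.sv_type, c.chrom, c.chrom2, c.start, c.end, c.size,
                c.gq, c.spanning_pairs, c.rd_ratio, c.carriers, c.truth_id)

    write_bedpe(calls, tmp_path / "c.bedpe")
    back = ingest_callset(tmp_path / "c.bedpe", calls[0].caller, "bedpe")
    back = [b.__class__(**{**b.__dict__, "caller": c.caller}) for b, c in zip(back, calls)]
    assert [key(c) for c in back] == [key(c) for c in calls]

    write_callset_vcf(calls, tmp_path / "c.vcf")
    back2 = ingest_callset(tmp_path / "c.vcf", "x", "vcf_svtype")
    assert [(c.sv_type, c.chrom, c.start, c.end) for c in back2] == [
        (c.sv_type, c.chrom, c.start, c.end) for c in calls
    ]


# ----------------------------------------------------------------------
# reciprocal overlap
# ----------------------------------------------------------------------
def test_reciprocal_overlap_cases():
    assert reciprocal_overlap((1000, 2000), (1000, 2000)) == 1.0
    assert reciprocal_overlap((1000, 2000), (1100, 2100)) == pytest.approx(0.9)
    assert reciprocal_overlap((0, 100), (500, 600)) == 0.0
    with pytest.raises(ValueError, match="zero-length"):
        reciprocal_overlap((5, 5), (0, 10))


def test_reciprocal_overlap_is_min_of_both_fractions():
    # nested intervals: RO limited by the larger interval
    assert reciprocal_overlap((0, 1000), (0, 10_000)) == pytest.approx(0.1)


# ----------------------------------------------------------------------
# raw filters
# ----------------------------------------------------------------------
def test_del_passing_all_rules_is_retained():
    retained, tally = apply_raw_filters([_call(rd_ratio=0.5)], SVFilterConfig())
    assert len(retained) == 1 and tally == {}


def test_del_with_high_rd_ratio_removed():
    _, tally = apply_raw_filters([_call(rd_ratio=0.8)], SVFilterConfig())
    assert tally == {"rd_ratio": 1}


def test_dup_needs_mirrored_rd_excess():
    ok = _call(sv_type="DUP", rd_ratio=2.0)
    bad = _call(sv_type="DUP", rd_ratio=1.1)
    retained, tally = apply_raw_filters([ok, bad], SVFilterConfig())
    assert len(retained) == 1 and tally == {"rd_ratio": 1}


def test_missing_rd_ratio_on_del_is_unevaluable():
    _, tally = apply_raw_filters([_call(rd_ratio=None)], SVFilterConfig())
    assert tally == {"rd_unevaluable": 1}


def test_planted_single_rule_violations_tally_by_construction():
    """60 calls with one planted violation each + 10 clean."""
    cfg = SVFilterConfig()
    cent = [("c1", 50_000, 60_000)]
    gaps = [("c1", 80_000, 80_100)]
    syn = [("c1", 90_000, 95_000)]
    calls = []
    for i in range(10):
        calls.append(_call(start=1000 + 5000 * i, end=3000 + 5000 * i))
    planted = []
    for i in range(10):
        planted += [
            _call(rd_ratio=0.9),  # rd_ratio
            _call(spanning_pairs=10),  # spanning_pairs (threshold strict)
            _call(start=59_500, end=60_900),  # breakpoint in padded centromere
            _call(start=80_120, end=81_500),  # breakpoint within 50 bp of gap
            _call(gq=30.0),  # gq (threshold strict)
            SVCall(caller="t1", sv_type="TRA_intra", chrom="c1", start=91_000,
                   end=140_000, gq=60, spanning_pairs=25),  # syntenic TRA
        ]
    retained, tally = apply_raw_filters(calls + planted, cfg, centromeres=cent, gaps=gaps, syntenic=syn)
    assert len(retained) == 10
    assert tally == {
        "rd_ratio": 10,
        "spanning_pairs": 10,
        "centromere": 10,
        "gap": 10,
        "gq": 10,
        "tra_syntenic": 10,
    }


def test_inversion_support_rules():
    cfg = SVFilterConfig()
    good = _call(sv_type="INV", rd_ratio=None, n_genotyped=50, n_samples_total=100,
                 carrier_pair_fraction=0.5)
    low_ratio = _call(sv_type="INV", rd_ratio=None, n_genotyped=20, n_samples_total=100,
                      carrier_pair_fraction=0.5)
    low_pairs = _call(sv_type="INV", rd_ratio=None, n_genotyped=50, n_samples_total=100,
                      carrier_pair_fraction=0.2)
    retained, tally = apply_raw_filters([good, low_ratio, low_pairs], cfg)
    assert len(retained) == 1
    assert tally == {"inv_genotyped_ratio": 1, "inv_carrier_pairs": 1}
    # alternative reading: genotyped / total
    cfg2 = SVFilterConfig(inv_ratio_mode="genotyped_to_total")
    retained2, tally2 = apply_raw_filters([good, low_ratio], cfg2)
    assert len(retained2) == 1 and tally2 == {"inv_genotyped_ratio": 1}


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
def test_identical_calls_from_two_tools_merge():
    sites = cluster_calls([_call(caller="a"), _call(caller="b")])
    assert len(sites) == 1
    assert sites[0].support == 2
    assert (sites[0].start, sites[0].end) == (1000, 2000)


def test_low_reciprocal_overlap_stays_separate():
    a = _call(caller="a", start=0, end=1000)
    b = _call(caller="b", start=0, end=10_000)
    sites = cluster_calls([a, b])
    assert len(sites) == 2


def test_breakpoint_offset_and_ro_are_conjunctive():
    cfg = SVFilterConfig()
    a = _call(start=0, end=100_000)
    b = _call(caller="b", start=300, end=100_300)  # RO ~0.994 but offsets > 250
    assert not calls_match(a, b, cfg)
    c = _call(caller="b", start=200, end=100_200)
    assert calls_match(a, c, cfg)


def _cluster_oracle(calls, cfg):
    """All-pairs + networkx connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if calls_match(calls[i], calls[j], cfg):
                g.add_edge(i, j)
    comps = []
    for comp in nx.connected_components(g):
        comps.append(sorted((calls[i].caller, calls[i].call_id) for i in comp))
    return sorted(comps)


def test_clustering_matches_union_find_oracle_on_jittered_calls():
    rng = np.random.default_rng(13)
    calls = []
    k = 0
    for i in range(100):  # 100 truth positions x up to 3 tools, jitter sd 50
        start = int(rng.integers(0, 2_000_000))
        size = int(rng.integers(300, 5000))
        for tool in ("a", "b", "c"):
            if rng.random() < 0.8:
                k += 1
                ds, de = rng.normal(0, 50, 2).astype(int)
                calls.append(
                    _call(caller=tool, start=max(0, start + ds), end=start + size + de,
                          call_id=f"{tool}{k}")
                )
    assert len(calls) <= 500
    cfg = SVFilterConfig()
    sites = cluster_calls(calls, cfg)
    got = sorted(
        sorted((m.caller, m.call_id) for m in s.members) for s in sites
    )
    assert got == _cluster_oracle(calls, cfg)


def test_clustering_is_permutation_invariant_and_conserves_calls():
    rng = np.random.default_rng(14)
    calls = []
    for i in range(60):
        start = int(rng.integers(0, 500_000))
        for tool in ("a", "b"):
            calls.append(
                _call(caller=tool, start=start + int(rng.normal(0, 30)),
                      end=start + 2000 + int(rng.normal(0, 30)), call_id=f"{tool}{i}")
            )
    ref = cluster_calls(calls)
    perm = [calls[i] for i in rng.permutation(len(calls))]
    shuf = cluster_calls(perm)
    as_keys = lambda sites: [
        (s.sv_type, s.chrom, s.start, s.end, tuple(sorted(m.call_id for m in s.members)))
        for s in sites
    ]
    assert as_keys(ref) == as_keys(shuf)
    assert sum(len(s.members) for s in ref) == len(calls)


def test_representative_is_lower_median():
    calls = [
        _call(caller="a", start=100, end=2100),
        _call(caller="b", start=110, end=2110),
        _call(caller="c", start=130, end=2130),
        _call(caller="d", start=140, end=2140),
    ]
    (site,) = cluster_calls(calls)
    assert (site.start, site.end) == (110, 2110)
    assert site.precision == 30


# ----------------------------------------------------------------------
# unification and concordance
# ----------------------------------------------------------------------
def test_full_agreement_gives_unit_concordance(small_truth):
    from svmosaic.synth import CallerProfile, simulate_caller_outputs

    rng = np.random.default_rng(0)
    out = simulate_caller_outputs(
        small_truth.svs,
        tuple(CallerProfile(n, fn_rate=0.0, fp_count=0, jitter_sd=0.0) for n in "abc"),
        rng,
        small_truth.spec,
    )
    sites = cluster_calls([c for cl in out.values() for c in cl])
    catalogue, stats, _ = unify_and_score(sites)
    assert all(v == 1.0 for v in stats.per_type_call_rate.values())
    assert all(v == 1.0 for v in stats.per_type_site_rate.values())
    # zero-noise mocks reproduce the truth per-type site counts exactly
    truth_counts = {}
    for t in small_truth.svs:
        truth_counts[t.sv_type] = truth_counts.get(t.sv_type, 0) + 1
    got_counts = {}
    for s in catalogue:
        got_counts[s.sv_type] = got_counts.get(s.sv_type, 0) + 1
    assert got_counts == truth_counts


def test_two_of_three_tools_still_unify_all_truth_sites(small_truth):
    from svmosaic.synth import CallerProfile, simulate_caller_outputs

    rng = np.random.default_rng(1)
    out = simulate_caller_outputs(
        small_truth.svs,
        tuple(CallerProfile(n, fn_rate=0.0, fp_count=0, jitter_sd=0.0) for n in "ab"),
        rng,
        small_truth.spec,
    )
    sites = cluster_calls([c for cl in out.values() for c in cl])
    catalogue, _, _ = unify_and_score(sites)
    assert len(catalogue) == len(small_truth.svs)


def test_weighted_mean_equals_hand_computed_average():
    from svmosaic.synth import simulate_agreement_callsets
    from svmosaic.svmerge import WEIGHTED_TYPES

    rng = np.random.default_rng(2)
    truth = []
    for i, svt in enumerate(["DEL"] * 120 + ["INS"] * 40 + ["INV"] * 20 + ["DUP"] * 10):
        start = 10_000 * i
        truth.append(
            SVCall(caller="truth", sv_type=svt, chrom="c1", start=start,
                   end=start + (1 if svt == "INS" else 500),
                   length=500 if svt == "INS" else None, truth_id=f"T{i}")
        )
    out = simulate_agreement_callsets(
        truth, {"DEL": 0.91, "INS": 0.87, "INV": 0.86, "DUP": 0.83}, rng
    )
    sites = cluster_calls([c for cl in out.values() for c in cl])
    _, stats, _ = unify_and_score(sites)
    hand = sum(
        stats.per_type_site_rate[t] * stats.per_type_site_counts[t] for t in WEIGHTED_TYPES
    ) / sum(stats.per_type_site_counts[t] for t in WEIGHTED_TYPES)
    assert stats.weighted_site_rate == pytest.approx(hand)


def test_absent_type_row_is_omitted():
    sites = cluster_calls([_call(caller="a"), _call(caller="b")])
    _, _, summary = unify_and_score(sites)
    assert list(summary["sv_type"]) == ["DEL"]
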