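"""Tests for the five-filter chain and nested-deletion deduplication."""

import numpy as np
import pytest

from conftest import make_pair
from gainloss.detect import SVCall, SVType
from gainloss.filters import (
    CANONICAL_STAGES,
    DepthTrack,
    FilterConfig,
    FilterEvidence,
    FilterReport,
    MismatchTrack,
    PairIndex,
    apply_filter,
    coverage_filter,
    dedup_deletions,
    depth_filter,
    gap_filter,
    ratio_filter,
    run_filter_chain,
    snv_filter,
)
from gainloss.pairs import PairClass, Reason

ANOM = PairClass("ANOMALOUS", Reason.INSERT_TOO_LARGE)
NORM = PairClass("NORMAL", Reason.NONE)


def sv(sv_id="d1", typ=SVType.DELETION, start=1000, end=2000, region2=None,
       support=5, bps=()):
    return SVCall(
        id=sv_id, sv_type=typ, region1=("chr1", start, end), region2=region2,
        support=support, size_estimate=end - start + 1, pair_ids=(),
        breakpoints=bps,
    )


def spanning_index(n_anom, n_conc, lo=900, hi=2100):
    classified = []
    for i in range(n_anom):
        classified.append((make_pair(pid=f"a{i}", pos1=lo, pos2=hi - 89), ANOM))
    for i in range(n_conc):
        classified.append((make_pair(pid=f"c{i}", pos1=lo, pos2=hi - 89), NORM))
    return PairIndex(classified)


# ---------------------------------------------------------------------------
# ratio filter

def test_ratio_all_anomalous_passes():
    ok, _ = ratio_filter(sv(), spanning_index(10, 0), 0.5)
    assert ok


def test_ratio_low_fraction_fails():
    ok, reason = ratio_filter(sv(), spanning_index(2, 18), 0.5)
    assert not ok and "ratio" in reason


def test_ratio_no_evidence():
    ok, reason = ratio_filter(sv(start=50_000, end=51_000), spanning_index(5, 5))
    assert not ok and reason == "NO_EVIDENCE"


def test_ratio_uses_breakpoint_hints():
    call = sv(bps=(("chr1", 1000), ("chr1", 2000)))
    assert ratio_filter(call, spanning_index(10, 0))[0]


def test_ratio_complex_type_needs_one_junction():
    """Non-deletion types pass with one supported junction (the other
    estimated side may have no reference junction at all)."""
    call = sv(typ=SVType.INVERSION, bps=(("chr1", 1000), ("chr1", 90_000)))
    assert ratio_filter(call, spanning_index(10, 0))[0]
    dele = sv(typ=SVType.DELETION, bps=(("chr1", 1000), ("chr1", 90_000)))
    assert not ratio_filter(dele, spanning_index(10, 0))[0]


def test_interchromosomal_pairs_counted_at_both_ends():
    classified = [
        (make_pair(pid=f"i{i}", chrom1="chr1", pos1=1000, chrom2="chr2",
                   pos2=5000, strand2="+"),
         PairClass("ANOMALOUS", Reason.INTERCHROMOSOMAL))
        for i in range(5)
    ]
    idx = PairIndex(classified)
    assert idx.spanning_counts("chr1", 1090)[0] == 5  # 1 bp padding
    assert idx.spanning_counts("chr2", 4999)[0] == 5


# ---------------------------------------------------------------------------
# gap filter

GAPS = [("chr1", 1500, 1549)]


def test_gap_free_region_passes():
    assert gap_filter(sv(start=3000, end=4000), GAPS)[0]


def test_gap_overlap_fails():
    ok, reason = gap_filter(sv(start=1000, end=2000), GAPS)
    assert not ok and "gap overlap 50" in reason


def test_gap_adjacent_passes():
    assert gap_filter(sv(start=1550, end=2000), GAPS)[0]
    assert gap_filter(sv(start=1000, end=1499), GAPS)[0]


# ---------------------------------------------------------------------------
# SNV filter

def mismatch_track(nm, n_pairs=20):
    classified = [make_pair(pid=f"m{i}", pos1=900, pos2=2011, nm=nm)
                  for i in range(n_pairs)]
    return MismatchTrack.from_pairs(classified, {"chr1": 10_000})


def test_snv_clean_reads_pass():
    assert snv_filter(sv(), mismatch_track(nm=0))[0]


def test_snv_dense_mismatches_fail():
    ok, reason = snv_filter(sv(), mismatch_track(nm=5))  # 5/90 > 0.02
    assert not ok and "density" in reason


def test_snv_empty_window_passes():
    assert snv_filter(sv(start=8000, end=9000), mismatch_track(nm=5))[0]


# ---------------------------------------------------------------------------
# coverage / depth filters

def depth_track(cover_interval=True):
    pairs = []
    pos = 100
    while pos < 9400:
        # either read of a pair started in [501, 2000] would touch [1000, 2000]
        touches_del = 501 <= pos <= 2000
        if cover_interval or not touches_del:
            pairs.append(make_pair(pid=f"p{pos}", pos1=pos, pos2=pos + 410))
        pos += 30
    return DepthTrack.from_pairs(pairs, {"chr1": 10_000})


def test_coverage_true_deletion_passes():
    assert coverage_filter(sv(), depth_track(cover_interval=False))[0]


def test_coverage_covered_interval_fails():
    ok, reason = coverage_filter(sv(), depth_track(cover_interval=True))
    assert not ok and "covered" in reason


def test_coverage_type_exemption():
    call = sv(typ=SVType.INVERSION)
    assert coverage_filter(call, depth_track(cover_interval=True))[0]


def test_depth_true_deletion_passes():
    assert depth_filter(sv(), depth_track(cover_interval=False))[0]


def test_depth_covered_interval_fails():
    assert not depth_filter(sv(), depth_track(cover_interval=True))[0]


def test_depth_zero_genome_mean_errors():
    empty = DepthTrack({"chr1": np.zeros(10_000, dtype=np.int64)})
    with pytest.raises(ValueError, match="genome mean"):
        depth_filter(sv(), empty)


# ---------------------------------------------------------------------------
# dedup

def dele(i, start, end, support=5):
    return sv(sv_id=f"d{i}", start=start, end=end, support=support)


def test_dedup_containment():
    out = dedup_deletions([dele(1, 100, 900), dele(2, 200, 300)])
    assert [d.id for d in out] == ["d2"]


def test_dedup_disjoint_unchanged():
    dels = [dele(1, 100, 200), dele(2, 300, 400)]
    assert dedup_deletions(dels) == dels


def test_dedup_chain():
    out = dedup_deletions([dele(1, 100, 900), dele(2, 200, 800), dele(3, 300, 400)])
    assert [d.id for d in out] == ["d3"]


def test_dedup_identical_interval_tiebreak():
    out = dedup_deletions([dele(1, 100, 200, support=3), dele(2, 100, 200, support=9)])
    assert [d.id for d in out] == ["d2"]
    out = dedup_deletions([dele(2, 100, 200), dele(1, 100, 200)])
    assert [d.id for d in out] == ["d1"]


def test_dedup_partial_overlap_kept():
    dels = [dele(1, 100, 500), dele(2, 300, 700)]
    assert len(dedup_deletions(dels)) == 2


def test_dedup_rejects_non_deletions():
    with pytest.raises(ValueError):
        dedup_deletions([sv(typ=SVType.INVERSION)])


def test_dedup_matches_brute_force_oracle():
    rng = np.random.default_rng(13)
    dels = [
        dele(i, s, s + L)
        for i, (s, L) in enumerate(
            zip(rng.integers(1, 100_000, 1000), rng.integers(50, 2000, 1000))
        )
    ]
    out = {d.id for d in dedup_deletions(dels)}
    # oracle: drop identical-interval losers, then any strict container
    best = {}
    for d in dels:
        k = (d.start, d.end)
        if k not in best or (-d.support, d.id) < (-best[k].support, best[k].id):
            best[k] = d
    keep = set()
    for d in best.values():
        if not any(
            (o.start, o.end) != (d.start, d.end)
            and d.start <= o.start and o.end <= d.end
            for o in dels
        ):
            keep.add(d.id)
    assert out == keep
    # no surviving pair is strictly nested
    surv = [d for d in dels if d.id in out]
    for a in surv:
        for b in surv:
            assert a is b or not (
                a.start <= b.start and b.end <= a.end
                and (a.start, a.end) != (b.start, b.end)
            )


# ---------------------------------------------------------------------------
# chain

def all_pass_evidence():
    return FilterEvidence(
        pair_index=spanning_index(10, 0),
        gap_track=[],
        mismatch_track=mismatch_track(nm=0),
        depth_track=depth_track(cover_interval=False),
    )


def test_chain_all_pass_counts():
    calls = [sv(sv_id=f"d{i}", start=1000, end=2000) for i in range(5)]
    # make the five identical intervals distinct so dedup keeps them all
    for i, c in enumerate(calls):
        c.region1 = ("chr1", 1000 + i, 2000 - i)
    survivors, report = run_filter_chain(calls, all_pass_evidence())
    assert report.counts[:6] == [5, 5, 5, 5, 5, 5]
    assert report.counts[-1] == 1  # nested intervals: innermost kept
    assert report.canonical_order


def test_chain_permuted_flagged_non_canonical():
    calls = [sv()]
    _, report = run_filter_chain(
        calls, all_pass_evidence(), stages=tuple(reversed(CANONICAL_STAGES))
    )
    assert not report.canonical_order


def test_chain_monotone_and_flags(efficacy_bed):
    calls = list(efficacy_bed["calls_raw"])
    for c in calls:
        c.filter_flags.clear()
    survivors, report = run_filter_chain(calls, efficacy_bed["evidence"])
    assert report.counts == sorted(report.counts, reverse=True)
    for c in calls:
        failed = [s for s, v in c.filter_flags.items() if v.startswith("fail")]
        assert len(failed) <= 1  # first failing stage only


def test_chain_equals_per_filter_intersection(efficacy_bed):
    """Independent filters: chain survivors (pre-dedup) equal the calls
    passing every filter applied in isolation."""
    calls = list(efficacy_bed["calls_raw"])
    evidence = efficacy_bed["evidence"]
    cfg = FilterConfig()
    survivors, _ = run_filter_chain(calls, evidence, cfg, dedup=False)
    expected = {
        c.id for c in calls
        if all(apply_filter(s, c, evidence, cfg)[0] for s in CANONICAL_STAGES)
    }
    assert {c.id for c in survivors} == expected


def test_filters_idempotent(efficacy_bed):
    evidence = efficacy_bed["evidence"]
    cfg = FilterConfig()
    for c in efficacy_bed["calls_raw"][:40]:
        for stage in CANONICAL_STAGES:
            once = apply_filter(stage, c, evidence, cfg)
            twice = apply_filter(stage, c, evidence, cfg)
            assert once == twice


def test_filter_report_validation():
    with pytest.raises(ValueError):
        FilterReport(["raw", "x"], [3])
    with pytest.raises(ValueError):
        FilterReport(["raw", "x"], [3, 5])
    r = FilterReport(["raw", "x"], [4, 2])
    assert r.retention == [100.0, 50.0]


def test_unknown_stage_rejected():
    with pytest.raises(ValueError, match="unknown filter stage"):
        apply_filter("bogus", sv(), all_pass_evidence(), FilterConfig())
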