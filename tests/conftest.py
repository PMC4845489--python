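"""Shared fixtures.

Heavy synthetic beds are session-scoped so the several tests that consult
them pay the simulation cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

from gainloss import simulate as sim
from gainloss.detect import DetectorConfig, SVCall, SVType, detect_svs
from gainloss.filters import (
    DepthTrack,
    FilterEvidence,
    MismatchTrack,
    PairIndex,
)
from gainloss.pairs import AlignedPair, classify_pairs, estimate_insert_distribution
from gainloss.report import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_result():
    """The standard 2 Mb pipeline run: 50 deletions (500-5000 bp),
    10 inversions, 5 translocations at 30x, mu=500, sigma=30, seed 0."""
    return run_pipeline(PipelineConfig())


def make_pair(
    pid="p1", chrom1="chr1", pos1=100, strand1="+",
    chrom2=None, pos2=510, strand2="-", length=90, nm=0,
):
    return AlignedPair(
        pair_id=pid, chrom1=chrom1, pos1=pos1, strand1=strand1,
        chrom2=chrom2 or chrom1, pos2=pos2, strand2=strand2,
        length1=length, length2=length, nm1=nm, nm2=nm,
    )


@pytest.fixture
def mk_pair():
    return make_pair


@pytest.fixture(scope="session")
def efficacy_bed():
    """A 600 kb bed with gaps, deletions, inverted duplications and
    divergent (paralog-like) regions, plus injected false-positive call
    classes, for the per-filter efficacy tests."""
    scfg = sim.SimulationConfig(
        chrom_lengths=(600_000,),
        gap_spec=(("chr1", 150_000, 300), ("chr1", 320_000, 300),
                  ("chr1", 470_000, 300)),
        seed=11,
    )
    reference = sim.generate_reference(scfg)
    requests = sim.plan_variants(
        reference, scfg,
        n_deletions=12, deletion_sizes=(800, 3000),
        n_inversions=0, n_translocations=0,
        n_duplications=3, duplication_sizes=(1500, 2500),
    )
    sample, truth = sim.implant_variants(reference, requests, scfg, seed=scfg.seed)

    # divergent regions: 2 kb blocks clear of every variant, gap and margin
    rng = np.random.default_rng([scfg.seed, 99])
    avoid = [(t.start - 6000, t.end + 6000) for t in truth]
    avoid += [(s - 6000, e + 6000) for _, s, e in reference.gaps]
    divergent = []
    while len(divergent) < 5:
        s = int(rng.integers(10_000, 580_000))
        e = s + 2000
        if any(s <= ae and e >= as_ for as_, ae in avoid):
            continue
        divergent.append(("chr1", s, e, 0.05))
        avoid.append((s - 6000, e + 6000))

    pairset = sim.simulate_read_pairs(sample, scfg, divergent_regions=tuple(divergent))
    pairs = pairset.to_aligned_pairs()
    model = estimate_insert_distribution(pairs)
    classified = classify_pairs(pairs, model)
    chrom_lengths = {c: reference.length(c) for c in reference.chrom_names}
    depth = DepthTrack.from_pairs(pairs, chrom_lengths)
    evidence = FilterEvidence(
        pair_index=PairIndex(classified),
        gap_track=reference.gaps,
        mismatch_track=MismatchTrack.from_pairs(pairs, chrom_lengths),
        depth_track=depth,
    )
    calls_raw = detect_svs(
        pairs, model, DetectorConfig(), read_length=scfg.read_length,
        depth_track=depth, classes=[c for _, c in classified],
    )

    # ---- injected false-positive call classes -----------------------------
    def fp_call(i, start, end):
        return SVCall(
            id=f"fp{i:03d}", sv_type=SVType.DELETION,
            region1=("chr1", start, end), region2=None,
            support=3, size_estimate=end - start + 1, pair_ids=(),
        )

    clean_avoid = [(t.start - 6000, t.end + 6000) for t in truth]
    clean_avoid += [(s - 6000, e + 6000) for _, s, e in reference.gaps]
    clean_avoid += [(s - 6000, e + 6000) for _, s, e, _ in divergent]
    random_calls = []
    while len(random_calls) < 40:
        s = int(rng.integers(10_000, 575_000))
        e = s + int(rng.integers(1000, 3000))
        if any(s <= ae and e >= as_ for as_, ae in clean_avoid):
            continue
        random_calls.append(fp_call(len(random_calls), s, e))

    gap_calls = []
    for j, (_, gs, ge) in enumerate(reference.gaps):
        for k in range(7):
            # offsets stay small enough that every call overlaps the gap
            off = 100 * k
            gap_calls.append(fp_call(100 + 10 * j + k, gs - 600 + off, ge + 600 + off))
    gap_calls = gap_calls[:20]

    snv_calls = []
    for j, (_, ds, de, _) in enumerate(divergent):
        for k in range(4):
            snv_calls.append(fp_call(200 + 10 * j + k, ds + 200 + 100 * k, de - 200))

    dups = [t for t in truth if t.sv_type is SVType.INVERTED_DUPLICATION]
    dup_calls = []
    for j, t in enumerate(dups):
        for k in range(5):
            s = t.start + 100 + 50 * k
            e = t.end - 100
            dup_calls.append(fp_call(300 + 10 * j + k, s, e))

    truth_del_calls = [
        c for c in calls_raw
        if c.sv_type is SVType.DELETION and any(
            t.sv_type is SVType.DELETION and t.chrom == c.chrom
            and min(c.end, t.end) - max(c.start, t.start) + 1
            >= 0.5 * max(c.end - c.start + 1, t.end - t.start + 1)
            for t in truth
        )
    ]

    return dict(
        config=scfg, reference=reference, sample=sample, truth=truth,
        pairs=pairs, model=model, classified=classified, evidence=evidence,
        calls_raw=calls_raw, divergent=divergent,
        random_calls=random_calls, gap_calls=gap_calls, snv_calls=snv_calls,
        dup_calls=dup_calls, truth_del_calls=truth_del_calls,
    )
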