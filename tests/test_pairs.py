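"""Tests for pair parsing, insert-model estimation and classification."""

import numpy as np
import pytest
from scipy.stats import norm

from gainloss.pairs import (
    AlignedPair,
    InsertModel,
    PairClass,
    Reason,
    classify_pair,
    classify_pairs,
    estimate_insert_distribution,
    read_alignments,
)
from conftest import make_pair


# ---------------------------------------------------------------------------
# AlignedPair arithmetic

def test_outer_distance_insert():
    p = make_pair(pos1=100, pos2=510)  # len 90 each
    assert p.inferred_insert == 500


def test_interchromosomal_insert_undefined():
    p = make_pair(chrom1="chr1", chrom2="chr2")
    assert p.inferred_insert is None
    assert not p.same_chrom


def test_left_strand_uses_leftmost_mate():
    p = make_pair(pos1=510, strand1="-", pos2=100, strand2="+")
    assert p.left_strand == "+"


def test_invalid_pair_rejected():
    with pytest.raises(ValueError):
        make_pair(pos1=0)
    with pytest.raises(ValueError):
        make_pair(strand1="x")


# ---------------------------------------------------------------------------
# SAM parsing

def test_read_alignments_sam_roundtrip(tmp_path):
    from gainloss import simulate as sim

    c = sim.SimulationConfig(chrom_lengths=(20_000,), coverage=15, seed=4)
    ref = sim.generate_reference(c)
    sample, _ = sim.implant_variants(ref, [])
    ps = sim.simulate_read_pairs(sample, c)
    sam = tmp_path / "x.sam"
    sim.write_sam(ps, ref, sam)
    pairs, counts = read_alignments(sam)
    assert counts.pairs == len(ps)
    assert counts.unpaired == 0 and counts.unmapped == 0
    mem = {(p.pair_id, p.chrom1, p.pos1, p.strand1, p.pos2, p.strand2)
           for p in ps.to_aligned_pairs()}
    parsed = {(p.pair_id, p.chrom1, p.pos1, p.strand1, p.pos2, p.strand2)
              for p in pairs}
    assert mem == parsed


def test_read_alignments_skips_low_mapq(tmp_path):
    sam = tmp_path / "t.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
        "a\t99\tchr1\t100\t5\t90M\t=\t510\t500\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
        "a\t147\tchr1\t510\t5\t90M\t=\t100\t-500\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
        "b\t99\tchr1\t100\t60\t90M\t=\t510\t500\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
        "b\t147\tchr1\t510\t60\t90M\t=\t100\t-500\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
    )
    pairs, counts = read_alignments(sam, min_mapq=20)
    assert [p.pair_id for p in pairs] == ["b"]
    assert counts.low_mapq == 1


def test_read_alignments_counts_unmapped_and_unpaired(tmp_path):
    sam = tmp_path / "t.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
        "u\t101\tchr1\t100\t0\t*\t=\t100\t0\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
        "u\t69\tchr1\t100\t60\t90M\t=\t100\t0\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
        "w\t99\tchr1\t100\t60\t90M\t=\t510\t500\t" + "A" * 90 + "\t" + "I" * 90 + "\n"
    )
    pairs, counts = read_alignments(sam)
    assert pairs == []
    assert counts.unmapped == 1
    assert counts.unpaired == 1


# ---------------------------------------------------------------------------
# insert-model estimation

def test_estimate_matches_sampling_oracle():
    rng = np.random.default_rng(5)
    inserts = rng.normal(500, 30, 10_000)
    pairs = [make_pair(pid=f"p{i}", pos1=1000, pos2=1000 + int(x) - 90)
             for i, x in enumerate(np.round(inserts))]
    m = estimate_insert_distribution(pairs)
    assert 498 <= m.mu <= 502
    assert 27 <= m.sigma <= 33


def test_estimate_robust_to_outliers():
    rng = np.random.default_rng(6)
    inserts = list(np.round(rng.normal(500, 30, 9500)))
    inserts += [10_000] * 500  # 5% SV-supporting outliers
    pairs = [make_pair(pid=f"p{i}", pos1=1000, pos2=1000 + int(x) - 90)
             for i, x in enumerate(inserts)]
    m = estimate_insert_distribution(pairs, trim_fraction=0.05)
    # contamination saturating the upper trim leaves the lower trim cutting
    # genuine values, so a small positive bias (~sigma/10) is expected; the
    # untrimmed mean would be off by ~475
    assert abs(m.mu - 500) <= 5
    assert abs(np.mean(inserts) - 500) > 400  # what trimming protects against


def test_estimate_degenerate_sigma_errors():
    pairs = [make_pair(pid=f"p{i}") for i in range(200)]  # all inserts 500
    with pytest.raises(ValueError, match="explicit InsertModel"):
        estimate_insert_distribution(pairs)


def test_estimate_too_few_pairs_errors():
    with pytest.raises(ValueError, match="< 100"):
        estimate_insert_distribution([make_pair()])


def test_insert_model_validation():
    with pytest.raises(ValueError):
        InsertModel(500, 0)
    with pytest.raises(ValueError):
        InsertModel(500, 30, k=0)
    m = InsertModel(500, 30, 3)
    assert m.lower == 410 and m.upper == 590


# ---------------------------------------------------------------------------
# classification

MODEL = InsertModel(500, 30, 3)


def test_normal_pair():
    c = classify_pair(make_pair(), MODEL)
    assert c == PairClass("NORMAL", Reason.NONE)


def test_insert_too_large_is_deletion_signature():
    c = classify_pair(make_pair(pos2=1610), MODEL)  # insert 1600
    assert c.reason is Reason.INSERT_TOO_LARGE


def test_insert_too_small():
    c = classify_pair(make_pair(pos2=300), MODEL)  # insert 290
    assert c.reason is Reason.INSERT_TOO_SMALL


def test_interchromosomal_precedes_everything():
    c = classify_pair(make_pair(chrom2="chr2", strand2="+"), MODEL)
    assert c.reason is Reason.INTERCHROMOSOMAL


def test_wrong_orientation():
    c = classify_pair(make_pair(strand2="+"), MODEL)
    assert c.reason is Reason.WRONG_ORIENTATION


def test_wrong_order():
    c = classify_pair(make_pair(strand1="-", strand2="+"), MODEL)
    assert c.reason is Reason.WRONG_ORDER


def test_window_boundary_inclusive():
    assert classify_pair(make_pair(pos2=100 + 590 - 90), MODEL).status == "NORMAL"
    assert classify_pair(make_pair(pos2=100 + 591 - 90), MODEL).status == "ANOMALOUS"


def test_partition_property():
    rng = np.random.default_rng(7)
    pairs = [
        make_pair(
            pid=f"p{i}",
            chrom2="chr2" if rng.random() < 0.1 else "chr1",
            pos2=int(rng.integers(1, 3000)),
            strand1="+-"[rng.integers(2)],
            strand2="+-"[rng.integers(2)],
        )
        for i in range(500)
    ]
    classified = classify_pairs(pairs, MODEL)
    assert len(classified) == 500
    n_normal = sum(c.status == "NORMAL" for _, c in classified)
    n_anom = sum(c.is_anomalous for _, c in classified)
    assert n_normal + n_anom == 500
    for _, c in classified:
        assert (c.status == "NORMAL") == (c.reason is Reason.NONE)


def test_anomalous_fraction_matches_tail_mass():
    """No implanted SVs, no errors: anomalous fraction = 2*Phi(-k)."""
    from gainloss import simulate as sim

    c = sim.SimulationConfig(chrom_lengths=(300_000,), coverage=30, seed=9)
    ref = sim.generate_reference(c)
    sample, _ = sim.implant_variants(ref, [])
    pairs = sim.simulate_read_pairs(sample, c).to_aligned_pairs()
    model = estimate_insert_distribution(pairs)
    frac = np.mean([classify_pair(p, model).is_anomalous for p in pairs])
    expected = 2 * norm.cdf(-3)
    assert abs(frac - expected) < 1e-3


def test_pairclass_invariant():
    with pytest.raises(ValueError):
        PairClass("NORMAL", Reason.INSERT_TOO_LARGE)
    with pytest.raises(ValueError):
        PairClass("ANOMALOUS", Reason.NONE)
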