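"""Tests for the synthetic test-bed generator."""

import numpy as np
import pytest

from gainloss import simulate as sim
from gainloss._util import gc_fraction
from gainloss.detect import SVType


def cfg(**kw):
    base = dict(chrom_lengths=(10_000,), seed=1)
    base.update(kw)
    return sim.SimulationConfig(**base)


# ---------------------------------------------------------------------------
# reference generation

def test_reference_length_and_no_ns():
    ref = sim.generate_reference(cfg(chrom_lengths=(1000,), gc_content=0.5))
    seq = ref.sequences["chr1"]
    assert len(seq) == 1000
    assert seq.count(b"N") == 0
    assert set(seq) <= set(b"ACGT")


def test_gap_placement():
    ref = sim.generate_reference(cfg(gap_spec=(("chr1", 101, 50),)))
    seq = ref.sequences["chr1"]
    assert seq[100:150] == b"N" * 50
    assert seq[99:100] != b"N" and seq[150:151] != b"N"
    assert ref.gaps == [("chr1", 101, 150)]


def test_gc_binomial_ci():
    n = 100_000
    ref = sim.generate_reference(cfg(chrom_lengths=(n,), gc_content=0.7))
    assert abs(gc_fraction(ref.sequences["chr1"]) - 0.7) < 0.01


def test_overlapping_gap_spec_rejected():
    with pytest.raises(ValueError, match="overlapping gap_spec"):
        cfg(gap_spec=(("chr1", 100, 50), ("chr1", 120, 10)))


def test_gap_outside_chromosome_rejected():
    with pytest.raises(ValueError):
        cfg(gap_spec=(("chr1", 9990, 50),))


def test_reference_deterministic():
    a = sim.generate_reference(cfg())
    b = sim.generate_reference(cfg())
    assert a.sequences == b.sequences


# ---------------------------------------------------------------------------
# variant implantation

def ref10k():
    return sim.generate_reference(cfg())


def test_deletion_bookkeeping():
    ref = ref10k()
    sample, truth = sim.implant_variants(
        ref, [sim.SVRequest(SVType.DELETION, "chr1", 2001, 3000)]
    )
    assert sample.length("chr1") == 9000
    assert truth == [sim.TruthSV(SVType.DELETION, "chr1", 2001, 3000, 1000)]


def test_inversion_bookkeeping():
    ref = ref10k()
    sample, truth = sim.implant_variants(
        ref, [sim.SVRequest(SVType.INVERSION, "chr1", 5001, 6000)]
    )
    assert sample.length("chr1") == 10_000
    assert truth[0].sv_type is SVType.INVERSION
    from gainloss._util import revcomp
    assert sample.sequence("chr1")[5000:6000] == revcomp(ref.fetch("chr1", 5001, 6000))


def test_translocation_bookkeeping():
    ref = sim.generate_reference(cfg(chrom_lengths=(10_000, 10_000)))
    sample, truth = sim.implant_variants(
        ref,
        [sim.SVRequest(SVType.TRANSLOCATION, "chr1", 7001, 7500,
                       dest_chrom="chr2", dest_pos=4000)],
    )
    t = truth[0]
    assert (t.chrom, t.dest_chrom) == ("chr1", "chr2")
    assert sample.length("chr1") == 9500
    assert sample.length("chr2") == 10_500
    # moved segment is intact at its destination
    assert sample.sequence("chr2")[3999:4499] == ref.fetch("chr1", 7001, 7500)


def test_overlapping_requests_rejected():
    ref = ref10k()
    with pytest.raises(ValueError, match="overlapping"):
        sim.implant_variants(
            ref,
            [sim.SVRequest(SVType.DELETION, "chr1", 2001, 3000),
             sim.SVRequest(SVType.INVERSION, "chr1", 2500, 3500)],
        )


def test_variant_past_end_rejected():
    with pytest.raises(ValueError, match="past"):
        sim.implant_variants(
            ref10k(), [sim.SVRequest(SVType.DELETION, "chr1", 9500, 10_500)]
        )


def test_detectability_bounds_enforced():
    ref = ref10k()
    c = cfg()  # max_insertion_size = 500 - 180 = 320
    with pytest.raises(ValueError, match="below the detectable"):
        sim.implant_variants(
            ref, [sim.SVRequest(SVType.DELETION, "chr1", 2001, 2100)], config=c
        )
    with pytest.raises(ValueError, match="exceeds the detectable"):
        sim.implant_variants(
            ref, [sim.SVRequest(SVType.INSERTION, "chr1", 2001, size=400)], config=c
        )


def test_truth_intervals_never_overlap(default_result):
    ivals = sorted((t.chrom, t.start, t.end) for t in default_result.truth)
    for (c1, s1, e1), (c2, s2, e2) in zip(ivals, ivals[1:]):
        assert c1 != c2 or s2 > e1


def test_coordinate_round_trip():
    ref = ref10k()
    sample, _ = sim.implant_variants(
        ref,
        [sim.SVRequest(SVType.DELETION, "chr1", 2001, 3000),
         sim.SVRequest(SVType.INVERSION, "chr1", 5001, 6000)],
    )
    for pos in (1, 1500, 4000, 5500, 7000, 9000):
        mapped = sample.ref_to_sample("chr1", pos)
        if 2001 <= pos <= 3000:
            assert mapped is None  # deleted
            continue
        schrom, spos, strand = mapped
        back = sample.sample_to_ref(schrom, spos)
        assert back == ("chr1", pos, strand)
        if not 5001 <= pos <= 6000:
            assert strand == "+"


# ---------------------------------------------------------------------------
# read simulation

def test_pair_count_formula():
    ref = ref10k()
    sample, _ = sim.implant_variants(ref, [])
    ps = sim.simulate_read_pairs(sample, cfg(coverage=30))
    expected = 30 * 10_000 / (2 * 90)
    assert ps.n_requested == round(expected)
    assert abs(len(ps) - expected) / expected < 0.05


def test_zero_coverage_warns_empty():
    ref = ref10k()
    sample, _ = sim.implant_variants(ref, [])
    with pytest.warns(UserWarning, match="zero fragments"):
        ps = sim.simulate_read_pairs(sample, cfg(coverage=0))
    assert len(ps) == 0


def test_straddling_pairs_see_enlarged_insert():
    c = cfg(chrom_lengths=(30_000,), coverage=60)
    ref = sim.generate_reference(c)
    sample, _ = sim.implant_variants(
        ref, [sim.SVRequest(SVType.DELETION, "chr1", 10_001, 11_000)], config=c
    )
    pairs = sim.simulate_read_pairs(sample, c).to_aligned_pairs()
    straddle = [
        p.inferred_insert for p in pairs
        if min(p.pos1, p.pos2) + 89 < 10_001 and max(p.pos1, p.pos2) > 11_000
    ]
    assert len(straddle) >= 10
    assert abs(float(np.median(straddle)) - 1500) < 3 * 30


def test_pairs_in_quiet_region_normal():
    from gainloss.pairs import InsertModel, classify_pair

    ref = ref10k()
    sample, _ = sim.implant_variants(ref, [])
    pairs = sim.simulate_read_pairs(sample, cfg(coverage=30)).to_aligned_pairs()
    model = InsertModel(500, 30)
    frac = np.mean([classify_pair(p, model).is_anomalous for p in pairs])
    assert frac < 0.01  # only the Normal tail


def test_simulation_byte_identical(tmp_path):
    c = cfg(chrom_lengths=(5000,), coverage=10)
    outs = []
    for run in ("a", "b"):
        ref = sim.generate_reference(c)
        sample, _ = sim.implant_variants(
            ref, [sim.SVRequest(SVType.DELETION, "chr1", 2001, 2500)], config=c
        )
        ps = sim.simulate_read_pairs(sample, c)
        fa = tmp_path / f"ref_{run}.fa"
        sam = tmp_path / f"aln_{run}.sam"
        fq1 = tmp_path / f"r1_{run}.fq"
        fq2 = tmp_path / f"r2_{run}.fq"
        ref.write_fasta(fa)
        sim.write_sam(ps, ref, sam)
        sim.write_fastq(ps, sample, fq1, fq2)
        outs.append(tuple(p.read_bytes() for p in (fa, sam, fq1, fq2)))
    assert outs[0] == outs[1]


# ---------------------------------------------------------------------------
# annotations and transcripts

def anno(n_genes=100, te=0.3034, retro=0.7097, n_qtls=10, seed=3):
    ref = sim.generate_reference(cfg(chrom_lengths=(800_000,)))
    return sim.generate_annotations(
        ref, n_genes=n_genes, te_fraction=te, retro_fraction_of_te=retro,
        n_qtls=n_qtls, seed=seed,
    )


def test_te_fraction_zero():
    genes, _ = anno(te=0.0)
    assert not any(g.is_te for g in genes)


def test_retro_fraction_one():
    genes, _ = anno(retro=1.0)
    assert all(g.is_retrotransposon for g in genes if g.is_te)


def test_te_fraction_binomial_consistent():
    genes, _ = anno(n_genes=100, te=0.3034)
    n_te = sum(g.is_te for g in genes)
    # 99.7% binomial interval around 30.34 of 100
    assert abs(n_te - 30.34) <= 3 * np.sqrt(100 * 0.3034 * (1 - 0.3034))


def test_genes_non_overlapping():
    genes, _ = anno(n_genes=120)
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for ivals in by_chrom.values():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert s2 > e1


def test_qtl_traits_from_vocab():
    _, qtls = anno(n_qtls=25)
    from gainloss.simulate import DEFAULT_TRAIT_VOCAB
    for q in qtls:
        assert DEFAULT_TRAIT_VOCAB[q.trait] == q.category


def test_simulate_transcripts_truth():
    genes, _ = anno(n_genes=60)
    ref = sim.generate_reference(cfg(chrom_lengths=(800_000,)))
    organellar = sim.make_organellar_sets(seed=3)
    records, truth = sim.simulate_transcripts(
        genes, ref, organellar, n_lost=5, n_organellar=6,
        fragmentation_rate=0.5, seed=3,
    )
    assert len(truth.lost_ids) == 5
    assert len(truth.organellar_ids) == 6
    assert sum(1 for v in truth.labels.values() if v == "lost") == 5
    # roughly half the gene-derived transcripts truncated (binomial 99.7% CI)
    gene_recs = [r for r in records if truth.labels[r.transcript_id] == "gene"]
    by_gene = {g.gene_id: g for g in genes}
    n_frag = sum(
        1 for r in gene_recs
        if r.length < by_gene[r.gene_id].end - by_gene[r.gene_id].start + 1
    )
    n = len(gene_recs)
    assert abs(n_frag - 0.5 * n) <= 3 * np.sqrt(n * 0.25)


def test_transcripts_exceed_min_length():
    genes, _ = anno(n_genes=30)
    ref = sim.generate_reference(cfg(chrom_lengths=(800_000,)))
    records, _ = sim.simulate_transcripts(
        genes, ref, sim.make_organellar_sets(seed=1), seed=1
    )
    assert all(r.length >= 200 for r in records)
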