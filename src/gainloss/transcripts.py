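"""Transcript presence/absence screening.

An assembled wild-genome transcript with no qualifying homolog in the
cultivar's reference transcriptome, its organellar (mitochondrial and
chloroplast) cDNA sets, or its nuclear genome is called a *lost* transcript:
sequence the wild genome expresses but the cultivar no longer carries.

The screen is hierarchical: transcripts are first searched against the
reference transcriptome; the unmapped remainder is searched against the
organellar cDNAs and the nuclear genome; survivors are labelled LOST.
Homology is decided by an internal deterministic seed-and-extend search
(exact k-mer seeds chained on shared diagonals, gapless x-drop extension)
with identity and query-coverage thresholds.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._util import gc_fraction, revcomp, round_half_up, percent


class ScreenStatus(enum.Enum):
    MAPPED_TRANSCRIPTOME = "MAPPED_TRANSCRIPTOME"
    MAPPED_ORGANELLE = "MAPPED_ORGANELLE"
    MAPPED_GENOME = "MAPPED_GENOME"
    LOST = "LOST"


MIN_TRANSCRIPT_LENGTH = 200  # assembly contigs below this are discarded


@dataclass(slots=True)
class TranscriptRecord:
    """An assembled transcript with its screening outcome."""

    transcript_id: str
    gene_id: str
    sequence: bytes
    screen_status: ScreenStatus | None = None
    best_hit: "SimilarityHit | None" = None

    def __post_init__(self):
        if isinstance(self.sequence, str):
            self.sequence = self.sequence.encode()
        if len(self.sequence) < MIN_TRANSCRIPT_LENGTH:
            raise ValueError(
                f"{self.transcript_id}: length {len(self.sequence)} < "
                f"{MIN_TRANSCRIPT_LENGTH} bp minimum"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass(frozen=True, slots=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    identity: float        # matches / aligned columns, in [0, 1]
    query_coverage: float  # aligned query span / query length, in [0, 1]
    score: int             # match count over the aligned span
    strand: str = "+"


@dataclass(frozen=True)
class ScreenThresholds:
    k: int = 16
    min_identity: float = 0.90
    min_query_coverage: float = 0.50

    def __post_init__(self):
        if self.k < 11:
            raise ValueError("seed length k must be >= 11")
        for v in (self.min_identity, self.min_query_coverage):
            if not 0 <= v <= 1:
                raise ValueError("thresholds must be in [0, 1]")


# ---------------------------------------------------------------------------
# k-mer index

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _encode(seq: bytes) -> np.ndarray:
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer values and their start positions (windows with an
    ambiguous base are dropped)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | codes[j : n - k + 1 + j].astype(np.uint64)
    bad = np.concatenate([[0], np.cumsum(codes < 0)])
    valid = (bad[k:] - bad[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return vals[pos], pos


class KmerIndex:
    """Exact k-mer index over a collection of subject sequences (forward
    strand only; queries are searched on both strands)."""

    def __init__(self, subjects, k: int = 16):
        self.k = k
        self.subjects: list[tuple[str, bytes]] = [
            (sid, seq.encode() if isinstance(seq, str) else bytes(seq))
            for sid, seq in subjects
        ]
        kmer_parts, pos_parts, subj_parts = [], [], []
        for i, (_, seq) in enumerate(self.subjects):
            vals, pos = _kmer_values(_encode(seq), k)
            kmer_parts.append(vals)
            pos_parts.append(pos)
            subj_parts.append(np.full(len(vals), i, dtype=np.int32))
        if kmer_parts:
            kmers = np.concatenate(kmer_parts)
            order = np.argsort(kmers, kind="stable")
            self._kmers = kmers[order]
            self._pos = np.concatenate(pos_parts)[order]
            self._subj = np.concatenate(subj_parts)[order]
        else:
            self._kmers = np.empty(0, dtype=np.uint64)
            self._pos = np.empty(0, dtype=np.int64)
            self._subj = np.empty(0, dtype=np.int32)

    def __len__(self) -> int:
        return len(self.subjects)

    def lookup(self, vals: np.ndarray, qpos: np.ndarray):
        """Seed matches for query k-mers: arrays (query_pos, subject_idx,
        subject_pos)."""
        lo = np.searchsorted(self._kmers, vals, side="left")
        hi = np.searchsorted(self._kmers, vals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        qp = np.repeat(qpos, counts)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        return qp, self._subj[idx].astype(np.int64), self._pos[idx]


# ---------------------------------------------------------------------------
# seed-and-extend search

def _extend_gapless(
    q: bytes, s: bytes, qlo: int, qhi: int, slo: int, x_drop: int
) -> tuple[int, int]:
    """Extend the seeded span [qlo, qhi) on a fixed diagonal in both
    directions with +1/-2 scoring and an x-drop stop; returns the final
    query span (half-open)."""
    # rightward
    score, best, best_qhi = 0, 0, qhi
    i, j = qhi, slo + (qhi - qlo)
    while i < len(q) and j < len(s):
        score += 1 if q[i] == s[j] else -2
        i += 1
        j += 1
        if score > best:
            best, best_qhi = score, i
        elif best - score > x_drop:
            break
    # leftward
    score, best, best_qlo = 0, 0, qlo
    i, j = qlo - 1, slo - 1
    while i >= 0 and j >= 0:
        score += 1 if q[i] == s[j] else -2
        if score > best:
            best, best_qlo = score, i
        elif best - score > x_drop:
            break
        i -= 1
        j -= 1
    return best_qlo, best_qhi


def similarity_search(
    query_id: str,
    query: bytes,
    index: KmerIndex,
    min_identity: float = 0.90,
    min_query_coverage: float = 0.50,
    x_drop: int = 20,
    max_groups: int = 50,
) -> SimilarityHit | None:
    """Best qualifying hit of ``query`` against the index, or None.

    Seeds are exact k-mers; seeds sharing a (subject, diagonal) are chained
    and extended gaplessly with an x-drop.  A hit is reported iff identity
    >= ``min_identity`` over the aligned span and the span covers
    >= ``min_query_coverage`` of the query.  Both strands are searched; ties
    break by (score desc, subject_id asc, forward strand first).
    """
    if isinstance(query, str):
        query = query.encode()
    if len(index) == 0:
        return None
    best: SimilarityHit | None = None
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        vals, qpos = _kmer_values(_encode(qseq), index.k)
        if len(vals) == 0:
            continue
        qp, subj, spos = index.lookup(vals, qpos)
        if len(qp) == 0:
            continue
        groups: dict[tuple[int, int], list[int]] = defaultdict(list)
        for t in range(len(qp)):
            groups[(int(subj[t]), int(spos[t] - qp[t]))].append(int(qp[t]))
        ranked = sorted(
            groups.items(), key=lambda kv: (-len(kv[1]), kv[0])
        )[:max_groups]
        qarr = np.frombuffer(qseq, dtype=np.uint8)
        for (si, diag), seed_qpos in ranked:
            sid, sseq = index.subjects[si]
            qlo, qhi = min(seed_qpos), max(seed_qpos) + index.k
            qlo, qhi = _extend_gapless(qseq, sseq, qlo, qhi, qlo + diag, x_drop)
            span = qhi - qlo
            if span <= 0:
                continue
            sarr = np.frombuffer(sseq, dtype=np.uint8)[qlo + diag : qhi + diag]
            matches = int(np.count_nonzero(qarr[qlo:qhi] == sarr))
            identity = matches / span
            coverage = span / len(query)
            if identity < min_identity or coverage < min_query_coverage:
                continue
            hit = SimilarityHit(
                query_id=query_id,
                subject_id=sid,
                identity=identity,
                query_coverage=coverage,
                score=matches,
                strand=strand,
            )
            if best is None or (-hit.score, hit.subject_id) < (-best.score, best.subject_id):
                best = hit
    return best


# ---------------------------------------------------------------------------
# the hierarchical screen

@dataclass
class ScreenResult:
    records: list[TranscriptRecord]
    stage_counts: dict[str, int]
    lost_transcripts: list[str] = field(default_factory=list)
    lost_genes: list[str] = field(default_factory=list)


def _load_subjects(source, stage: str) -> list[tuple[str, bytes]]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"{stage}: subject file {path} not found")
        return [(r.id, bytes(str(r.seq), "ascii")) for r in SeqIO.parse(str(path), "fasta")]
    return [
        (sid, seq.encode() if isinstance(seq, str) else bytes(seq))
        for sid, seq in source
    ]


def screen_lost(
    transcripts: list[TranscriptRecord],
    ref_transcriptome,
    mito_cdna,
    chloro_cdna,
    nuclear_genome,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> ScreenResult:
    """Two-stage presence/absence screen.

    Stage 1 searches every transcript against the reference transcriptome;
    unmapped transcripts proceed to stage 2 against the mitochondrial cDNA,
    chloroplast cDNA and nuclear genome together.  Transcripts unmapped at
    both stages are labelled LOST, and lost genes are the distinct gene ids
    among LOST transcripts.
    """
    ref = _load_subjects(ref_transcriptome, "reference-transcriptome stage")
    stage2 = (
        [(f"mito|{i}", s) for i, s in _load_subjects(mito_cdna, "mitochondrial-cDNA stage")]
        + [(f"chloro|{i}", s) for i, s in _load_subjects(chloro_cdna, "chloroplast-cDNA stage")]
        + [(f"nuclear|{i}", s) for i, s in _load_subjects(nuclear_genome, "nuclear-genome stage")]
    )
    idx1 = KmerIndex(ref, k=thresholds.k)
    idx2 = KmerIndex(stage2, k=thresholds.k)

    counts = {
        "input": len(transcripts),
        "mapped_transcriptome": 0,
        "unmapped_stage1": 0,
        "mapped_organelle": 0,
        "mapped_genome": 0,
        "lost": 0,
    }
    lost_t, lost_g = [], set()
    for t in transcripts:
        hit = similarity_search(
            t.transcript_id, t.sequence, idx1,
            thresholds.min_identity, thresholds.min_query_coverage,
        )
        if hit is not None:
            t.screen_status = ScreenStatus.MAPPED_TRANSCRIPTOME
            t.best_hit = hit
            counts["mapped_transcriptome"] += 1
            continue
        counts["unmapped_stage1"] += 1
        hit = similarity_search(
            t.transcript_id, t.sequence, idx2,
            thresholds.min_identity, thresholds.min_query_coverage,
        )
        if hit is not None:
            t.best_hit = hit
            if hit.subject_id.startswith(("mito|", "chloro|")):
                t.screen_status = ScreenStatus.MAPPED_ORGANELLE
                counts["mapped_organelle"] += 1
            else:
                t.screen_status = ScreenStatus.MAPPED_GENOME
                counts["mapped_genome"] += 1
            continue
        t.screen_status = ScreenStatus.LOST
        counts["lost"] += 1
        lost_t.append(t.transcript_id)
        lost_g.add(t.gene_id)
    return ScreenResult(
        records=transcripts,
        stage_counts=counts,
        lost_transcripts=lost_t,
        lost_genes=sorted(lost_g),
    )


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class TranscriptomeStats:
    n_genes: int
    n_transcripts: int
    mean_length: int
    n50: int
    n_below_500: int
    pct_below_500: float
    length_hist: tuple
    gc_hist: tuple


def compute_n50(lengths) -> int:
    """Largest length L such that transcripts of length >= L hold at least
    half the total assembled bases."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("N50 of an empty set")
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(arr), half, side="left"))
    return int(arr[idx])


def transcriptome_stats(
    transcripts: list[TranscriptRecord], min_len: int = MIN_TRANSCRIPT_LENGTH
) -> TranscriptomeStats:
    kept = [t for t in transcripts if t.length >= min_len]
    if not kept:
        raise ValueError("no transcripts pass the length filter")
    lengths = np.array([t.length for t in kept])
    gcs = np.array([t.gc for t in kept])
    n_below = int((lengths < 500).sum())
    lh = np.histogram(lengths, bins=20)
    gh = np.histogram(gcs, bins=np.linspace(0, 1, 21))
    return TranscriptomeStats(
        n_genes=len({t.gene_id for t in kept}),
        n_transcripts=len(kept),
        mean_length=int(round_half_up(float(lengths.mean()), 0)),
        n50=compute_n50(lengths),
        n_below_500=n_below,
        pct_below_500=percent(n_below, len(kept)),
        length_hist=(lh[0].tolist(), lh[1].tolist()),
        gc_hist=(gh[0].tolist(), gh[1].tolist()),
    )


# ---------------------------------------------------------------------------
# I/O

def read_transcript_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts, deriving the gene (cluster) id from the assembler's
    isoform naming: everything before a final ``_t<k>`` or ``_i<k>`` suffix,
    else the full id."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        gene = tid
        for sep in ("_t", "_i"):
            head, _, tail = tid.rpartition(sep)
            if head and tail.isdigit():
                gene = head
                break
        out.append(TranscriptRecord(tid, gene, str(rec.seq).encode()))
    return out


def write_screen_table(result: ScreenResult, path) -> None:
    import pandas as pd

    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "length": t.length,
            "gc": round(t.gc, 4),
            "status": t.screen_status.value if t.screen_status else "",
            "best_hit": t.best_hit.subject_id if t.best_hit else "",
            "identity": round(t.best_hit.identity, 4) if t.best_hit else "",
            "coverage": round(t.best_hit.query_coverage, 4) if t.best_hit else "",
        }
        for t in result.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
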