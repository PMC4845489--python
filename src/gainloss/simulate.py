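"""Synthetic genomes, variants, reads, annotation tracks and transcripts.

Every downstream stage of the pipeline is exercised against data generated
here with a known truth: a reference genome with N-gaps, a derived "wild"
sample genome carrying implanted structural variants, paired-end alignments
reported in reference coordinates (so pairs spanning an implanted variant
become anomalous by construction), gene/QTL tracks, and a transcript set
with known lost members.

The simulation works in the read-versus-reference frame: a DELETION truth
record means reference sequence absent from the sample, i.e. exactly what
produces a deletion signature when sample reads are aligned to the
reference.  The sample genome is homozygous (wild rice material selfed for
many generations has little residual heterozygosity, and the detection
theory assumes a single haplotype).

All randomness flows from ``SimulationConfig.seed`` through one named
stream per sub-task (genome, variants, reads, annotations, transcripts), so
adding a consumer never perturbs the draws of an existing one.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import STREAMS, random_dna, revcomp, rng_for
from .annotate import GeneFeature, QTLFeature, TRAIT_CATEGORIES
from .detect import SVType
from .pairs import AlignedPair
from .transcripts import MIN_TRANSCRIPT_LENGTH, TranscriptRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic test bed.

    Library geometry follows a 500 bp-insert, 90 bp paired-end DNA
    sequencing design.  The insert-size standard deviation is not a library
    specification and defaults to 30 bp (6% CV, typical of size-selected
    short-insert libraries).
    """

    chrom_lengths: tuple[int, ...] = (2_000_000,)
    gc_content: float = 0.436  # rice nuclear genome GC
    gap_spec: tuple[tuple[str, int, int], ...] = ()  # (chrom, start 1-based, length)
    read_length: int = 90
    insert_mean: float = 500.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be > 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.read_length <= 0 or self.insert_sd <= 0 or self.coverage < 0:
            raise ValueError("read_length, insert_sd must be > 0; coverage >= 0")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError(
                "insert_mean must exceed 2 x read_length "
                "(required by the small-insertion detection bound)"
            )
        names = self.chrom_names
        lens = dict(zip(names, self.chrom_lengths))
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, length in self.gap_spec:
            if chrom not in lens:
                raise ValueError(f"gap on unknown chromosome {chrom}")
            if start < 1 or length <= 0 or start + length - 1 > lens[chrom]:
                raise ValueError(f"gap ({chrom},{start},{length}) outside chromosome")
            for s, e in seen.get(chrom, []):
                if start <= e and start + length - 1 >= s:
                    raise ValueError(f"overlapping gap_spec entries on {chrom}")
            seen.setdefault(chrom, []).append((start, start + length - 1))

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))

    @property
    def max_insertion_size(self) -> int:
        """Largest insertion whose flanking pairs can still straddle it."""
        return int(self.insert_mean - 2 * self.read_length)


# ---------------------------------------------------------------------------
# reference genome

@dataclass
class ReferenceGenome:
    sequences: dict[str, bytes]
    gaps: list[tuple[str, int, int]]  # 1-based inclusive (chrom, start, end)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> bytes:
        """1-based inclusive slice."""
        return self.sequences[chrom][start - 1 : end]

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width].decode() + "\n")

    def write_gap_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.gaps:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def generate_reference(config: SimulationConfig) -> ReferenceGenome:
    """I.i.d. bases at the configured GC, with the specified N-runs."""
    rng = rng_for(config.seed, "genome")
    seqs: dict[str, bytes] = {}
    gaps: list[tuple[str, int, int]] = []
    gap_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, length in config.gap_spec:
        gap_by_chrom.setdefault(chrom, []).append((start, start + length - 1))
    for name, length in zip(config.chrom_names, config.chrom_lengths):
        seq = bytearray(random_dna(rng, length, config.gc_content))
        for s, e in sorted(gap_by_chrom.get(name, [])):
            seq[s - 1 : e] = b"N" * (e - s + 1)
            gaps.append((name, s, e))
        seqs[name] = bytes(seq)
    return ReferenceGenome(sequences=seqs, gaps=gaps)


# ---------------------------------------------------------------------------
# variant implantation

@dataclass(frozen=True)
class SVRequest:
    """One variant to implant, in reference coordinates (1-based inclusive).

    DELETION/INVERSION/INVERTED_DUPLICATION edit [start, end] in place;
    INSERTION places ``size`` novel bases immediately before ``start``;
    TRANSLOCATION and INVERTED_TRANSLOCATION move [start, end] to just
    before ``dest_pos`` on ``dest_chrom``.
    """

    sv_type: SVType
    chrom: str
    start: int
    end: int = 0
    size: int = 0
    dest_chrom: str | None = None
    dest_pos: int | None = None


@dataclass(frozen=True)
class TruthSV:
    sv_type: SVType
    chrom: str
    start: int
    end: int
    size: int
    dest_chrom: str | None = None
    dest_pos: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("truth interval start > end")


@dataclass
class Block:
    """A contiguous run of the sample genome and its reference provenance.

    ``ref_chrom`` is None for novel (inserted) sequence.  ``extra_copy``
    marks the second copy of a duplicated segment: it maps back to the same
    reference interval but is excluded from the reference-to-sample map.
    """

    seq: bytes
    ref_chrom: str | None
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    extra_copy: bool = False
    sample_start: int = 0  # assigned at assembly
    sample_end: int = 0


class SampleGenome:
    """The edited genome plus a bidirectional coordinate map."""

    def __init__(self, blocks: dict[str, list[Block]], reference: ReferenceGenome):
        self.blocks = blocks
        self.reference = reference
        self._starts: dict[str, list[int]] = {}
        for chrom, blist in blocks.items():
            pos = 1
            for b in blist:
                b.sample_start = pos
                b.sample_end = pos + len(b.seq) - 1
                pos = b.sample_end + 1
            self._starts[chrom] = [b.sample_start for b in blist]
        # reference -> primary sample block index
        self._ref_index: dict[str, list[tuple[int, int, str, Block]]] = {}
        for chrom, blist in blocks.items():
            for b in blist:
                if b.ref_chrom is not None and not b.extra_copy:
                    self._ref_index.setdefault(b.ref_chrom, []).append(
                        (b.ref_start, b.ref_end, chrom, b)
                    )
        for entries in self._ref_index.values():
            entries.sort()

    @property
    def chrom_names(self) -> list[str]:
        return list(self.blocks)

    def length(self, chrom: str) -> int:
        blist = self.blocks[chrom]
        return blist[-1].sample_end if blist else 0

    @property
    def total_length(self) -> int:
        return sum(self.length(c) for c in self.blocks)

    def sequence(self, chrom: str) -> bytes:
        return b"".join(b.seq for b in self.blocks[chrom])

    def block_at(self, chrom: str, pos: int) -> Block:
        i = bisect_right(self._starts[chrom], pos) - 1
        if i < 0 or pos > self.blocks[chrom][i].sample_end:
            raise IndexError(f"{chrom}:{pos} outside sample genome")
        return self.blocks[chrom][i]

    def sample_to_ref(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """Map a sample position to (ref_chrom, ref_pos, strand); None for
        novel sequence."""
        b = self.block_at(chrom, pos)
        if b.ref_chrom is None:
            return None
        off = pos - b.sample_start
        if b.strand == "+":
            return b.ref_chrom, b.ref_start + off, "+"
        return b.ref_chrom, b.ref_end - off, "-"

    def ref_to_sample(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """Inverse map for reference positions still present in the sample
        (deleted positions return None)."""
        for rs, re, schrom, b in self._ref_index.get(chrom, []):
            if rs <= pos <= re:
                off = pos - rs
                if b.strand == "+":
                    return schrom, b.sample_start + off, "+"
                return schrom, b.sample_end - off, "-"
        return None

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in self.blocks:
                fh.write(f">{name}\n")
                seq = self.sequence(name)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width].decode() + "\n")


_INTERVAL_TYPES = (
    SVType.DELETION,
    SVType.INVERSION,
    SVType.INVERTED_DUPLICATION,
    SVType.TRANSLOCATION,
    SVType.INVERTED_TRANSLOCATION,
)


def implant_variants(
    reference: ReferenceGenome,
    requests: list[SVRequest],
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[SampleGenome, list[TruthSV]]:
    """Edit the reference into a sample genome and return truth records.

    Requested variants must not overlap on the reference (translocation
    destinations count as points).  When a config is given, deletion sizes
    below the detectability bound (insert_mean - 2 x read_length) and
    insertions above it are rejected.
    """
    rng = np.random.default_rng([seed, STREAMS["variants"], 1])
    intervals: list[tuple[str, int, int, str]] = []  # for overlap validation
    edits: dict[str, list[SVRequest]] = {c: [] for c in reference.chrom_names}
    inserts: dict[str, list[tuple[int, Block, SVRequest]]] = {
        c: [] for c in reference.chrom_names
    }
    truth: list[TruthSV] = []

    for i, req in enumerate(requests):
        if req.chrom not in reference.sequences:
            raise ValueError(f"request {i}: unknown chromosome {req.chrom}")
        L = reference.length(req.chrom)
        if req.sv_type is SVType.INSERTION:
            if not 1 <= req.start <= L + 1:
                raise ValueError(f"request {i}: insertion anchor outside chromosome")
            if req.size <= 0:
                raise ValueError(f"request {i}: insertion needs size > 0")
            if config and req.size > config.max_insertion_size:
                raise ValueError(
                    f"request {i}: insertion of {req.size} bp exceeds the "
                    f"detectable bound {config.max_insertion_size} bp"
                )
            intervals.append((req.chrom, req.start, req.start, f"ins{i}"))
            novel = random_dna(rng, req.size, 0.5)
            inserts[req.chrom].append(
                (req.start, Block(novel, None, 0, 0, "+"), req)
            )
            truth.append(
                TruthSV(SVType.INSERTION, req.chrom, req.start, req.start, req.size)
            )
            continue
        if req.sv_type not in _INTERVAL_TYPES:
            raise ValueError(f"request {i}: cannot implant type {req.sv_type}")
        if not 1 <= req.start <= req.end <= L:
            raise ValueError(f"request {i}: variant extends past chromosome end")
        size = req.end - req.start + 1
        if (
            config
            and req.sv_type is SVType.DELETION
            and size < config.max_insertion_size
        ):
            raise ValueError(
                f"request {i}: deletion of {size} bp is below the detectable "
                f"bound {config.max_insertion_size} bp"
            )
        intervals.append((req.chrom, req.start, req.end, f"req{i}"))
        edits[req.chrom].append(req)
        if req.sv_type in (SVType.TRANSLOCATION, SVType.INVERTED_TRANSLOCATION):
            if req.dest_chrom not in reference.sequences or not req.dest_pos:
                raise ValueError(f"request {i}: translocation needs dest_chrom/dest_pos")
            intervals.append((req.dest_chrom, req.dest_pos, req.dest_pos, f"dest{i}"))
            strand = "-" if req.sv_type is SVType.INVERTED_TRANSLOCATION else "+"
            seg = reference.fetch(req.chrom, req.start, req.end)
            seg = revcomp(seg) if strand == "-" else seg
            inserts[req.dest_chrom].append(
                (
                    req.dest_pos,
                    Block(seg, req.chrom, req.start, req.end, strand),
                    req,
                )
            )
        truth.append(
            TruthSV(
                req.sv_type, req.chrom, req.start, req.end, size,
                dest_chrom=req.dest_chrom, dest_pos=req.dest_pos,
            )
        )

    # pairwise overlap check (sweep per chromosome)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, tag in intervals:
        by_chrom.setdefault(chrom, []).append((s, e, tag))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1, t1), (s2, e2, t2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping variant requests on {chrom}: {t1} and {t2}"
                )

    blocks: dict[str, list[Block]] = {}
    for chrom in reference.chrom_names:
        blist: list[Block] = []
        cursor = 1
        L = reference.length(chrom)
        for req in sorted(edits[chrom], key=lambda r: r.start):
            if cursor < req.start:
                blist.append(
                    Block(
                        reference.fetch(chrom, cursor, req.start - 1),
                        chrom, cursor, req.start - 1, "+",
                    )
                )
            seg = reference.fetch(chrom, req.start, req.end)
            if req.sv_type is SVType.DELETION:
                pass
            elif req.sv_type is SVType.INVERSION:
                blist.append(Block(revcomp(seg), chrom, req.start, req.end, "-"))
            elif req.sv_type is SVType.INVERTED_DUPLICATION:
                blist.append(Block(seg, chrom, req.start, req.end, "+"))
                blist.append(
                    Block(revcomp(seg), chrom, req.start, req.end, "-", extra_copy=True)
                )
            # translocation source: segment leaves this locus entirely
            cursor = req.end + 1
        if cursor <= L:
            blist.append(Block(reference.fetch(chrom, cursor, L), chrom, cursor, L, "+"))
        blocks[chrom] = blist

    # splice insertion blocks (novel sequence and translocated segments)
    for chrom, entries in inserts.items():
        for anchor, newblock, req in sorted(entries, key=lambda t: t[0], reverse=True):
            blist = blocks[chrom]
            for j, b in enumerate(blist):
                if (
                    b.ref_chrom == chrom
                    and not b.extra_copy
                    and b.strand == "+"
                    and b.ref_start <= anchor <= b.ref_end + 1
                ):
                    left = Block(
                        b.seq[: anchor - b.ref_start], chrom, b.ref_start, anchor - 1, "+"
                    )
                    right = Block(b.seq[anchor - b.ref_start :], chrom, anchor, b.ref_end, "+")
                    pieces = [p for p in (left, newblock, right) if len(p.seq)]
                    blocks[chrom] = blist[:j] + pieces + blist[j + 1 :]
                    break
            else:
                raise ValueError(
                    f"insertion anchor {chrom}:{anchor} falls in edited sequence"
                )

    return SampleGenome(blocks, reference), truth


def plan_variants(
    reference: ReferenceGenome,
    config: SimulationConfig,
    n_deletions: int = 50,
    deletion_sizes: tuple[int, int] = (500, 5000),
    n_inversions: int = 10,
    inversion_sizes: tuple[int, int] = (500, 5000),
    n_translocations: int = 5,
    translocation_sizes: tuple[int, int] = (500, 5000),
    n_insertions: int = 0,
    insertion_sizes: tuple[int, int] = (100, 280),
    n_duplications: int = 0,
    duplication_sizes: tuple[int, int] = (500, 5000),
    margin: int = 5000,
    max_tries: int = 10000,
) -> list[SVRequest]:
    """Randomly place non-overlapping variants, keeping ``margin`` bp clear
    of chromosome ends, gaps and each other so every variant's breakpoint
    evidence is unambiguous."""
    rng = rng_for(config.seed, "variants")
    names = list(reference.chrom_names)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for chrom, s, e in reference.gaps:
        occupied[chrom].append((s - margin, e + margin))

    def place(size: int) -> tuple[str, int, int]:
        for _ in range(max_tries):
            chrom = names[int(rng.integers(len(names)))]
            L = reference.length(chrom)
            if L < size + 2 * margin:
                continue
            start = int(rng.integers(margin + 1, L - size - margin + 1))
            end = start + size - 1
            if any(start - margin <= oe and end + margin >= os
                   for os, oe in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            return chrom, start, end
        raise RuntimeError("could not place variant without overlap; genome too small")

    reqs: list[SVRequest] = []
    for _ in range(n_deletions):
        size = int(rng.integers(deletion_sizes[0], deletion_sizes[1] + 1))
        chrom, s, e = place(size)
        reqs.append(SVRequest(SVType.DELETION, chrom, s, e))
    for _ in range(n_inversions):
        size = int(rng.integers(inversion_sizes[0], inversion_sizes[1] + 1))
        chrom, s, e = place(size)
        reqs.append(SVRequest(SVType.INVERSION, chrom, s, e))
    for i in range(n_translocations):
        size = int(rng.integers(translocation_sizes[0], translocation_sizes[1] + 1))
        chrom, s, e = place(size)
        dchrom, dpos, _ = place(1)
        typ = SVType.INVERTED_TRANSLOCATION if i % 2 else SVType.TRANSLOCATION
        reqs.append(SVRequest(typ, chrom, s, e, dest_chrom=dchrom, dest_pos=dpos))
    for _ in range(n_insertions):
        size = int(rng.integers(insertion_sizes[0], insertion_sizes[1] + 1))
        chrom, s, _ = place(1)
        reqs.append(SVRequest(SVType.INSERTION, chrom, s, size=size))
    for _ in range(n_duplications):
        size = int(rng.integers(duplication_sizes[0], duplication_sizes[1] + 1))
        chrom, s, e = place(size)
        reqs.append(SVRequest(SVType.INVERTED_DUPLICATION, chrom, s, e))
    return reqs


# ---------------------------------------------------------------------------
# read-pair simulation

@dataclass
class PairSet:
    """Truth-aligned read pairs in reference coordinates (array-backed)."""

    chrom_names: list[str]
    c1: np.ndarray   # ref chromosome index, mate 1 (leftmost on the fragment)
    p1: np.ndarray   # 1-based leftmost ref position
    fwd1: np.ndarray  # True if mate maps to the reference forward strand
    nm1: np.ndarray
    c2: np.ndarray
    p2: np.ndarray
    fwd2: np.ndarray
    nm2: np.ndarray
    read_length: int
    # sample-frame provenance, for sequence extraction by the writers
    schrom: np.ndarray
    sstart: np.ndarray  # fragment start on the sample genome
    frag: np.ndarray
    sample_chrom_names: list[str] = field(default_factory=list)
    n_requested: int = 0
    n_dropped: int = 0
    seed: int = 0

    def __len__(self) -> int:
        return len(self.p1)

    def to_aligned_pairs(self) -> list[AlignedPair]:
        names = self.chrom_names
        r = self.read_length
        return [
            AlignedPair(
                pair_id=f"p{i:07d}",
                chrom1=names[self.c1[i]],
                pos1=int(self.p1[i]),
                strand1="+" if self.fwd1[i] else "-",
                chrom2=names[self.c2[i]],
                pos2=int(self.p2[i]),
                strand2="+" if self.fwd2[i] else "-",
                length1=r,
                length2=r,
                nm1=int(self.nm1[i]),
                nm2=int(self.nm2[i]),
            )
            for i in range(len(self))
        ]


def simulate_read_pairs(
    sample: SampleGenome,
    config: SimulationConfig,
    divergent_regions: tuple[tuple[str, int, int, float], ...] = (),
) -> PairSet:
    """Draw fragments from the sample genome and report both reads in
    reference coordinates through the coordinate map.

    Fragment lengths are Normal(insert_mean, insert_sd) rounded half-up and
    truncated at 2 x read_length; pairs are emitted forward-reverse on the
    sample genome.  Reads that cross a block junction, land in novel
    sequence, or sit mostly (>= 50%) in an N-gap are unmappable and their
    pair is dropped.  ``divergent_regions`` (chrom, start, end, rate) add
    paralog-like extra mismatches to reads overlapping them.
    """
    rng = rng_for(config.seed, "reads")
    r = config.read_length
    schroms = sample.chrom_names
    lens = np.array([sample.length(c) for c in schroms], dtype=np.int64)
    total = int(lens.sum())
    n_pairs = int(round(config.coverage * total / (2 * r)))
    if n_pairs == 0:
        warnings.warn("coverage yields zero fragments; empty output")
        empty = np.empty(0, dtype=np.int64)
        return PairSet(
            sample.reference.chrom_names, empty, empty, empty.astype(bool), empty,
            empty, empty, empty.astype(bool), empty, r, empty, empty, empty,
            schroms, 0, 0, config.seed,
        )

    cid = rng.choice(len(schroms), size=n_pairs, p=lens / total)
    frag = np.floor(rng.normal(config.insert_mean, config.insert_sd, n_pairs) + 0.5)
    frag = np.maximum(frag, 2 * r).astype(np.int64)
    frag = np.minimum(frag, lens[cid])
    start = 1 + np.floor(rng.random(n_pairs) * (lens[cid] - frag + 1)).astype(np.int64)

    # per-chromosome block arrays for vectorised mapping
    ref_names = sample.reference.chrom_names
    ref_idx = {c: i for i, c in enumerate(ref_names)}
    block_arrays = {}
    for ci, chrom in enumerate(schroms):
        bl = sample.blocks[chrom]
        block_arrays[ci] = dict(
            bs=np.array([b.sample_start for b in bl], dtype=np.int64),
            be=np.array([b.sample_end for b in bl], dtype=np.int64),
            rs=np.array([b.ref_start for b in bl], dtype=np.int64),
            re=np.array([b.ref_end for b in bl], dtype=np.int64),
            fwd=np.array([b.strand == "+" for b in bl], dtype=bool),
            novel=np.array([b.ref_chrom is None for b in bl], dtype=bool),
            rc=np.array(
                [ref_idx[b.ref_chrom] if b.ref_chrom else -1 for b in bl],
                dtype=np.int64,
            ),
        )

    def map_reads(rstart, rend):
        """Vectorised sample->reference mapping of read intervals."""
        n = len(rstart)
        ok = np.zeros(n, dtype=bool)
        rchrom = np.full(n, -1, dtype=np.int64)
        rpos = np.zeros(n, dtype=np.int64)
        rfwd = np.ones(n, dtype=bool)
        for ci, ba in block_arrays.items():
            m = cid == ci
            if not m.any():
                continue
            i = np.searchsorted(ba["bs"], rstart[m], side="right") - 1
            inside = (i >= 0) & (rend[m] <= ba["be"][np.maximum(i, 0)])
            mappable = inside & ~ba["novel"][np.maximum(i, 0)]
            idx = np.nonzero(m)[0]
            good = idx[mappable]
            ib = i[mappable]
            off_l = rstart[good] - ba["bs"][ib]
            off_r = rend[good] - ba["bs"][ib]
            fwd_block = ba["fwd"][ib]
            pos = np.where(
                fwd_block, ba["rs"][ib] + off_l, ba["re"][ib] - off_r
            )
            ok[good] = True
            rchrom[good] = ba["rc"][ib]
            rpos[good] = pos
            rfwd[good] = fwd_block  # sample-forward read: ref strand = block strand
        return ok, rchrom, rpos, rfwd

    s1, e1 = start, start + r - 1
    s2, e2 = start + frag - r, start + frag - 1
    ok1, rc1, rp1, rf1 = map_reads(s1, e1)
    ok2, rc2, rp2, rf2 = map_reads(s2, e2)
    rf2 = np.where(ok2, ~rf2, rf2)  # mate 2 is sample-reverse

    # drop reads sitting mostly in N-gaps (unmappable in practice)
    def gap_ok(ok, rc, rp):
        keep = ok.copy()
        for chrom, gs, ge in sample.reference.gaps:
            gi = ref_idx[chrom]
            ov = np.minimum(rp + r - 1, ge) - np.maximum(rp, gs) + 1
            keep &= ~((rc == gi) & (ov >= r / 2))
        return keep

    ok1, ok2 = gap_ok(ok1, rc1, rp1), gap_ok(ok2, rc2, rp2)
    keep = ok1 & ok2

    nm1 = rng.binomial(r, config.base_error_rate, n_pairs).astype(np.int64)
    nm2 = rng.binomial(r, config.base_error_rate, n_pairs).astype(np.int64)
    for chrom, ds, de, rate in divergent_regions:
        gi = ref_idx[chrom]
        for rc, rp, nm in ((rc1, rp1, nm1), (rc2, rp2, nm2)):
            ov = np.minimum(rp + r - 1, de) - np.maximum(rp, ds) + 1
            m = (rc == gi) & (ov > 0)
            nm[m] += rng.binomial(np.where(m, ov, 0), rate)[m]

    return PairSet(
        chrom_names=list(ref_names),
        c1=rc1[keep], p1=rp1[keep], fwd1=rf1[keep], nm1=nm1[keep],
        c2=rc2[keep], p2=rp2[keep], fwd2=rf2[keep], nm2=nm2[keep],
        read_length=r,
        schrom=cid[keep], sstart=start[keep], frag=frag[keep],
        sample_chrom_names=list(schroms),
        n_requested=n_pairs, n_dropped=int(n_pairs - keep.sum()),
        seed=config.seed,
    )


def write_sam(pairset: PairSet, reference: ReferenceGenome, path) -> None:
    """Truth alignments as SAM (1-based POS, proper FLAG bits, NM tags).

    SEQ is the reference-forward sequence at the mapped interval with the
    recorded number of mismatches injected; byte-identical per seed.
    """
    import pysam

    rng = np.random.default_rng([pairset.seed, STREAMS["reads"], 7])
    names = pairset.chrom_names
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": len(reference.sequences[c])} for c in names
            ],
        }
    )
    r = pairset.read_length
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i in range(len(pairset)):
            qname = f"p{i:07d}"
            mates = (
                (pairset.c1[i], pairset.p1[i], pairset.fwd1[i], pairset.nm1[i], 0x40),
                (pairset.c2[i], pairset.p2[i], pairset.fwd2[i], pairset.nm2[i], 0x80),
            )
            for (c, p, fwd, nm, which), (mc, mp, mfwd, _, _) in zip(mates, mates[::-1]):
                seq = bytearray(reference.sequences[names[c]][p - 1 : p + r - 1])
                for j in sorted(rng.choice(r, size=min(int(nm), r), replace=False)):
                    seq[j] = _mutate(seq[j], rng)
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.query_sequence = seq.decode()
                a.flag = (
                    0x1 | which
                    | (0x10 if not fwd else 0)
                    | (0x20 if not mfwd else 0)
                )
                a.reference_id = int(c)
                a.reference_start = int(p) - 1
                a.mapping_quality = 60
                a.cigarstring = f"{r}M"
                a.next_reference_id = int(mc)
                a.next_reference_start = int(mp) - 1
                if c == mc:
                    left = min(int(p), int(mp))
                    right = max(int(p) + r - 1, int(mp) + r - 1)
                    tlen = right - left + 1
                    a.template_length = tlen if int(p) <= int(mp) else -tlen
                else:
                    a.template_length = 0
                a.query_qualities = pysam.qualitystring_to_array("I" * r)
                a.set_tag("NM", int(nm))
                out.write(a)


def _mutate(base: int, rng) -> int:
    alphabet = b"ACGT"
    choices = [b for b in alphabet if b != base]
    return choices[int(rng.integers(3))]


def write_fastq(pairset: PairSet, sample: SampleGenome, path1, path2) -> None:
    """Reads as sequenced (sample-genome orientation), Phred+33 quality."""
    rng = np.random.default_rng([pairset.seed, STREAMS["reads"], 8])
    r = pairset.read_length
    seqs = {c: sample.sequence(c) for c in sample.chrom_names}
    qual = "I" * r
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(len(pairset)):
            chrom = pairset.sample_chrom_names[pairset.schrom[i]]
            s = int(pairset.sstart[i])
            f = int(pairset.frag[i])
            read1 = bytearray(seqs[chrom][s - 1 : s + r - 1])
            read2 = bytearray(revcomp(seqs[chrom][s + f - r - 1 : s + f - 1]))
            for read, nm in ((read1, pairset.nm1[i]), (read2, pairset.nm2[i])):
                for j in rng.choice(r, size=min(int(nm), r), replace=False):
                    read[j] = _mutate(read[j], rng)
            f1.write(f"@p{i:07d}/1\n{read1.decode()}\n+\n{qual}\n")
            f2.write(f"@p{i:07d}/2\n{read2.decode()}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# annotation tracks

#: Trait vocabulary (trait -> category) emulating rice agronomic QTL labels.
DEFAULT_TRAIT_VOCAB: dict[str, str] = {
    "plant height": "anatomy",
    "spikelet number": "yield",
    "panicle number": "yield",
    "leaf senescence": "development",
    "panicle length": "anatomy",
    "biomass yield": "yield",
    "seedling vigor": "vigor",
    "leaf width": "anatomy",
    "tiller number": "vigor",
    "1000-seed weight": "yield",
    "seed dormancy": "development",
    "amylose content": "quality",
    "protein content": "biochemical",
    "chlorophyll content": "biochemical",
    "gelatinization temperature": "quality",
}


def generate_annotations(
    reference: ReferenceGenome,
    n_genes: int,
    te_fraction: float,
    retro_fraction_of_te: float,
    n_qtls: int,
    trait_vocab: dict[str, str] | None = None,
    seed: int = 0,
    gene_sizes: tuple[int, int] = (800, 4000),
    qtl_sizes: tuple[int, int] = (10000, 80000),
    max_tries_per_gene: int = 200,
) -> tuple[list[GeneFeature], list[QTLFeature]]:
    """Non-overlapping gene intervals with TE flags, plus QTL intervals
    (which may overlap anything) carrying trait labels."""
    for frac, name in ((te_fraction, "te_fraction"),
                       (retro_fraction_of_te, "retro_fraction_of_te")):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    vocab = trait_vocab or DEFAULT_TRAIT_VOCAB
    for trait, cat in vocab.items():
        if cat not in TRAIT_CATEGORIES:
            raise ValueError(f"trait {trait!r} has unknown category {cat!r}")
    rng = rng_for(seed, "annotations")
    names = list(reference.chrom_names)
    lens = np.array([reference.length(c) for c in names], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}

    genes: list[GeneFeature] = []
    for _ in range(n_genes):
        for attempt in range(max_tries_per_gene):
            chrom = names[int(rng.choice(len(names), p=lens / lens.sum()))]
            size = int(rng.integers(gene_sizes[0], gene_sizes[1] + 1))
            L = reference.length(chrom)
            if L <= size:
                continue
            start = int(rng.integers(1, L - size + 1))
            end = start + size - 1
            if any(start <= e and end >= s for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            is_te = bool(rng.random() < te_fraction)
            is_retro = bool(is_te and rng.random() < retro_fraction_of_te)
            genes.append(GeneFeature("", chrom, start, end, is_te, is_retro))
            break
        else:
            raise RuntimeError(
                f"could not place {n_genes} non-overlapping genes "
                f"after {max_tries_per_gene} tries each"
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    genes = [
        GeneFeature(f"gene{i + 1:05d}", g.chrom, g.start, g.end, g.is_te,
                    g.is_retrotransposon)
        for i, g in enumerate(genes)
    ]

    traits = sorted(vocab)
    qtls: list[QTLFeature] = []
    for i in range(n_qtls):
        chrom = names[int(rng.choice(len(names), p=lens / lens.sum()))]
        size = int(rng.integers(qtl_sizes[0], qtl_sizes[1] + 1))
        L = reference.length(chrom)
        size = min(size, L - 1)
        start = int(rng.integers(1, L - size + 1))
        trait = traits[int(rng.integers(len(traits)))]
        qtls.append(
            QTLFeature(f"qtl{i + 1:04d}", chrom, start, start + size - 1,
                       trait, vocab[trait])
        )
    return genes, qtls


# ---------------------------------------------------------------------------
# transcripts

def make_organellar_sets(
    seed: int = 0, n_mito: int = 10, n_chloro: int = 10,
    lengths: tuple[int, int] = (500, 2000),
) -> tuple[list[tuple[str, bytes]], list[tuple[str, bytes]]]:
    """Synthetic mitochondrial and chloroplast cDNA sets (random sequences
    standing in for real organellar transcript catalogues)."""
    rng = np.random.default_rng([seed, STREAMS["transcripts"], 2])
    mito = [
        (f"mito_cdna{i + 1:03d}", random_dna(rng, int(rng.integers(*lengths)), 0.45))
        for i in range(n_mito)
    ]
    chloro = [
        (f"chloro_cdna{i + 1:03d}", random_dna(rng, int(rng.integers(*lengths)), 0.38))
        for i in range(n_chloro)
    ]
    return mito, chloro


@dataclass
class TranscriptTruth:
    labels: dict[str, str]  # transcript_id -> gene | organellar | lost
    lost_ids: list[str]
    organellar_ids: list[str]


def simulate_transcripts(
    genes: list[GeneFeature],
    reference: ReferenceGenome,
    organellar_sets: tuple[list, list],
    n_lost: int = 6,
    n_organellar: int = 8,
    fragmentation_rate: float = 0.3,
    seed: int = 0,
    lost_lengths: tuple[int, int] = (400, 1500),
) -> tuple[list[TranscriptRecord], TranscriptTruth]:
    """Assembled-transcript set with known truth.

    Gene-derived transcripts are copies of reference gene sequence, a
    fraction of them truncated to mimic incomplete short-read assembly;
    organellar transcripts are drawn from the provided cDNA sets; lost
    transcripts are novel random sequence with no reference homolog.
    """
    if not 0 <= fragmentation_rate < 1:
        raise ValueError("fragmentation_rate must be in [0, 1)")
    mito, chloro = organellar_sets
    if n_organellar > len(mito) + len(chloro):
        raise ValueError("n_organellar exceeds the provided cDNA sets")
    rng = rng_for(seed, "transcripts")
    records: list[TranscriptRecord] = []
    labels: dict[str, str] = {}

    for g in genes:
        seq = reference.fetch(g.chrom, g.start, g.end)
        if len(seq) < MIN_TRANSCRIPT_LENGTH:
            continue
        if len(seq) > MIN_TRANSCRIPT_LENGTH and rng.random() < fragmentation_rate:
            cut = int(rng.integers(MIN_TRANSCRIPT_LENGTH, len(seq)))
            seq = seq[:cut]
        tid = f"{g.gene_id}_t1"
        records.append(TranscriptRecord(tid, g.gene_id, seq))
        labels[tid] = "gene"

    pool = [("mito", sid, s) for sid, s in mito] + [("chloro", sid, s) for sid, s in chloro]
    pick = rng.choice(len(pool), size=n_organellar, replace=False)
    organellar_ids = []
    for j in sorted(int(x) for x in pick):
        origin, sid, seq = pool[j]
        tid = f"{sid}_t1"
        records.append(TranscriptRecord(tid, sid, bytes(seq)))
        labels[tid] = "organellar"
        organellar_ids.append(tid)

    lost_ids = []
    for i in range(n_lost):
        seq = random_dna(rng, int(rng.integers(*lost_lengths)), 0.42)
        tid = f"novel{i + 1:03d}_t1"
        records.append(TranscriptRecord(tid, f"novel{i + 1:03d}", seq))
        labels[tid] = "lost"
        lost_ids.append(tid)

    return records, TranscriptTruth(labels, lost_ids, organellar_ids)


def write_transcript_fasta(records: list[TranscriptRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for t in records:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width].decode() + "\n")


def write_truth_tsv(truth: list[TruthSV], path) -> None:
    with open(path, "w") as fh:
        fh.write("sv_type\tchrom\tstart\tend\tsize\tdest_chrom\tdest_pos\n")
        for t in truth:
            fh.write(
                f"{t.sv_type.value}\t{t.chrom}\t{t.start}\t{t.end}\t{t.size}"
                f"\t{t.dest_chrom or '.'}\t{t.dest_pos or '.'}\n"
            )
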