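"""Clustering anomalous read pairs into typed structural-variant calls.

Anomalous pairs are binned into genomic windows; pairs whose two reads fall
into the same pair of windows form a *link*, adjacent links are merged, and
each link is assigned one of eight SV types by the majority signature of its
supporting pairs:

========================  =============================================
signature (majority)      call
========================  =============================================
same chrom, FR, ordered,  DELETION (size = median insert - mu)
insert > mu + k.sigma
same chrom, FR, ordered,  INSERTION (size = mu - median insert, capped
insert < mu - k.sigma     at mu - 2 x read length, the structural bound
                          on detectable insertions)
same chrom, same strand   INVERSION; INVERTED_DUPLICATION when a
                          reciprocal link and a depth gain support a
                          second copy
same chrom, FR, outward   FRAGMENT_INSERTION; INVERTED_FRAGMENT_INVERSION
order                     when the reciprocal link is inverted
inter-chrom, FR           TRANSLOCATION
inter-chrom, same strand  INVERTED_TRANSLOCATION
below majority fraction   UNDEFINED
========================  =============================================

The signature table is a reconstruction of standard read-pair SV theory and
is deliberately isolated in :func:`classify_link` for easy revision.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

from .pairs import AlignedPair, InsertModel, PairClass, Reason, classify_pair


class SVType(enum.Enum):
    DELETION = "DELETION"
    INSERTION = "INSERTION"
    INVERSION = "INVERSION"
    TRANSLOCATION = "TRANSLOCATION"
    INVERTED_TRANSLOCATION = "INVERTED_TRANSLOCATION"
    INVERTED_DUPLICATION = "INVERTED_DUPLICATION"
    INVERTED_FRAGMENT_INVERSION = "INVERTED_FRAGMENT_INVERSION"
    FRAGMENT_INSERTION = "FRAGMENT_INSERTION"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class DetectorConfig:
    window_size: int | None = None  # default mu + 2 sigma
    window_step: int | None = None  # default window_size // 2
    min_support: int = 3
    majority_fraction: float = 0.8
    dup_depth_ratio: float = 1.6

    def resolve(self, model: InsertModel) -> tuple[int, int]:
        ws = self.window_size or max(1, int(model.mu + 2 * model.sigma))
        step = self.window_step or max(1, ws // 2)
        if step > ws:
            raise ValueError("window_step must be <= window_size")
        return ws, step


@dataclass
class WindowLink:
    """Two genomic windows joined by anomalous pairs."""

    window_a: tuple[str, int, int]  # (chrom, start, end) 1-based inclusive
    window_b: tuple[str, int, int]
    pairs: list[AlignedPair] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.pairs)

    @property
    def orientation_profile(self) -> Counter:
        return Counter((p.strand1, p.strand2) for p in self.pairs)

    @property
    def order_profile(self) -> Counter:
        out = Counter()
        for p in self.pairs:
            if not p.same_chrom:
                out["interchrom"] += 1
            elif p.strand1 == p.strand2:
                out["same_strand"] += 1
            else:
                out["fr" if p.left_strand == "+" else "rf"] += 1
        return out


@dataclass
class SVCall:
    id: str
    sv_type: SVType
    region1: tuple[str, int, int]
    region2: tuple[str, int, int] | None
    support: int
    size_estimate: int | None
    pair_ids: tuple[str, ...]
    filter_flags: dict = field(default_factory=dict)
    breakpoint_fallback: bool = False
    #: best-estimate junction positions, one per linked side, used by the
    #: ratio filter; falls back to region edges when absent
    breakpoints: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        if self.region1[1] > self.region1[2]:
            raise ValueError(f"{self.id}: region start > end")
        if self.sv_type is SVType.DELETION and self.region2 is not None:
            raise ValueError("DELETION has a single region")

    @property
    def chrom(self) -> str:
        return self.region1[0]

    @property
    def start(self) -> int:
        return self.region1[1]

    @property
    def end(self) -> int:
        return self.region1[2]


# ---------------------------------------------------------------------------
# link construction

def _endpoints(pair: AlignedPair) -> tuple[tuple[str, int], tuple[str, int]]:
    """The pair's two leftmost read positions, canonically ordered."""
    a = (pair.chrom1, pair.pos1)
    b = (pair.chrom2, pair.pos2)
    return (a, b) if a <= b else (b, a)


def build_links(
    anomalous_pairs: Sequence[AlignedPair],
    window_size: int,
    window_step: int,
) -> list[WindowLink]:
    """Bin each anomalous pair by the windows holding its reads' leftmost
    positions; merge links whose windows overlap.  Output is deterministic,
    ordered by (chrom_a, start_a, chrom_b, start_b)."""
    if window_step > window_size:
        raise ValueError("window_step must be <= window_size")
    raw: dict[tuple, list[AlignedPair]] = {}
    for p in anomalous_pairs:
        (ca, pa), (cb, pb) = _endpoints(p)
        key = (ca, (pa - 1) // window_step, cb, (pb - 1) // window_step)
        raw.setdefault(key, []).append(p)

    # union-find merge of links in adjacent/overlapping window pairs
    merge_dist = max(1, -(-window_size // window_step) - 1)
    parent = {k: k for k in raw}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for key in raw:
        ca, wa, cb, wb = key
        for da in range(-merge_dist, merge_dist + 1):
            for db in range(-merge_dist, merge_dist + 1):
                other = (ca, wa + da, cb, wb + db)
                if other != key and other in raw:
                    union(key, other)

    clusters: dict[tuple, list[AlignedPair]] = {}
    for key, pairs in raw.items():
        clusters.setdefault(find(key), []).extend(pairs)

    links = []
    for key in sorted(clusters):
        pairs = clusters[key]
        eps = [_endpoints(p) for p in pairs]
        ca = key[0]
        cb = key[2]
        a_pos = [pa for (c1, pa), _ in eps]
        b_pos = [pb for _, (c2, pb) in eps]
        wa = (ca, min(a_pos), max(a_pos) + window_size - 1)
        wb = (cb, min(b_pos), max(b_pos) + window_size - 1)
        links.append(WindowLink(window_a=wa, window_b=wb, pairs=sorted(
            pairs, key=lambda p: p.pair_id)))
    links.sort(key=lambda l: (l.window_a[0], l.window_a[1], l.window_b[0], l.window_b[1]))
    return links


# ---------------------------------------------------------------------------
# signatures and classification

def _pair_signature(p: AlignedPair, model: InsertModel) -> str:
    if not p.same_chrom:
        return "ITX_INV" if p.strand1 == p.strand2 else "ITX"
    if p.strand1 == p.strand2:
        return "INV"
    if p.left_strand == "-":
        return "OUTWARD"
    ins = p.inferred_insert
    if ins > model.upper:
        return "DEL"
    if ins < model.lower:
        return "INS"
    return "CONCORDANT"


def estimate_breakpoints(
    link: WindowLink, model: InsertModel
) -> tuple[int, int, bool]:
    """Refined interval for an intra-chromosomal interval-type link.

    Interval = [max over supporting pairs of the left read's end + 1,
    min over supporting pairs of the right read's start - 1].  If the pairs
    contradict each other (empty interval), fall back to the window bounds
    and flag it.
    """
    left_ends, right_starts = [], []
    for p in link.pairs:
        if p.pos1 <= p.pos2:
            left_ends.append(p.pos1 + p.length1 - 1)
            right_starts.append(p.pos2)
        else:
            left_ends.append(p.pos2 + p.length2 - 1)
            right_starts.append(p.pos1)
    start = max(left_ends) + 1
    end = min(right_starts) - 1
    if start > end:
        return link.window_a[1], link.window_b[2], True
    return start, end, False


def _envelope(link: WindowLink) -> tuple[str, int, int]:
    chrom = link.window_a[0]
    starts, ends = [], []
    for p in link.pairs:
        lo, hi = p.outer_span
        starts.append(lo)
        ends.append(hi)
    return chrom, min(starts), max(ends)


def _side_reads(link: WindowLink):
    """Split each pair's reads into the link's two sides (canonical order);
    each read is (chrom, start, end, strand)."""
    a, b = [], []
    for p in link.pairs:
        r1 = (p.chrom1, p.pos1, p.pos1 + p.length1 - 1, p.strand1)
        r2 = (p.chrom2, p.pos2, p.pos2 + p.length2 - 1, p.strand2)
        if (r1[0], r1[1]) <= (r2[0], r2[1]):
            a.append(r1)
            b.append(r2)
        else:
            a.append(r2)
            b.append(r1)
    return a, b


def _junction(reads) -> tuple[str, int]:
    """Per-side junction estimate.

    Forward reads approach their junction from the left (upper quantile of
    read ends + 1), reverse reads from the right (lower quantile of read
    starts - 1); when a side carries both (e.g. the merged FF+RR clusters of
    an inversion) the two estimates are averaged.  Quantiles rather than
    extrema keep a single stray pair from dragging the estimate away.
    """
    import numpy as np

    chrom = reads[0][0]
    ends_plus = [r[2] for r in reads if r[3] == "+"]
    starts_minus = [r[1] for r in reads if r[3] == "-"]
    ests = []
    if ends_plus:
        ests.append(float(np.quantile(ends_plus, 0.9, method="higher")) + 1)
    if starts_minus:
        ests.append(float(np.quantile(starts_minus, 0.1, method="lower")) - 1)
    return chrom, int(round(sum(ests) / len(ests)))


def classify_link(
    link: WindowLink,
    model: InsertModel,
    read_length: int = 90,
    config: DetectorConfig = DetectorConfig(),
    depth_track=None,
    has_reciprocal: bool = False,
    reciprocal_inverted: bool = False,
    call_id: str = "sv",
) -> SVCall:
    """Assign an SV type to a link by majority pair signature (see the
    module docstring for the signature table)."""
    sigs = Counter(_pair_signature(p, model) for p in link.pairs)
    sig, n = sigs.most_common(1)[0]
    pair_ids = tuple(p.pair_id for p in link.pairs)
    majority = n / link.support
    side_a, side_b = _side_reads(link)
    bps = (_junction(side_a), _junction(side_b))

    def make(sv_type, region1, region2=None, size=None, fallback=False):
        return SVCall(
            id=call_id, sv_type=sv_type, region1=region1, region2=region2,
            support=link.support, size_estimate=size, pair_ids=pair_ids,
            breakpoint_fallback=fallback, breakpoints=bps,
        )

    if majority < config.majority_fraction or sig == "CONCORDANT":
        return make(SVType.UNDEFINED, _envelope_or_window(link))

    if sig == "DEL":
        start, end, fb = estimate_breakpoints(link, model)
        inserts = [p.inferred_insert for p in link.pairs
                   if _pair_signature(p, model) == "DEL"]
        size = int(round(median(inserts) - model.mu))
        return make(SVType.DELETION, (link.window_a[0], start, end), size=size,
                    fallback=fb)
    if sig == "INS":
        start, end, fb = estimate_breakpoints(link, model)
        if start > end:
            start, end = end, start
        inserts = [p.inferred_insert for p in link.pairs
                   if _pair_signature(p, model) == "INS"]
        cap = int(model.mu - 2 * read_length)
        size = min(int(round(model.mu - median(inserts))), cap)
        return make(SVType.INSERTION, (link.window_a[0], start, end), size=size,
                    fallback=fb)
    if sig == "INV":
        region = _envelope(link)
        if (
            has_reciprocal
            and depth_track is not None
            and depth_track.mean_ratio(*region) >= config.dup_depth_ratio
        ):
            return make(SVType.INVERTED_DUPLICATION, region,
                        size=region[2] - region[1] + 1)
        return make(SVType.INVERSION, region, size=region[2] - region[1] + 1)
    if sig == "OUTWARD":
        region = _envelope(link)
        if has_reciprocal and reciprocal_inverted:
            return make(SVType.INVERTED_FRAGMENT_INVERSION, region)
        return make(SVType.FRAGMENT_INSERTION, region)
    if sig in ("ITX", "ITX_INV"):
        typ = SVType.TRANSLOCATION if sig == "ITX" else SVType.INVERTED_TRANSLOCATION
        return make(typ, link.window_a, region2=link.window_b)
    return make(SVType.UNDEFINED, _envelope_or_window(link))


def _envelope_or_window(link: WindowLink) -> tuple[str, int, int]:
    if link.window_a[0] == link.window_b[0]:
        return (link.window_a[0],
                min(link.window_a[1], link.window_b[1]),
                max(link.window_a[2], link.window_b[2]))
    return link.window_a


# ---------------------------------------------------------------------------
# top-level detection

def detect_svs(
    pairs: Sequence[AlignedPair],
    model: InsertModel,
    config: DetectorConfig = DetectorConfig(),
    read_length: int = 90,
    depth_track=None,
    classes: Sequence[PairClass] | None = None,
) -> list[SVCall]:
    """Classify pairs, build links, and emit typed SV calls with support of
    at least ``config.min_support`` distinct pairs."""
    if classes is None:
        classes = [classify_pair(p, model) for p in pairs]
    anomalous = [p for p, c in zip(pairs, classes) if c.is_anomalous]
    ws, step = config.resolve(model)
    links = [l for l in build_links(anomalous, ws, step)
             if l.support >= config.min_support]

    # reciprocal lookup: another qualifying link on the same chromosome whose
    # envelope overlaps this link's envelope
    envs = []
    for l in links:
        if l.window_a[0] == l.window_b[0]:
            envs.append(_envelope(l))
        else:
            envs.append(None)
    calls = []
    for i, link in enumerate(links):
        recip = False
        recip_inv = False
        if envs[i] is not None:
            c, s, e = envs[i]
            for j, other in enumerate(envs):
                if j == i or other is None:
                    continue
                oc, os_, oe = other
                if oc == c and os_ <= e and oe >= s:
                    recip = True
                    osigs = Counter(
                        _pair_signature(p, model) for p in links[j].pairs
                    )
                    if osigs.most_common(1)[0][0] == "INV":
                        recip_inv = True
        calls.append(
            classify_link(
                link, model, read_length=read_length, config=config,
                depth_track=depth_track, has_reciprocal=recip,
                reciprocal_inverted=recip_inv, call_id=f"sv{i + 1:05d}",
            )
        )
    calls.sort(key=lambda c: (c.region1[0], c.region1[1], c.region1[2], c.id))
    for i, c in enumerate(calls):
        c.id = f"sv{i + 1:05d}"
    return calls


# ---------------------------------------------------------------------------
# output formats

def write_sv_tables(calls: Sequence[SVCall], tsv_path, bed_path=None, bedpe_path=None):
    """TSV for all calls; BED (0-based half-open) for single-region calls;
    BEDPE for two-region calls."""
    with open(tsv_path, "w") as fh:
        fh.write(
            "id\tsv_type\tchrom\tstart\tend\tchrom2\tstart2\tend2\t"
            "support\tsize_estimate\tfilter_flags\n"
        )
        for c in calls:
            r2 = c.region2 or (".", ".", ".")
            flags = ";".join(f"{k}={v}" for k, v in c.filter_flags.items()) or "."
            fh.write(
                f"{c.id}\t{c.sv_type.value}\t{c.region1[0]}\t{c.region1[1]}\t"
                f"{c.region1[2]}\t{r2[0]}\t{r2[1]}\t{r2[2]}\t{c.support}\t"
                f"{c.size_estimate if c.size_estimate is not None else '.'}\t{flags}\n"
            )
    if bed_path:
        with open(bed_path, "w") as fh:
            for c in calls:
                if c.region2 is None:
                    fh.write(
                        f"{c.region1[0]}\t{c.region1[1] - 1}\t{c.region1[2]}\t"
                        f"{c.id}\t{c.support}\t{c.sv_type.value}\n"
                    )
    if bedpe_path:
        with open(bedpe_path, "w") as fh:
            for c in calls:
                if c.region2 is not None:
                    fh.write(
                        f"{c.region1[0]}\t{c.region1[1] - 1}\t{c.region1[2]}\t"
                        f"{c.region2[0]}\t{c.region2[1] - 1}\t{c.region2[2]}\t"
                        f"{c.id}\t{c.support}\t.\t.\t{c.sv_type.value}\n"
                    )
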