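"""The false-positive filter chain for candidate structural variants.

Read-pair SV detection over-calls heavily; five successive filters remove
the dominant false-positive classes, followed by a nested-deletion
deduplication:

ratiofilter     anomalous-pair fraction at both breakpoints must reach a
                minimum (spurious calls sit in concordant coverage)
gapfilter       calls overlapping assembly N-gaps are artefacts of gap edges
SNVfilter       dense mismatches around the breakpoints flag paralogous
                misalignment
coveragefilter  a true homozygous deletion loses read cover: the fraction of
                covered bases inside the interval must be small
depthfilter     mean depth inside a deletion relative to the genome mean
                must be low (duplicated sequence miscalled as deletion fails)
dedup           larger deletions strictly containing a smaller inside
                deletion are removed; the inner call is kept

All thresholds live in :class:`FilterConfig`; the filter semantics are
reconstructions from the filters' roles and observed effects, with every
default configurable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import percent
from .detect import SVCall, SVType
from .pairs import AlignedPair, PairClass

CANONICAL_STAGES = ("ratiofilter", "gapfilter", "SNVfilter", "coveragefilter", "depthfilter")


@dataclass(frozen=True)
class FilterConfig:
    min_ratio: float = 0.5            # ratiofilter: anomalous fraction at breakpoints
    max_gap_overlap_bp: int = 0       # gapfilter
    max_snv_density: float = 0.02     # SNVfilter: mismatches per aligned base
    max_covered_fraction: float = 0.2  # coveragefilter (deletions)
    max_depth_ratio: float = 1 / 3    # depthfilter (deletions)
    breakpoint_window: int = 500      # half-width of breakpoint windows


# ---------------------------------------------------------------------------
# evidence tracks

class DepthTrack:
    """Per-base read depth over the reference."""

    def __init__(self, depths: dict[str, np.ndarray]):
        self.depths = depths
        total_bases = sum(float(d.sum()) for d in depths.values())
        total_len = sum(len(d) for d in depths.values())
        self.genome_mean = total_bases / total_len if total_len else 0.0

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[AlignedPair], chrom_lengths: dict[str, int]
    ) -> "DepthTrack":
        starts: dict[str, list] = defaultdict(list)
        ends: dict[str, list] = defaultdict(list)
        for p in pairs:
            starts[p.chrom1].append(p.pos1)
            ends[p.chrom1].append(p.pos1 + p.length1)
            starts[p.chrom2].append(p.pos2)
            ends[p.chrom2].append(p.pos2 + p.length2)
        depths = {}
        for chrom, L in chrom_lengths.items():
            diff = np.zeros(L + 2, dtype=np.int64)
            if starts.get(chrom):
                s = np.array(starts[chrom])
                e = np.minimum(np.array(ends[chrom]), L + 1)
                np.add.at(diff, s, 1)
                np.add.at(diff, e, -1)
            depths[chrom] = np.cumsum(diff)[1 : L + 1]
        return cls(depths)

    def _slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        d = self.depths[chrom]
        return d[max(start - 1, 0) : min(end, len(d))]

    def covered_fraction(self, chrom: str, start: int, end: int) -> float:
        s = self._slice(chrom, start, end)
        return float((s >= 1).mean()) if len(s) else 0.0

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        s = self._slice(chrom, start, end)
        return float(s.mean()) if len(s) else 0.0

    def mean_ratio(self, chrom: str, start: int, end: int) -> float:
        if self.genome_mean == 0:
            raise ValueError("genome mean depth is zero")
        return self.mean_depth(chrom, start, end) / self.genome_mean


class MismatchTrack:
    """Binned mismatch density (mismatches per aligned base)."""

    def __init__(self, chrom_lengths: dict[str, int], bin_size: int = 100):
        self.bin_size = bin_size
        self.mismatches = {
            c: np.zeros(L // bin_size + 2) for c, L in chrom_lengths.items()
        }
        self.aligned = {
            c: np.zeros(L // bin_size + 2) for c, L in chrom_lengths.items()
        }

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[AlignedPair], chrom_lengths: dict[str, int],
        bin_size: int = 100,
    ) -> "MismatchTrack":
        t = cls(chrom_lengths, bin_size)
        for p in pairs:
            for chrom, pos, length, nm in (
                (p.chrom1, p.pos1, p.length1, p.nm1),
                (p.chrom2, p.pos2, p.length2, p.nm2),
            ):
                b = (pos + length // 2 - 1) // bin_size
                t.mismatches[chrom][b] += nm
                t.aligned[chrom][b] += length
        return t

    def density(self, chrom: str, start: int, end: int) -> float | None:
        """Mean mismatches per aligned base over [start, end]; None when no
        bases align there (no evidence)."""
        b0 = max((start - 1) // self.bin_size, 0)
        b1 = min((end - 1) // self.bin_size + 1, len(self.aligned[chrom]))
        aligned = self.aligned[chrom][b0:b1].sum()
        if aligned == 0:
            return None
        return float(self.mismatches[chrom][b0:b1].sum() / aligned)


class PairIndex:
    """Spanning-pair counts: how many anomalous vs concordant pairs span a
    given breakpoint position (a pair spans it when its outer span contains
    the position)."""

    def __init__(self, classified: Sequence[tuple[AlignedPair, PairClass]]):
        lefts: dict[str, list] = defaultdict(list)
        rights: dict[str, list] = defaultdict(list)
        anom: dict[str, list] = defaultdict(list)
        for p, c in classified:
            if p.same_chrom:
                lo, hi = p.outer_span
                lefts[p.chrom1].append(lo)
                rights[p.chrom1].append(hi)
                anom[p.chrom1].append(c.is_anomalous)
            else:
                # inter-chromosomal pairs have no outer span; each read
                # contributes its own interval (padded 1 bp so a read ending
                # flush against a junction still spans it)
                for chrom, pos, length in (
                    (p.chrom1, p.pos1, p.length1),
                    (p.chrom2, p.pos2, p.length2),
                ):
                    lefts[chrom].append(pos - 1)
                    rights[chrom].append(pos + length)
                    anom[chrom].append(True)
        self._lefts = {c: np.array(v, dtype=np.int64) for c, v in lefts.items()}
        self._rights = {c: np.array(v, dtype=np.int64) for c, v in rights.items()}
        self._anom = {c: np.array(v, dtype=bool) for c, v in anom.items()}

    def spanning_counts(self, chrom: str, pos: int) -> tuple[int, int]:
        """(anomalous, concordant) pairs spanning ``pos``."""
        if chrom not in self._lefts:
            return 0, 0
        m = (self._lefts[chrom] <= pos) & (self._rights[chrom] >= pos)
        a = int((m & self._anom[chrom]).sum())
        return a, int(m.sum()) - a


@dataclass
class FilterEvidence:
    pair_index: PairIndex | None = None
    gap_track: Sequence[tuple[str, int, int]] = ()  # 1-based inclusive
    mismatch_track: MismatchTrack | None = None
    depth_track: DepthTrack | None = None


# ---------------------------------------------------------------------------
# individual filters (each returns (passed, reason))

def _breakpoints(sv: SVCall) -> list[tuple[str, int]]:
    if sv.breakpoints:
        return list(sv.breakpoints)
    if sv.region2 is None:
        return [(sv.region1[0], sv.region1[1]), (sv.region1[0], sv.region1[2])]
    return [
        (sv.region1[0], (sv.region1[1] + sv.region1[2]) // 2),
        (sv.region2[0], (sv.region2[1] + sv.region2[2]) // 2),
    ]


def ratio_filter(
    sv: SVCall, pair_index: PairIndex, min_ratio: float = 0.5
) -> tuple[bool, str]:
    """Pass iff anomalous/(anomalous+concordant) >= min_ratio among the
    pairs spanning the call's breakpoints.

    DELETION and INSERTION calls have two well-defined junctions in
    reference coordinates and must pass at both; for the other types one
    estimated side can fall where the reference has no junction at all
    (e.g. the inner edge of a duplicated copy), so one passing junction
    suffices.  No spanning pairs at any required breakpoint is fatal
    (NO_EVIDENCE).
    """
    require_all = sv.sv_type in (SVType.DELETION, SVType.INSERTION)
    worst = "NO_EVIDENCE"
    for chrom, pos in _breakpoints(sv):
        a, c = pair_index.spanning_counts(chrom, pos)
        if a + c == 0:
            if require_all:
                return False, "NO_EVIDENCE"
            continue
        if a / (a + c) >= min_ratio:
            if not require_all:
                return True, ""
        else:
            worst = f"ratio {a}/{a + c} < {min_ratio}"
            if require_all:
                return False, worst
    if require_all:
        return True, ""
    return False, worst


def gap_filter(
    sv: SVCall, gap_track: Sequence[tuple[str, int, int]],
    max_gap_overlap_bp: int = 0,
) -> tuple[bool, str]:
    """Fail iff any SV region overlaps an assembly N-gap by more than
    ``max_gap_overlap_bp`` bases."""
    regions = [sv.region1] + ([sv.region2] if sv.region2 else [])
    for chrom, start, end in regions:
        for gchrom, gs, ge in gap_track:
            if gchrom != chrom:
                continue
            ov = min(end, ge) - max(start, gs) + 1
            if ov > max_gap_overlap_bp:
                return False, f"gap overlap {ov} bp"
    return True, ""


def snv_filter(
    sv: SVCall, mismatch_track: MismatchTrack, max_density: float = 0.02,
    window: int = 500,
) -> tuple[bool, str]:
    """Fail iff the mean mismatch density in the breakpoint windows exceeds
    ``max_density``; windows with no aligned bases carry no evidence against
    the call and pass."""
    densities = []
    for chrom, pos in _breakpoints(sv):
        d = mismatch_track.density(chrom, pos - window, pos + window)
        if d is not None:
            densities.append(d)
    if not densities:
        return True, ""
    mean = sum(densities) / len(densities)
    if mean > max_density:
        return False, f"mismatch density {mean:.4f} > {max_density}"
    return True, ""


def coverage_filter(
    sv: SVCall, depth_track: DepthTrack, max_covered_fraction: float = 0.2
) -> tuple[bool, str]:
    """DELETIONs: pass iff the fraction of interval bases with depth >= 1 is
    at most ``max_covered_fraction``.  Other types pass unchanged."""
    if sv.sv_type is not SVType.DELETION:
        return True, ""
    frac = depth_track.covered_fraction(*sv.region1)
    if frac > max_covered_fraction:
        return False, f"covered fraction {frac:.3f} > {max_covered_fraction}"
    return True, ""


def depth_filter(
    sv: SVCall, depth_track: DepthTrack, max_depth_ratio: float = 1 / 3
) -> tuple[bool, str]:
    """DELETIONs: pass iff mean interval depth / genome mean is at most
    ``max_depth_ratio``.  Other types pass unchanged."""
    if sv.sv_type is not SVType.DELETION:
        return True, ""
    ratio = depth_track.mean_ratio(*sv.region1)
    if ratio > max_depth_ratio:
        return False, f"depth ratio {ratio:.3f} > {max_depth_ratio}"
    return True, ""


# ---------------------------------------------------------------------------
# deduplication

def dedup_deletions(deletions: Sequence[SVCall]) -> list[SVCall]:
    """Remove deletions whose interval strictly contains another deletion's
    interval (the smaller inside call is kept).  Identical intervals keep
    the higher-support call, then the lexicographically smaller id."""
    for d in deletions:
        if d.sv_type is not SVType.DELETION:
            raise ValueError(f"{d.id} is not a DELETION")
    removed: set[str] = set()
    by_chrom: dict[str, list[SVCall]] = defaultdict(list)
    for d in deletions:
        by_chrom[d.chrom].append(d)
    for chrom, dels in by_chrom.items():
        groups: dict[tuple[int, int], list[SVCall]] = defaultdict(list)
        for d in dels:
            groups[(d.start, d.end)].append(d)
        for g in groups.values():
            if len(g) > 1:
                g.sort(key=lambda d: (-d.support, d.id))
                removed.update(d.id for d in g[1:])
        tree = IntervalTree()
        for d in dels:
            tree.addi(d.start, d.end + 1, d.id)
        for d in dels:
            if d.id in removed:
                continue
            for iv in tree.envelop(d.start, d.end + 1):
                if (iv.begin, iv.end) != (d.start, d.end + 1):
                    removed.add(d.id)
                    break
    return [d for d in deletions if d.id not in removed]


# ---------------------------------------------------------------------------
# the chain

@dataclass
class FilterReport:
    stage_names: list[str]
    counts: list[int]
    canonical_order: bool = True

    def __post_init__(self):
        if len(self.stage_names) != len(self.counts):
            raise ValueError("stage/count length mismatch")
        for a, b in zip(self.counts, self.counts[1:]):
            if b > a:
                raise ValueError("stage counts must be non-increasing")

    @property
    def retention(self) -> list[float]:
        raw = self.counts[0]
        if raw == 0:
            return [100.0] + [0.0] * (len(self.counts) - 1)
        return [percent(c, raw) for c in self.counts]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stage_names, "count": self.counts,
             "retention_pct": self.retention}
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def apply_filter(
    stage: str, sv: SVCall, evidence: FilterEvidence, config: FilterConfig
) -> tuple[bool, str]:
    if stage == "ratiofilter":
        return ratio_filter(sv, evidence.pair_index, config.min_ratio)
    if stage == "gapfilter":
        return gap_filter(sv, evidence.gap_track, config.max_gap_overlap_bp)
    if stage == "SNVfilter":
        return snv_filter(sv, evidence.mismatch_track, config.max_snv_density,
                          config.breakpoint_window)
    if stage == "coveragefilter":
        return coverage_filter(sv, evidence.depth_track, config.max_covered_fraction)
    if stage == "depthfilter":
        return depth_filter(sv, evidence.depth_track, config.max_depth_ratio)
    raise ValueError(f"unknown filter stage {stage!r}")


def run_filter_chain(
    svs: Sequence[SVCall],
    evidence: FilterEvidence,
    config: FilterConfig = FilterConfig(),
    stages: Sequence[str] = CANONICAL_STAGES,
    dedup: bool = True,
) -> tuple[list[SVCall], FilterReport]:
    """Apply the filters successively in the given order (canonical:
    ratiofilter, gapfilter, SNVfilter, coveragefilter, depthfilter), then
    deduplicate nested deletions.  Each SV's ``filter_flags`` records every
    stage it passed and the first stage it failed."""
    canonical = tuple(stages) == CANONICAL_STAGES
    counts = [len(svs)]
    alive = list(svs)
    for stage in stages:
        survivors = []
        for sv in alive:
            passed, reason = apply_filter(stage, sv, evidence, config)
            sv.filter_flags[stage] = "pass" if passed else f"fail:{reason}"
            if passed:
                survivors.append(sv)
        alive = survivors
        counts.append(len(alive))
    if dedup:
        dels = [s for s in alive if s.sv_type is SVType.DELETION]
        kept = {d.id for d in dedup_deletions(dels)} if dels else set()
        survivors = []
        for sv in alive:
            if sv.sv_type is SVType.DELETION and sv.id not in kept:
                sv.filter_flags["dedup"] = "fail:contains smaller deletion"
            else:
                sv.filter_flags["dedup"] = "pass"
                survivors.append(sv)
        alive = survivors
        counts.append(len(alive))
        names = ["raw", *stages, "dedup"]
    else:
        names = ["raw", *stages]
    return alive, FilterReport(names, counts, canonical_order=canonical)
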