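"""Composition reports and the end-to-end pipeline.

Reporting follows the "X % (a/b)" convention: every percentage is printed
with its numerator and denominator, rounded half-up to two decimals.
``run_pipeline`` chains the whole analysis on a synthetic test bed with
known truth: simulate -> classify pairs -> detect -> filter -> annotate ->
transcript screen -> summary tables, with a manifest of parameters and
artifact hashes so a run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from ._util import percent
from . import annotate as ann
from . import simulate as sim
from .detect import DetectorConfig, SVCall, SVType, detect_svs
from .filters import (
    DepthTrack,
    FilterConfig,
    FilterEvidence,
    FilterReport,
    MismatchTrack,
    PairIndex,
    run_filter_chain,
)
from .pairs import InsertModel, classify_pairs, estimate_insert_distribution
from .transcripts import (
    ScreenResult,
    ScreenThresholds,
    screen_lost,
    transcriptome_stats,
)


@dataclass(frozen=True)
class FractionStatement:
    """A count fraction reported as a two-decimal percentage."""

    label: str
    numerator: int
    denominator: int

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValueError(f"{self.label}: denominator must be > 0")

    @property
    def percent(self) -> float:
        return percent(self.numerator, self.denominator)

    def __str__(self) -> str:
        return f"{self.label}: {self.percent:.2f} % ({self.numerator}/{self.denominator})"


#: Output order of SV types in the type-fraction table.
SV_TYPE_ORDER = (
    SVType.DELETION,
    SVType.TRANSLOCATION,
    SVType.INVERTED_TRANSLOCATION,
    SVType.INVERSION,
    SVType.INVERTED_DUPLICATION,
    SVType.INVERTED_FRAGMENT_INVERSION,
    SVType.FRAGMENT_INSERTION,
    SVType.INSERTION,
    SVType.UNDEFINED,
)


def sv_type_fractions(sv_calls) -> pd.DataFrame:
    """Fraction of total calls per SV type, plus a combined row for the
    translocation class (translocations + inverted translocations).

    ``sv_calls`` is either a sequence of calls or a mapping of type (enum or
    name) to count.
    """
    if isinstance(sv_calls, dict):
        counts = {
            (t if isinstance(t, SVType) else SVType(t)): int(n)
            for t, n in sv_calls.items()
        }
    else:
        counts = {}
        for c in sv_calls:
            counts[c.sv_type] = counts.get(c.sv_type, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no SV calls")
    rows = []
    for t in SV_TYPE_ORDER:
        n = counts.get(t, 0)
        rows.append(
            {"sv_type": t.value, "count": n, "percent": percent(n, total)}
        )
    combined = counts.get(SVType.TRANSLOCATION, 0) + counts.get(
        SVType.INVERTED_TRANSLOCATION, 0
    )
    rows.append(
        {
            "sv_type": "TRANSLOCATION+INVERTED_TRANSLOCATION",
            "count": combined,
            "percent": percent(combined, total),
        }
    )
    df = pd.DataFrame(rows)
    df["total"] = total
    return df


def stage_retention(report: FilterReport) -> list[FractionStatement]:
    """Retention of each filter stage relative to the raw candidate count."""
    raw = report.counts[0]
    if raw == 0:
        raise ValueError("empty raw candidate set")
    return [
        FractionStatement(stage, count, raw)
        for stage, count in zip(report.stage_names, report.counts)
    ]


# ---------------------------------------------------------------------------
# truth matching

def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def match_deletions(
    calls, truth, min_reciprocal: float = 0.5
) -> dict:
    """Recall and precision of deletion calls against truth deletions at a
    reciprocal-overlap criterion (each interval covering at least the stated
    fraction of the other)."""
    call_dels = [c for c in calls if c.sv_type is SVType.DELETION]
    truth_dels = [t for t in truth if t.sv_type is SVType.DELETION]
    matched_truth: set[int] = set()
    matched_calls: set[str] = set()
    for c in call_dels:
        for i, t in enumerate(truth_dels):
            if t.chrom != c.chrom:
                continue
            if reciprocal_overlap((c.start, c.end), (t.start, t.end)) >= min_reciprocal:
                matched_truth.add(i)
                matched_calls.add(c.id)
    recall = len(matched_truth) / len(truth_dels) if truth_dels else 0.0
    precision = len(matched_calls) / len(call_dels) if call_dels else 0.0
    return {
        "n_truth": len(truth_dels),
        "n_calls": len(call_dels),
        "n_truth_matched": len(matched_truth),
        "n_calls_matched": len(matched_calls),
        "recall": recall,
        "precision": precision,
    }


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    variants: dict = field(
        default_factory=lambda: dict(
            n_deletions=50,
            deletion_sizes=(500, 5000),
            n_inversions=10,
            inversion_sizes=(500, 5000),
            n_translocations=5,
            translocation_sizes=(500, 5000),
            n_insertions=0,
            n_duplications=0,
        )
    )
    annotations: dict = field(
        default_factory=lambda: dict(
            n_genes=150,
            te_fraction=0.3034,          # genome-wide TE proportion emulated
            retro_fraction_of_te=0.7097,  # retrotransposon share of TEs
            n_qtls=40,
        )
    )
    transcripts: dict = field(
        default_factory=lambda: dict(
            n_lost=6, n_organellar=8, fragmentation_rate=0.3
        )
    )
    min_mapq: int = 20
    insert_trim_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "simulate" in raw:
            d = dict(raw["simulate"])
            if "chrom_lengths" in d:
                d["chrom_lengths"] = tuple(d["chrom_lengths"])
            if "gap_spec" in d:
                d["gap_spec"] = tuple(tuple(g) for g in d["gap_spec"])
            cfg.simulation = sim.SimulationConfig(**d)
        if "detect" in raw:
            cfg.detector = DetectorConfig(**raw["detect"])
        if "filter" in raw:
            cfg.filters = FilterConfig(**raw["filter"])
        if "transcripts" in raw:
            tr = dict(raw["transcripts"])
            screen_keys = {"k", "min_identity", "min_query_coverage"}
            screen = {k: tr.pop(k) for k in list(tr) if k in screen_keys}
            if screen:
                cfg.screen = ScreenThresholds(**screen)
            cfg.transcripts.update(tr)
        if "variants" in raw:
            cfg.variants.update(raw["variants"])
        if "annotate" in raw:
            cfg.annotations.update(raw["annotate"])
        return cfg


@dataclass
class PipelineResult:
    truth: list
    insert_model: InsertModel
    pair_counts: dict
    calls_raw: list[SVCall]
    calls_filtered: list[SVCall]
    filter_report: FilterReport
    deletion_match: dict
    genes: list
    qtls: list
    gene_mapping: dict
    qtl_mapping: dict
    gene_stats: ann.DeletionGeneStats
    te: ann.TESummary
    trait_table: pd.DataFrame
    relationship: pd.DataFrame
    screen_result: ScreenResult
    transcript_truth: sim.TranscriptTruth
    transcript_stats: object
    type_fractions: pd.DataFrame
    retention: list[FractionStatement]
    manifest: dict


def _hash(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run the complete analysis on the synthetic test bed.

    Deterministic for a fixed config (all randomness flows from
    ``config.simulation.seed``); writes TSV/JSON artifacts plus a manifest
    when ``outdir`` is given.
    """
    scfg = config.simulation
    reference = sim.generate_reference(scfg)
    requests = sim.plan_variants(reference, scfg, **config.variants)
    sample, truth = sim.implant_variants(reference, requests, scfg, seed=scfg.seed)
    pairset = sim.simulate_read_pairs(sample, scfg)
    pairs = pairset.to_aligned_pairs()

    model = estimate_insert_distribution(pairs, config.insert_trim_fraction)
    classified = classify_pairs(pairs, model)
    n_anom = sum(1 for _, c in classified if c.is_anomalous)
    pair_counts = {
        "requested": pairset.n_requested,
        "emitted": len(pairs),
        "dropped_unmappable": pairset.n_dropped,
        "anomalous": n_anom,
        "normal": len(pairs) - n_anom,
    }

    chrom_lengths = {c: reference.length(c) for c in reference.chrom_names}
    depth = DepthTrack.from_pairs(pairs, chrom_lengths)
    mism = MismatchTrack.from_pairs(pairs, chrom_lengths)
    evidence = FilterEvidence(
        pair_index=PairIndex(classified),
        gap_track=reference.gaps,
        mismatch_track=mism,
        depth_track=depth,
    )

    classes = [c for _, c in classified]
    calls_raw = detect_svs(
        pairs, model, config.detector, read_length=scfg.read_length,
        depth_track=depth, classes=classes,
    )
    calls_filtered, filter_report = run_filter_chain(
        calls_raw, evidence, config.filters
    )
    deletion_match = match_deletions(calls_filtered, truth)

    genes, qtls = sim.generate_annotations(
        reference, seed=scfg.seed, **config.annotations
    )
    qtls = ann.qtl_dedup(qtls)
    deletions = [c for c in calls_filtered if c.sv_type is SVType.DELETION]
    gene_mapping = ann.intersect_deletions_features(deletions, genes)
    qtl_mapping = ann.intersect_deletions_features(deletions, qtls)
    gene_stats = ann.deletion_gene_stats(gene_mapping)
    deleted_genes = sorted(
        {g.gene_id: g for gs in gene_mapping.values() for g in gs}.values(),
        key=lambda g: g.gene_id,
    )
    te = ann.te_summary(deleted_genes, genes)
    trait_table = ann.trait_summary(qtl_mapping, gene_mapping)
    relationship = ann.relationship_table(deletions, gene_mapping, qtl_mapping)

    organellar = sim.make_organellar_sets(seed=scfg.seed)
    transcripts, t_truth = sim.simulate_transcripts(
        genes, reference, organellar, seed=scfg.seed, **config.transcripts
    )
    ref_transcriptome = [
        (f"{g.gene_id}_ref", reference.fetch(g.chrom, g.start, g.end))
        for g in genes
    ]
    nuclear = [(c, reference.sequences[c]) for c in reference.chrom_names]
    screen = screen_lost(
        transcripts, ref_transcriptome, organellar[0], organellar[1], nuclear,
        config.screen,
    )
    t_stats = transcriptome_stats(transcripts)

    type_fractions = sv_type_fractions(calls_filtered)
    retention = stage_retention(filter_report)

    manifest = {
        "config": _config_dict(config),
        "hashes": {
            "reference": _hash(b"".join(reference.sequences.values())),
            "sample": _hash(
                b"".join(sample.sequence(c) for c in sample.chrom_names)
            ),
            "truth": _hash(
                json.dumps([asdict_truth(t) for t in truth]).encode()
            ),
            "calls": _hash(
                json.dumps(
                    [(c.id, c.sv_type.value, c.region1, c.region2, c.support)
                     for c in calls_filtered]
                ).encode()
            ),
        },
        "counts": {
            **pair_counts,
            "stage_counts": dict(
                zip(filter_report.stage_names, filter_report.counts)
            ),
            "deletions_final": len(deletions),
            "lost_transcripts": len(screen.lost_transcripts),
        },
    }

    result = PipelineResult(
        truth=truth, insert_model=model, pair_counts=pair_counts,
        calls_raw=calls_raw, calls_filtered=calls_filtered,
        filter_report=filter_report, deletion_match=deletion_match,
        genes=genes, qtls=qtls, gene_mapping=gene_mapping,
        qtl_mapping=qtl_mapping, gene_stats=gene_stats, te=te,
        trait_table=trait_table, relationship=relationship,
        screen_result=screen, transcript_truth=t_truth,
        transcript_stats=t_stats, type_fractions=type_fractions,
        retention=retention, manifest=manifest,
    )
    if outdir is not None:
        _write_artifacts(result, reference, Path(outdir))
    return result


def asdict_truth(t) -> dict:
    return {
        "sv_type": t.sv_type.value, "chrom": t.chrom, "start": t.start,
        "end": t.end, "size": t.size, "dest_chrom": t.dest_chrom,
        "dest_pos": t.dest_pos,
    }


def _config_dict(config: PipelineConfig) -> dict:
    return {
        "simulate": asdict(config.simulation),
        "detect": asdict(config.detector),
        "filter": asdict(config.filters),
        "screen": asdict(config.screen),
        "variants": dict(config.variants),
        "annotate": dict(config.annotations),
        "transcripts": dict(config.transcripts),
    }


def _write_artifacts(result: PipelineResult, reference, outdir: Path) -> None:
    from .detect import write_sv_tables
    from .transcripts import write_screen_table

    outdir.mkdir(parents=True, exist_ok=True)
    write_sv_tables(
        result.calls_filtered,
        outdir / "svs.tsv",
        bed_path=outdir / "deletions.bed",
        bedpe_path=outdir / "svs.bedpe",
    )
    result.filter_report.write_tsv(outdir / "filter_report.tsv")
    result.type_fractions.to_csv(outdir / "sv_type_fractions.tsv", sep="\t", index=False)
    result.relationship.to_csv(outdir / "relationship.tsv", sep="\t", index=False)
    result.trait_table.to_csv(outdir / "trait_summary.tsv", sep="\t", index=False)
    write_screen_table(result.screen_result, outdir / "transcript_screen.tsv")
    sim.write_truth_tsv(result.truth, outdir / "truth_svs.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {
                "deletion_match": result.deletion_match,
                "pair_counts": result.pair_counts,
                "stage_counts": result.manifest["counts"]["stage_counts"],
                "screen_counts": result.screen_result.stage_counts,
                "transcriptome": {
                    "n_transcripts": result.transcript_stats.n_transcripts,
                    "n_genes": result.transcript_stats.n_genes,
                    "mean_length": result.transcript_stats.mean_length,
                    "n50": result.transcript_stats.n50,
                    "pct_below_500": result.transcript_stats.pct_below_500,
                },
            },
            fh, indent=2, sort_keys=True,
        )
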