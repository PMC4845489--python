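"""Intersection of deletions with gene and QTL tracks.

Deletions that survive filtering delimit reference sequence absent from the
sequenced sample; genes inside them are candidates for having been acquired
by the reference cultivar.  This module maps deletions onto gene and QTL
annotation tracks, summarises transposable-element composition, and builds
the deletion-gene-QTL relationship and per-trait summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from ._util import percent

#: Fixed six-way trait-category vocabulary for QTL records.
TRAIT_CATEGORIES = ("yield", "vigor", "anatomy", "quality", "biochemical", "development")


@dataclass(frozen=True, slots=True)
class GeneFeature:
    """A gene interval (1-based inclusive) with transposable-element flags."""

    gene_id: str
    chrom: str
    start: int
    end: int
    is_te: bool = False
    is_retrotransposon: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.is_retrotransposon and not self.is_te:
            raise ValueError(f"{self.gene_id}: retrotransposon implies TE")


@dataclass(frozen=True, slots=True)
class QTLFeature:
    """A quantitative-trait-locus interval with a trait label and category."""

    qtl_id: str
    chrom: str
    start: int
    end: int
    trait: str
    category: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.qtl_id}: start > end")
        if self.category not in TRAIT_CATEGORIES:
            raise ValueError(f"{self.qtl_id}: unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# track I/O

def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};is_te={int(g.is_te)};"
                f"is_retro={int(g.is_retrotransposon)}"
            )
            fh.write(
                f"{g.chrom}\tgainloss\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneFeature]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(
                GeneFeature(
                    gene_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    chrom=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    is_te=attrs.get("is_te", "0") == "1",
                    is_retrotransposon=attrs.get("is_retro", "0") == "1",
                )
            )
    return genes


def write_qtl_bed(qtls, path) -> None:
    """QTL track as BED (0-based half-open) with trait and category columns."""
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(
                f"{q.chrom}\t{q.start - 1}\t{q.end}\t{q.trait}\t{q.category}\t{q.qtl_id}\n"
            )


def read_qtl_bed(path) -> list[QTLFeature]:
    qtls = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qtls.append(
                QTLFeature(
                    qtl_id=f[5] if len(f) > 5 else f"qtl{i}",
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    trait=f[3],
                    category=f[4] if len(f) > 4 else TRAIT_CATEGORIES[0],
                )
            )
    return qtls


# ---------------------------------------------------------------------------
# intersection

def intersect_deletions_features(deletions, features) -> dict[str, list]:
    """Map each deletion to the features sharing at least one base with it.

    ``deletions`` is a sequence of objects with ``id`` and a ``region1``
    triple (chrom, start, end), or (id, chrom, start, end) tuples.  Both
    coordinate systems are 1-based inclusive; a feature starting exactly one
    base past a deletion's end does not overlap.  Features on chromosomes
    absent from the deletion set trigger a warning and are skipped.
    """
    dels = [_as_interval(d) for d in deletions]
    chroms = {c for _, c, _, _ in dels}
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    for f in features:
        if f.chrom not in trees:
            warnings.warn(f"feature {_feature_id(f)} on unknown chromosome {f.chrom}; skipped")
            continue
        # half-open storage: 1-based inclusive [s, e] -> [s, e+1)
        trees[f.chrom].addi(f.start, f.end + 1, f)
    mapping: dict[str, list] = {}
    for del_id, chrom, start, end in dels:
        hits = trees[chrom].overlap(start, end + 1)
        mapping[del_id] = sorted((h.data for h in hits), key=_feature_id)
    return mapping


def _as_interval(d) -> tuple[str, str, int, int]:
    if hasattr(d, "region1"):
        chrom, start, end = d.region1
        return d.id, chrom, start, end
    del_id, chrom, start, end = d
    return del_id, chrom, start, end


def _feature_id(f) -> str:
    return getattr(f, "gene_id", None) or getattr(f, "qtl_id", "")


# ---------------------------------------------------------------------------
# summaries

@dataclass
class DeletionGeneStats:
    n_deletions: int
    n_with_gene: int
    n_single_gene: int
    n_genes: int
    pct_with_gene: float
    pct_single_gene: float
    top_deletions: list = field(default_factory=list)


def deletion_gene_stats(mapping: dict[str, list], top_k: int = 8) -> DeletionGeneStats:
    """Summary of the deletion-to-gene mapping: fraction of deletions hitting
    at least one gene, fraction of those with exactly one, and the top-k
    deletions by gene count.  Percentages are round-half-up to 2 decimals,
    with an explicit zero-denominator guard."""
    n = len(mapping)
    hit = {d: gs for d, gs in mapping.items() if gs}
    n_hit = len(hit)
    n_single = sum(1 for gs in hit.values() if len(gs) == 1)
    genes = {g.gene_id for gs in hit.values() for g in gs}
    top = sorted(hit.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_k]
    return DeletionGeneStats(
        n_deletions=n,
        n_with_gene=n_hit,
        n_single_gene=n_single,
        n_genes=len(genes),
        pct_with_gene=percent(n_hit, n) if n else 0.00,
        pct_single_gene=percent(n_single, n_hit) if n_hit else 0.00,
        top_deletions=[(d, len(gs)) for d, gs in top],
    )


@dataclass(frozen=True)
class TESummary:
    te_pct_subset: float
    retro_pct_of_te_subset: float
    te_pct_universe: float
    retro_pct_of_te_universe: float
    counts: dict


def te_summary(gene_subset, gene_universe) -> TESummary:
    """Transposable-element composition of a gene subset (e.g. deleted genes)
    against the whole-genome gene universe."""

    def comp(genes):
        te = [g for g in genes if g.is_te]
        retro = [g for g in te if g.is_retrotransposon]
        return len(genes), len(te), len(retro)

    ns, ts, rs = comp(gene_subset)
    nu, tu, ru = comp(gene_universe)
    return TESummary(
        te_pct_subset=percent(ts, ns) if ns else 0.00,
        retro_pct_of_te_subset=percent(rs, ts) if ts else 0.00,
        te_pct_universe=percent(tu, nu) if nu else 0.00,
        retro_pct_of_te_universe=percent(ru, tu) if tu else 0.00,
        counts=dict(
            subset=ns, subset_te=ts, subset_retro=rs,
            universe=nu, universe_te=tu, universe_retro=ru,
        ),
    )


def qtl_dedup(raw_qtls, key: str = "coord+trait") -> list[QTLFeature]:
    """Collapse redundant QTL records.

    With the default key, records identical in (chrom, start, end, trait)
    collapse to one; ``key="coord"`` collapses on coordinates alone.
    """
    if key not in ("coord+trait", "coord"):
        raise ValueError("key must be 'coord+trait' or 'coord'")
    seen = set()
    out = []
    for q in raw_qtls:
        k = (q.chrom, q.start, q.end) if key == "coord" else (q.chrom, q.start, q.end, q.trait)
        if k in seen:
            continue
        seen.add(k)
        out.append(q)
    return out


def relationship_table(
    deletions, gene_mapping: dict[str, list], qtl_mapping: dict[str, list]
) -> pd.DataFrame:
    """Rows of (deletion, co-located gene ids, co-located QTL ids), restricted
    to deletions touching at least one gene or QTL."""
    rows = []
    for d in deletions:
        del_id, chrom, start, end = _as_interval(d)
        genes = gene_mapping.get(del_id, [])
        qtls = qtl_mapping.get(del_id, [])
        if not genes and not qtls:
            continue
        rows.append(
            {
                "deletion_id": del_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "gene_ids": ";".join(g.gene_id for g in genes),
                "qtl_ids": ";".join(q.qtl_id for q in qtls),
            }
        )
    return pd.DataFrame(
        rows, columns=["deletion_id", "chrom", "start", "end", "gene_ids", "qtl_ids"]
    )


def trait_summary(
    qtl_mapping: dict[str, list],
    gene_mapping: dict[str, list],
    dedup_genes_across_traits: bool = False,
) -> pd.DataFrame:
    """Per-trait table (trait, qtl_count, gene_count), sorted by QTL count.

    A trait's gene count is the number of distinct genes sharing at least one
    deletion with any QTL of that trait.  By default a gene contributes to
    every trait it co-locates with; with ``dedup_genes_across_traits`` each
    gene is credited only to the trait with the most QTLs (sort order).
    Also reports the number of unique QTL regions (identical coordinates
    merged) per trait.
    """
    trait_qtls: dict[str, set] = {}
    trait_regions: dict[str, set] = {}
    trait_genes: dict[str, set] = {}
    for del_id, qtls in qtl_mapping.items():
        genes = gene_mapping.get(del_id, [])
        for q in qtls:
            trait_qtls.setdefault(q.trait, set()).add(q.qtl_id)
            trait_regions.setdefault(q.trait, set()).add((q.chrom, q.start, q.end))
            trait_genes.setdefault(q.trait, set()).update(g.gene_id for g in genes)
    order = sorted(trait_qtls, key=lambda t: (-len(trait_qtls[t]), t))
    if dedup_genes_across_traits:
        claimed: set = set()
        for t in order:
            trait_genes[t] = trait_genes.get(t, set()) - claimed
            claimed |= trait_genes[t]
    rows = [
        {
            "trait": t,
            "qtl_count": len(trait_qtls[t]),
            "gene_count": len(trait_genes.get(t, set())),
            "unique_regions": len(trait_regions[t]),
        }
        for t in order
    ]
    return pd.DataFrame(rows, columns=["trait", "qtl_count", "gene_count", "unique_regions"])
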